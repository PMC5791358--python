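"""Table conditioning: global-singleton removal, negative-control
subtraction, rarefaction, and relative-abundance standardization.

The canonical order of operations, mirrored by :func:`preprocess_pipeline`,
is singleton removal → control subtraction → rarefaction.  Reordering these
steps changes the result (a control read subtracted before rarefaction has a
different effect than after), so the driver fixes the order once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_model import FeatureTable, Metadata


@dataclass
class ControlProfile:
    """Per-method negative-control read counts, subtracted from field samples."""

    sample_type: str
    counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for otu, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative control count for OTU {otu!r}: {c}")


def _require_integer(table: FeatureTable, op: str) -> None:
    if not np.allclose(table.counts, np.round(table.counts), atol=1e-9):
        raise ValueError(f"{op} requires integer counts")


def remove_global_singletons(table: FeatureTable) -> FeatureTable:
    """Drop every OTU whose total count across ALL samples equals exactly 1."""
    _require_integer(table, "singleton removal")
    totals = table.otu_sums()
    keep = totals != 1
    if not keep.any():
        warnings.warn("all OTUs are global singletons; result is empty")
    kept_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    return FeatureTable(list(table.sample_ids), kept_ids, table.counts[:, keep])


def subtract_negative_control(
    table: FeatureTable, profile: ControlProfile, metadata: Metadata
) -> FeatureTable:
    """Subtract control reads, clamped at zero, from samples of the profile's type.

    Control counts are subtracted raw (reads, not proportions) from every
    sample whose metadata method matches ``profile.sample_type``; other
    samples and OTUs are untouched.  Subtraction is idempotent once a count
    reaches zero.
    """
    out = table.copy()
    otu_pos = {o: j for j, o in enumerate(table.otu_ids)}
    target_rows = [
        i for i, s in enumerate(table.sample_ids)
        if metadata.method_of(s) == profile.sample_type
    ]
    for otu, ctrl in profile.counts.items():
        j = otu_pos.get(otu)
        if j is None:
            warnings.warn(
                f"control profile ({profile.sample_type}) references OTU "
                f"{otu!r} absent from table; ignored"
            )
            continue
        for i in target_rows:
            out.counts[i, j] = max(0.0, out.counts[i, j] - ctrl)
    return out


def min_depth(table: FeatureTable) -> int:
    """Smallest per-sample read total — the conventional rarefaction depth."""
    if table.n_samples == 0:
        raise ValueError("empty table has no minimum depth")
    sums = table.sample_sums()
    depth = int(round(sums.min()))
    if depth == 0:
        warnings.warn("table contains an all-zero sample; min depth is 0")
    return depth


def rarefy(table: FeatureTable, depth: int, seed) -> FeatureTable:
    """Subsample each sample's reads to ``depth`` without replacement.

    Each retained sample is an exact multivariate-hypergeometric draw (all
    read subsets equally likely) summing to ``depth``; samples whose total is
    below ``depth`` are dropped with a warning.  Deterministic given ``seed``
    (an int or a ``numpy.random.Generator``).
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    _require_integer(table, "rarefaction")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.round(table.counts).astype(np.int64)
    kept_ids: list[str] = []
    rows: list[np.ndarray] = []
    dropped: list[str] = []
    for i, s in enumerate(table.sample_ids):
        total = int(counts[i].sum())
        if total < depth:
            dropped.append(s)
            continue
        if total == depth:
            rows.append(counts[i].astype(float))
        else:
            rows.append(rng.multivariate_hypergeometric(counts[i], depth).astype(float))
        kept_ids.append(s)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} sample(s) below depth {depth}: {dropped}")
    mat = np.array(rows, dtype=float).reshape(len(kept_ids), table.n_otus)
    return FeatureTable(kept_ids, list(table.otu_ids), mat)


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Standardize each sample to proportions of its total reads (rows sum to 1)."""
    sums = table.sample_sums()
    zero = np.nonzero(sums <= 0)[0]
    if zero.size:
        raise ValueError(
            f"cannot compute proportions: sample {table.sample_ids[zero[0]]!r} has zero total"
        )
    return FeatureTable(
        list(table.sample_ids), list(table.otu_ids), table.counts / sums[:, None]
    )


def preprocess_pipeline(
    table: FeatureTable,
    controls: list[ControlProfile],
    metadata: Metadata,
    depth="auto",
    seed=0,
) -> tuple[FeatureTable, int]:
    """Canonical conditioning chain: singletons → control subtraction → rarefaction.

    ``depth='auto'`` rarefies to the post-subtraction minimum sample total.
    Returns the rarefied table and the depth used.
    """
    out = remove_global_singletons(table)
    for profile in controls:
        out = subtract_negative_control(out, profile, metadata)
    out.counts = np.round(out.counts)
    d = min_depth(out) if depth == "auto" else int(depth)
    return rarefy(out, d, seed), d
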