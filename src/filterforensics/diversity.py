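"""Within-group diversity and membership statistics on rarefied tables.

Covers OTU richness per sample type, log(x+1) rank-abundance profiles with
standard errors, the minimum number of OTUs accounting for a given read
fraction, the core microbiome (OTUs present in every replicate of a group),
and the fraction of OTUs observed in exactly one sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_model import FeatureTable


@dataclass
class RankAbundance:
    group: str
    ranked_otu_ids: list[str]
    mean_log_abundance: np.ndarray  # non-increasing
    se: np.ndarray


@dataclass
class CoreResult:
    group: str
    core_otu_ids: list[str]
    pct_of_group_otus: float
    pct_of_group_reads: float


def _group_counts(table: FeatureTable, sample_ids: Sequence[str]) -> np.ndarray:
    idx = [table.sample_index(s) for s in sample_ids]
    return table.counts[idx]


def richness(table: FeatureTable, sample_ids: Sequence[str]) -> int:
    """Number of OTUs with nonzero total count across the group's samples."""
    if len(sample_ids) == 0:
        return 0
    sub = _group_counts(table, sample_ids)
    return int(np.count_nonzero(sub.sum(axis=0) > 0))


def rank_abundance(
    table: FeatureTable, sample_ids: Sequence[str], group: str = ""
) -> RankAbundance:
    """Per-OTU mean and SE of log(x+1) counts, ranked by mean descending.

    SE uses the n−1 sample standard deviation over the group's n samples;
    ties in the mean are broken by OTU id ascending so the ranking is
    deterministic.
    """
    sub = _group_counts(table, sample_ids)
    n = sub.shape[0]
    if n == 0:
        raise ValueError("rank_abundance needs at least one sample")
    logged = np.log1p(sub)
    means = logged.mean(axis=0)
    sds = logged.std(axis=0, ddof=1) if n > 1 else np.zeros_like(means)
    ses = sds / np.sqrt(n)
    order = sorted(range(table.n_otus), key=lambda j: (-means[j], table.otu_ids[j]))
    return RankAbundance(
        group=group,
        ranked_otu_ids=[table.otu_ids[j] for j in order],
        mean_log_abundance=means[order],
        se=ses[order],
    )


def min_otus_for_fraction(
    table: FeatureTable,
    sample_ids: Sequence[str],
    fraction: float = 0.5,
    ranking: str = "log_mean",
) -> int:
    """Smallest k such that the top-k ranked OTUs hold ≥ ``fraction`` of reads.

    Ranking follows the rank-abundance ordering (mean of log(x+1), the
    plotted quantity) by default; ``ranking='raw'`` orders by raw total
    counts instead.  Cumulative fractions always use raw counts.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(sample_ids) == 0:
        raise ValueError("empty group")
    sub = _group_counts(table, sample_ids)
    totals = sub.sum(axis=0)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("group has no reads")
    if ranking == "log_mean":
        order = [
            table.otu_ids.index(o)
            for o in rank_abundance(table, sample_ids).ranked_otu_ids
        ]
    elif ranking == "raw":
        order = sorted(range(table.n_otus), key=lambda j: (-totals[j], table.otu_ids[j]))
    else:
        raise ValueError(f"unknown ranking {ranking!r}")
    cum = np.cumsum(totals[order]) / grand
    k = int(np.searchsorted(cum, fraction - 1e-12) + 1)
    return k


def core_microbiome(
    table: FeatureTable, sample_ids: Sequence[str], group: str = ""
) -> CoreResult:
    """OTUs present (count > 0) in EVERY sample of the group.

    Percentages are relative to the OTUs observed in at least one group
    sample and to the group's total reads.
    """
    if len(sample_ids) == 0:
        raise ValueError("core microbiome needs at least one sample")
    sub = _group_counts(table, sample_ids)
    present = sub > 0
    observed = present.any(axis=0)
    core = present.all(axis=0)
    n_observed = int(observed.sum())
    core_ids = [o for o, c in zip(table.otu_ids, core) if c]
    group_reads = sub.sum()
    core_reads = sub[:, core].sum()
    return CoreResult(
        group=group,
        core_otu_ids=core_ids,
        pct_of_group_otus=100.0 * len(core_ids) / n_observed if n_observed else 0.0,
        pct_of_group_reads=100.0 * core_reads / group_reads if group_reads else 0.0,
    )


def singleton_fraction(table: FeatureTable) -> float:
    """Percent of OTUs observed (count > 0) in exactly one sample.

    This is occupancy-based presence, not total-count-1: global singleton
    OTUs are removed upstream, so a count-based reading would be vacuous.
    """
    if table.n_otus == 0:
        raise ValueError("empty table")
    occupancy = (table.counts > 0).sum(axis=0)
    return 100.0 * np.count_nonzero(occupancy == 1) / table.n_otus
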