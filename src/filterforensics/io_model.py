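"""Core data types and readers/writers for the formats the pipeline touches.

The central object is the :class:`FeatureTable`, a samples × OTUs count
matrix.  On disk, tables travel either in the classic QIIME-era tab-separated
OTU-table dialect (OTUs as rows, first header column literally ``#OTU ID``,
optional trailing ``taxonomy`` column) or as BIOM-JSON (format 1.0).  Trees
are newick (via dendropy), sample metadata and taxonomy are plain TSV.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

VALID_METHODS = ("cut", "swab", "vacuum", "control")

RANK_PREFIXES = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}
RANK_ORDER = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class FeatureTableError(ValueError):
    """Raised when a feature table violates its invariants or fails to parse."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FeatureTableError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class FeatureTable:
    """Samples × OTUs count matrix with ordered, unique axis labels.

    Counts are stored as floats internally; integrality is only enforced by
    the operations that require it (e.g. rarefaction).
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray  # shape (n_samples, n_otus)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.otu_ids = list(self.otu_ids)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.sample_ids),
            len(self.otu_ids),
        ):
            raise FeatureTableError(
                f"count matrix shape {self.counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            s, o = np.argwhere((self.counts < 0) | ~np.isfinite(self.counts))[0]
            raise FeatureTableError(
                f"invalid count for sample {self.sample_ids[s]!r}, "
                f"OTU {self.otu_ids[o]!r}: {self.counts[s, o]}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return FeatureTable(list(sample_ids), list(self.otu_ids), self.counts[idx])

    def select_otus(self, otu_ids: Sequence[str]) -> "FeatureTable":
        pos = {o: j for j, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in otu_ids]
        return FeatureTable(list(self.sample_ids), list(otu_ids), self.counts[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def copy(self) -> "FeatureTable":
        return FeatureTable(list(self.sample_ids), list(self.otu_ids), self.counts.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.allclose(self.counts, other.counts, atol=1e-9)
        )


@dataclass
class Lineage:
    """Ordered (rank, name) pairs from kingdom downward; '' marks unassigned."""

    levels: list[tuple[str, str]]

    def name_at(self, rank: str) -> Optional[str]:
        for r, n in self.levels:
            if r == rank:
                return n or None
        return None

    def to_string(self) -> str:
        parts = []
        for rank, name in self.levels:
            prefix = next(k for k, v in RANK_PREFIXES.items() if v == rank)
            parts.append(f"{prefix}__{name}")
        return "; ".join(parts)


def parse_lineage(text: str) -> Lineage:
    """Parse a Greengenes/UNITE-style lineage string like ``k__Fungi; p__Ascomycota``."""
    levels: list[tuple[str, str]] = []
    chunks = [c.strip() for c in text.split(";") if c.strip()]
    for pos, chunk in enumerate(chunks):
        if len(chunk) >= 3 and chunk[1:3] == "__" and chunk[0] in RANK_PREFIXES:
            rank = RANK_PREFIXES[chunk[0]]
            name = chunk[3:].strip()
        else:
            rank = RANK_ORDER[pos] if pos < len(RANK_ORDER) else f"level_{pos}"
            name = chunk
        levels.append((rank, name))
    ranks = [r for r, _ in levels]
    order = {r: i for i, r in enumerate(RANK_ORDER)}
    known = [order[r] for r in ranks if r in order]
    if known != sorted(known):
        raise ValueError(f"lineage ranks out of order in {text!r}")
    return Lineage(levels)


@dataclass
class TaxonomyMap:
    """otu_id → :class:`Lineage`."""

    assignments: dict[str, Lineage] = field(default_factory=dict)

    def __getitem__(self, otu_id: str) -> Lineage:
        return self.assignments[otu_id]

    def get(self, otu_id: str) -> Optional[Lineage]:
        return self.assignments.get(otu_id)

    def __len__(self) -> int:
        return len(self.assignments)

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.assignments


@dataclass
class Metadata:
    """Per-sample metadata: collection method, household, assay, area, mass."""

    frame: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValueError(f"duplicate sample id in metadata: {dup!r}")
        bad = set(self.frame["method"]) - set(VALID_METHODS)
        if bad:
            raise ValueError(
                f"unknown method value(s) {sorted(bad)}; allowed: {list(VALID_METHODS)}"
            )
        if "sampled_area_cm2" in self.frame.columns:
            areas = self.frame["sampled_area_cm2"].dropna()
            if (areas <= 0).any():
                raise ValueError("sampled_area_cm2 must be > 0")

    def method_of(self, sample_id: str) -> str:
        return str(self.frame.loc[sample_id, "method"])

    def samples_with_method(self, method: str) -> list[str]:
        return list(self.frame.index[self.frame["method"] == method])

    def methods_present(self) -> list[str]:
        seen: list[str] = []
        for m in self.frame["method"]:
            if m not in seen:
                seen.append(m)
        return seen

    def groups_for(self, sample_ids: Sequence[str], column: str = "method") -> np.ndarray:
        return self.frame.loc[list(sample_ids), column].to_numpy()


@dataclass
class PhyloTree:
    """Rooted tree over OTU leaf labels with non-negative branch lengths."""

    tree: dendropy.Tree
    was_midpoint_rooted: bool = False

    @property
    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        _check_unique(self.ids, "distance-matrix")
        if self.values.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if np.any(self.values < -1e-12):
            raise ValueError("negative distances")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix not symmetric within 1e-10")
        if not np.allclose(np.diag(self.values), 0, atol=1e-10):
            raise ValueError("distance matrix diagonal not zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def reorder(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Feature-table IO
# ---------------------------------------------------------------------------

def read_feature_table(
    path, dialect: str = "classic_tsv", with_taxonomy: bool = False
):
    """Read a feature table (and optionally its in-table taxonomy column).

    Parameters
    ----------
    path : str or Path
    dialect : {"classic_tsv", "biom_json"}
    with_taxonomy : bool
        If True, return ``(table, TaxonomyMap)``; the map is empty when the
        file carries no lineage information.
    """
    if dialect == "classic_tsv":
        table, tax = _read_classic_tsv(path)
    elif dialect == "biom_json":
        table, tax = _read_biom_json(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return (table, tax) if with_taxonomy else table


def _read_classic_tsv(path):
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    header_idx = None
    for i, ln in enumerate(lines):
        if ln.startswith("#OTU ID"):
            header_idx = i
            break
    if header_idx is None:
        raise FeatureTableError(f"{path}: no '#OTU ID' header line found")
    header = lines[header_idx].split("\t")
    has_tax = bool(header) and header[-1].strip().lower() == "taxonomy"
    sample_ids = header[1 : -1 if has_tax else None]
    otu_ids: list[str] = []
    rows: list[list[float]] = []
    tax = TaxonomyMap()
    for ln in lines[header_idx + 1 :]:
        if not ln.strip():
            continue
        fields_ = ln.split("\t")
        otu_id = fields_[0]
        vals = fields_[1 : len(sample_ids) + 1]
        if len(vals) != len(sample_ids):
            raise FeatureTableError(
                f"{path}: row {otu_id!r} has {len(vals)} counts, expected {len(sample_ids)}"
            )
        row = []
        for s_id, v in zip(sample_ids, vals):
            try:
                x = float(v)
            except ValueError:
                raise FeatureTableError(
                    f"{path}: non-numeric count {v!r} at OTU {otu_id!r}, sample {s_id!r}"
                ) from None
            if x < 0:
                raise FeatureTableError(
                    f"{path}: negative count {x} at OTU {otu_id!r}, sample {s_id!r}"
                )
            row.append(x)
        if has_tax and len(fields_) > len(sample_ids) + 1:
            lineage_text = fields_[len(sample_ids) + 1].strip()
            if lineage_text:
                tax.assignments[otu_id] = parse_lineage(lineage_text)
        otu_ids.append(otu_id)
        rows.append(row)
    counts = np.array(rows, dtype=float).reshape(len(otu_ids), len(sample_ids))
    return FeatureTable(sample_ids, otu_ids, counts.T), tax


def _read_biom_json(path):
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_r, n_c = doc["shape"]
    mat = np.zeros((n_r, n_c))
    if doc["matrix_type"] == "sparse":
        for r, c, v in doc["data"]:
            mat[r, c] = v
    else:
        mat = np.asarray(doc["data"], dtype=float)
    tax = TaxonomyMap()
    for r in doc["rows"]:
        meta = r.get("metadata") or {}
        lineage = meta.get("taxonomy")
        if lineage:
            if isinstance(lineage, list):
                lineage = "; ".join(lineage)
            tax.assignments[r["id"]] = parse_lineage(lineage)
    if np.any(mat < 0):
        r, c = np.argwhere(mat < 0)[0]
        raise FeatureTableError(
            f"{path}: negative count at OTU {otu_ids[r]!r}, sample {sample_ids[c]!r}"
        )
    return FeatureTable(sample_ids, otu_ids, mat.T), tax


def write_feature_table(
    table: FeatureTable, path, dialect: str = "classic_tsv",
    taxonomy: Optional[TaxonomyMap] = None,
) -> None:
    """Write ``table`` so that reading it back reproduces it exactly."""
    if dialect == "classic_tsv":
        _write_classic_tsv(table, path, taxonomy)
    elif dialect == "biom_json":
        _write_biom_json(table, path, taxonomy)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _fmt(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def _write_classic_tsv(table, path, taxonomy=None):
    with open(path, "w") as fh:
        header = ["#OTU ID", *table.sample_ids]
        if taxonomy is not None:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        for j, otu in enumerate(table.otu_ids):
            row = [otu, *(_fmt(v) for v in table.counts[:, j])]
            if taxonomy is not None:
                lin = taxonomy.get(otu)
                row.append(lin.to_string() if lin else "")
            fh.write("\t".join(row) + "\n")


def _write_biom_json(table, path, taxonomy=None):
    rows = []
    for otu in table.otu_ids:
        meta = None
        if taxonomy is not None and otu in taxonomy:
            meta = {"taxonomy": taxonomy[otu].to_string()}
        rows.append({"id": otu, "metadata": meta})
    mat = table.counts.T  # observations x samples
    data = [
        [int(r), int(c), float(mat[r, c])]
        for r, c in zip(*np.nonzero(mat))
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "filterforensics",
        "date": "",
        "rows": rows,
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": [table.n_otus, table.n_samples],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# Tree IO
# ---------------------------------------------------------------------------

def read_tree(path=None, newick: Optional[str] = None) -> PhyloTree:
    """Read a rooted newick tree; midpoint-roots (with a warning) if unrooted."""
    if newick is not None:
        src = io.StringIO(newick)
        tree = dendropy.Tree.get(file=src, schema="newick", preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length} in tree")
    midpointed = False
    root_children = tree.seed_node.child_nodes()
    if len(root_children) > 2:
        warnings.warn("tree appears unrooted (root has >2 children); midpoint-rooting")
        n_leaves = len(tree.leaf_nodes())
        trial = tree.clone(depth=1)
        trial.reroot_at_midpoint(update_bipartitions=True)
        if len(trial.leaf_nodes()) == n_leaves:
            tree = trial
        else:
            # midpoint falls exactly on a node (e.g. a star tree) and dendropy
            # degenerates; split the longest root-adjacent edge at its middle
            edge = max(
                (c.edge for c in tree.seed_node.child_nodes()),
                key=lambda e: e.length or 0.0,
            )
            half = (edge.length or 0.0) / 2
            tree.reroot_at_edge(edge, length1=half, length2=half)
        midpointed = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    _check_unique(labels, "leaf")
    return PhyloTree(tree, was_midpoint_rooted=midpointed)


def write_tree(ptree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(ptree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Metadata / taxonomy IO
# ---------------------------------------------------------------------------

_META_REQUIRED = ("sample_id", "method")


def read_metadata(path) -> Metadata:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in _META_REQUIRED:
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required metadata column {col!r}")
    frame = frame.set_index("sample_id")
    return Metadata(frame)


def write_metadata(meta: Metadata, path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_taxonomy(path) -> TaxonomyMap:
    """Read a 2-column TSV: otu_id TAB lineage ('; '-separated ranks)."""
    tax = TaxonomyMap()
    with open(path) as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: taxonomy line lacks a lineage: {ln!r}")
            otu_id, lineage = parts[0], parts[1]
            if otu_id in tax:
                raise ValueError(f"{path}: duplicate taxonomy for OTU {otu_id!r}")
            tax.assignments[otu_id] = parse_lineage(lineage)
    return tax


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        for otu_id, lineage in tax.assignments.items():
            fh.write(f"{otu_id}\t{lineage.to_string()}\n")


def read_distance_matrix(path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix([str(c) for c in frame.columns], frame.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.values, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
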