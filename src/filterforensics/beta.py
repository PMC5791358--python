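"""Pairwise community dissimilarities and principal coordinates analysis.

Two dissimilarities are implemented: Morisita-Horn (abundance overlap,
insensitive to total counts) and weighted UniFrac (phylogenetic, weighting
each branch by the difference in the fraction of reads descending from it).
Ordination is classical metric scaling (PCoA) on squared distances, with
negative-eigenvalue mass reported rather than silently dropped — Morisita-
Horn matrices need not be Euclidean-embeddable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_model import DistanceMatrix, FeatureTable, PhyloTree

METRICS = ("morisita_horn", "weighted_unifrac", "weighted_unifrac_normalized")


@dataclass
class Ordination:
    ids: list[str]
    coordinates: np.ndarray  # samples x positive axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues
    negative_eigenvalue_correction: bool


def morisita_horn(x, y) -> float:
    """Morisita-Horn dissimilarity: 1 − 2Σxy / ((dx+dy)·X·Y).

    X, Y are the totals and dx = Σx²/X², dy = Σy²/Y² are Simpson
    concentration indices.  Identical relative compositions give 0; disjoint
    support gives 1; either vector may be scaled by a positive constant
    without changing the value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X, Y = x.sum(), y.sum()
    if X <= 0 or Y <= 0:
        raise ValueError("Morisita-Horn requires positive totals")
    dx = (x @ x) / X**2
    dy = (y @ y) / Y**2
    sim = 2.0 * (x @ y) / ((dx + dy) * X * Y)
    return float(min(max(1.0 - sim, 0.0), 1.0))


class _TreeIndex:
    """Postorder array view of a rooted tree for fast branch-proportion sums."""

    def __init__(self, ptree: PhyloTree):
        nodes = list(ptree.tree.postorder_node_iter())
        self.index = {id(nd): i for i, nd in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        self.length = np.zeros(self.n_nodes)
        self.leaf_rows: list[tuple[int, str]] = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                self.parent[i] = self.index[id(nd.parent_node)]
                self.length[i] = nd.edge.length or 0.0
            if nd.is_leaf():
                self.leaf_rows.append((i, nd.taxon.label))
        self.leaf_label_to_node = {lab: i for i, lab in self.leaf_rows}

    def branch_proportions(self, table: FeatureTable) -> np.ndarray:
        """(samples × nodes) matrix of read fractions descending from each branch."""
        missing = []
        leaf_node = np.full(table.n_otus, -1, dtype=np.int64)
        nonzero = table.otu_sums() > 0
        for j, otu in enumerate(table.otu_ids):
            node = self.leaf_label_to_node.get(otu, -1)
            if node < 0 and nonzero[j]:
                missing.append(otu)
            leaf_node[j] = node
        if missing:
            raise ValueError(f"OTUs with reads missing from tree: {missing}")
        totals = table.sample_sums()
        if np.any(totals <= 0):
            raise ValueError("weighted UniFrac requires positive sample totals")
        acc = np.zeros((table.n_samples, self.n_nodes))
        for j, node in enumerate(leaf_node):
            if node >= 0:
                acc[:, node] += table.counts[:, j]
        # postorder: children precede parents, so a single forward pass sums subtrees
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                acc[:, p] += acc[:, i]
        return acc / totals[:, None]


def weighted_unifrac(x, y, tree: PhyloTree, otu_ids=None, normalized: bool = True) -> float:
    """Weighted UniFrac between two count vectors over the tree's leaves.

    Raw form: Σ_b len(b)·|p_x(b) − p_y(b)| over branches b, p being the
    fraction of the sample's reads descending from b.  The normalized form
    divides by Σ_b len(b)·(p_x(b) + p_y(b)), bounding the result in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if otu_ids is None:
        otu_ids = tree.leaf_names
    table = FeatureTable(["x", "y"], list(otu_ids), np.vstack([x, y]))
    idx = _TreeIndex(tree)
    P = idx.branch_proportions(table)
    return _unifrac_from_proportions(P[0], P[1], idx.length, normalized)


def _unifrac_from_proportions(pa, pb, lengths, normalized: bool) -> float:
    raw = float(lengths @ np.abs(pa - pb))
    if not normalized:
        return raw
    denom = float(lengths @ (pa + pb))
    if denom <= 0:
        return 0.0
    return raw / denom


def distance_matrix(
    table: FeatureTable, metric: str, tree: PhyloTree | None = None
) -> DistanceMatrix:
    """All-pairs dissimilarities over the table's samples."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    n = table.n_samples
    vals = np.zeros((n, n))
    if metric == "morisita_horn":
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = morisita_horn(
                    table.counts[i], table.counts[j]
                )
    else:
        if tree is None:
            raise ValueError("weighted UniFrac requires a tree")
        idx = _TreeIndex(tree)
        P = idx.branch_proportions(table)
        normalized = metric == "weighted_unifrac_normalized"
        for i in range(n):
            for j in range(i + 1, n):
                vals[i, j] = vals[j, i] = _unifrac_from_proportions(
                    P[i], P[j], idx.length, normalized
                )
    return DistanceMatrix(list(table.sample_ids), vals)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa_full(dmatrix: DistanceMatrix, tol: float = 1e-9):
    """Eigendecomposition of the Gower-centered matrix, all axes.

    Returns ``(eigenvalues_desc, real_coords, imag_coords)`` where real
    coordinates correspond to eigenvalues > tol and imaginary coordinates to
    eigenvalues < −tol (each scaled by √|λ|).  The imaginary part is what
    the dispersion test subtracts when distances are non-Euclidean.
    """
    g = _gower_center(dmatrix.values)
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    scale = np.sqrt(np.maximum(dmatrix.values.max(), 1.0))
    cut = tol * scale**2
    pos = eigval > cut
    neg = eigval < -cut
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return eigval, real, imag


def pcoa(dmatrix: DistanceMatrix) -> Ordination:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Coordinates are returned for positive eigenvalues only; proportion
    explained is relative to the positive eigenvalue total, and a flag
    records whether negative eigenvalues (non-Euclidean input) were present.
    """
    eigval, real, imag = pcoa_full(dmatrix)
    pos_sum = eigval[eigval > 0].sum()
    n_axes = real.shape[1]
    prop = (
        eigval[:n_axes] / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    )
    return Ordination(
        ids=list(dmatrix.ids),
        coordinates=real,
        eigenvalues=eigval,
        proportion_explained=prop,
        negative_eigenvalue_correction=imag.shape[1] > 0,
    )
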