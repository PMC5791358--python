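"""Permutation and resampling statistics.

One-factor PERMANOVA (the vegan ``adonis`` construction), the multivariate
homogeneity-of-dispersions test (``betadisper``: distances to group
centroids in PCoA space with Tukey HSD pairwise comparisons), the Mantel
test between distance matrices, and bootstrap confidence intervals for
coefficients of variation and CV differences.

Permutation p-values use the add-one convention
``p = (#{stat_perm >= stat_obs} + 1) / (n_perm + 1)`` so p is never 0 and
has resolution 1/(n_perm+1) — e.g. a floor of 0.001 at 999 permutations.
When the set of distinct label assignments (PERMANOVA) or row orders
(Mantel) is no larger than ``n_perm``, the null is enumerated exhaustively
and p is the exact fraction of the enumerated statistics at least as large
as the observed one (the identity assignment included).
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .beta import pcoa_full
from .io_model import DistanceMatrix


@dataclass
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: Optional[int]
    exhaustive: bool = False


@dataclass
class DispersionResult:
    group_distances: dict[str, np.ndarray]
    global_F: float
    global_p: float  # permutation p
    parametric_p: float
    pairwise: list[tuple[str, str, float]]  # Tukey HSD p by default
    n_permutations: int
    seed: Optional[int]


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: Optional[int]
    exhaustive: bool = False


@dataclass
class CvResult:
    cv: float
    ci_low: float
    ci_high: float
    n_boot: int
    alpha: float
    seed: Optional[int]
    excludes_zero_95: Optional[bool] = None
    excludes_zero_90: Optional[bool] = None
    n_redrawn: int = 0


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _encode_groups(groups: Sequence) -> tuple[np.ndarray, list]:
    labels = list(dict.fromkeys(groups))
    code = {g: i for i, g in enumerate(labels)}
    return np.array([code[g] for g in groups], dtype=np.int64), labels


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.nonzero(codes == g)[0]
        ng = idx.size
        if ng > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_between = ss_total - ss_within
    f = (ss_between / (k - 1)) / (ss_within / (n - k)) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _multiset_permutations(items: np.ndarray):
    """Yield every distinct ordering of a label vector (lexicographic)."""
    items = np.sort(items)
    n = items.size
    while True:
        yield items.copy()
        i = n - 2
        while i >= 0 and items[i] >= items[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while items[j] <= items[i]:
            j -= 1
        items[i], items[j] = items[j], items[i]
        items[i + 1 :] = items[i + 1 :][::-1]


def _n_distinct_assignments(codes: np.ndarray) -> int:
    n = codes.size
    total = math.factorial(n)
    for _, cnt in zip(*np.unique(codes, return_counts=True)):
        total //= math.factorial(int(cnt))
    return total


def permanova(
    dmatrix: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed: Optional[int] = None,
) -> PermanovaResult:
    """One-factor permutational multivariate ANOVA on a distance matrix.

    Pseudo-F partitions the sum of squared distances (SS_total = Σd²/n over
    all pairs; SS_within pooled per group) and R² = SS_between / SS_total is
    the fraction of distance variance the grouping explains.  The p-value
    permutes group labels.
    """
    codes, labels = _encode_groups(groups)
    k = len(labels)
    n = dmatrix.n
    if len(codes) != n:
        raise ValueError("groups length must match distance matrix")
    if k < 2:
        raise ValueError("PERMANOVA needs >= 2 groups")
    if n < 3:
        raise ValueError("PERMANOVA needs >= 3 samples")
    counts = np.bincount(codes, minlength=k)
    if (counts == 0).any():
        raise ValueError("every group needs >= 1 sample")
    d2 = dmatrix.values**2
    f_obs, r2 = _permanova_stats(d2, codes, k)

    n_distinct = _n_distinct_assignments(codes)
    if n_distinct <= n_perm:
        fs = np.array(
            [_permanova_stats(d2, perm, k)[0] for perm in _multiset_permutations(codes)]
        )
        p = float(np.mean(fs >= f_obs - 1e-12))
        return PermanovaResult(f_obs, r2, p, n_distinct, seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        f_p, _ = _permanova_stats(d2, perm, k)
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(f_obs, r2, p, n_perm, seed)


# ---------------------------------------------------------------------------
# Dispersion homogeneity (betadisper)
# ---------------------------------------------------------------------------

def _anova_f(values: np.ndarray, codes: np.ndarray, k: int) -> float:
    n = values.size
    grand = values.mean()
    ss_b = 0.0
    ss_w = 0.0
    for g in range(k):
        v = values[codes == g]
        ss_b += v.size * (v.mean() - grand) ** 2
        ss_w += ((v - v.mean()) ** 2).sum()
    if ss_w <= 0:
        return np.inf if ss_b > 0 else 0.0
    return (ss_b / (k - 1)) / (ss_w / (n - k))


def dispersion_distances(
    dmatrix: DistanceMatrix, groups: Sequence
) -> dict[str, np.ndarray]:
    """Distance of each sample to its group centroid in full PCoA space.

    Samples are embedded with all PCoA axes; negative-eigenvalue ("imaginary")
    axes are kept separately and their squared distances subtracted:
    d = sqrt(max(0, d_real² − d_imag²)), the standard correction for
    non-Euclidean dissimilarities.
    """
    codes, labels = _encode_groups(groups)
    _, real, imag = pcoa_full(dmatrix)
    out: dict[str, np.ndarray] = {}
    for g, label in enumerate(labels):
        idx = np.nonzero(codes == g)[0]
        if idx.size == 1:
            warnings.warn(f"group {label!r} has a single sample; dispersion is 0")
        c_real = real[idx].mean(axis=0)
        c_imag = imag[idx].mean(axis=0) if imag.shape[1] else np.zeros(0)
        d2_real = ((real[idx] - c_real) ** 2).sum(axis=1)
        d2_imag = (
            ((imag[idx] - c_imag) ** 2).sum(axis=1) if imag.shape[1] else 0.0
        )
        out[label] = np.sqrt(np.maximum(0.0, d2_real - d2_imag))
    return out


def dispersion_test(
    dmatrix: DistanceMatrix,
    groups: Sequence,
    n_perm: int = 999,
    seed: Optional[int] = None,
    pairwise: str = "tukey",
) -> DispersionResult:
    """Homogeneity of multivariate dispersions across groups.

    The global statistic is the one-way ANOVA F on distances-to-centroid;
    its p-value is obtained by permuting group labels over those distances
    (the parametric F p-value is reported alongside).  Pairwise comparisons
    use Tukey's HSD on the distances by default, or label-permutation |Δmean|
    tests with ``pairwise='permutation'``.
    """
    codes, labels = _encode_groups(groups)
    k = len(labels)
    by_group = dispersion_distances(dmatrix, groups)
    z = np.empty(len(codes))
    for g, label in enumerate(labels):
        z[codes == g] = by_group[label]
    f_obs = _anova_f(z, codes, k)
    n = z.size
    parametric_p = float(stats.f.sf(f_obs, k - 1, n - k)) if np.isfinite(f_obs) else 0.0

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _anova_f(z, rng.permutation(codes), k) >= f_obs - 1e-12:
            count += 1
    global_p = (count + 1) / (n_perm + 1)

    pairs: list[tuple[str, str, float]] = []
    if k >= 2 and all(by_group[lab].size >= 2 for lab in labels):
        if pairwise == "tukey":
            res = stats.tukey_hsd(*[by_group[lab] for lab in labels])
            for i in range(k):
                for j in range(i + 1, k):
                    pairs.append((labels[i], labels[j], float(res.pvalue[i, j])))
        elif pairwise == "permutation":
            for i in range(k):
                for j in range(i + 1, k):
                    zi, zj = by_group[labels[i]], by_group[labels[j]]
                    obs = abs(zi.mean() - zj.mean())
                    pooled = np.concatenate([zi, zj])
                    cnt = 0
                    for _ in range(n_perm):
                        perm = rng.permutation(pooled)
                        if abs(perm[: zi.size].mean() - perm[zi.size :].mean()) >= obs - 1e-12:
                            cnt += 1
                    pairs.append((labels[i], labels[j], (cnt + 1) / (n_perm + 1)))
        else:
            raise ValueError(f"unknown pairwise mode {pairwise!r}")

    return DispersionResult(
        group_distances=by_group,
        global_F=f_obs,
        global_p=global_p,
        parametric_p=parametric_p,
        pairwise=pairs,
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: Optional[int] = None,
    method: str = "pearson",
) -> MantelResult:
    """Permutational correlation between two distance matrices.

    r is the Pearson (or Spearman) correlation of the n(n−1)/2 off-diagonal
    pairs; the null permutes rows and columns of the second matrix jointly.
    One-sided (greater) p.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices must share ids in the same order")
    n = d1.n
    if n < 4:
        raise ValueError("Mantel test needs n >= 4")
    iu = np.triu_indices(n, k=1)
    v1 = d1.values[iu]
    if method == "spearman":
        v1 = stats.rankdata(v1)
    if np.std(v1) == 0:
        raise ValueError("first matrix has zero off-diagonal variance")

    def corr_with(mat: np.ndarray) -> float:
        v2 = mat[iu]
        if method == "spearman":
            v2 = stats.rankdata(v2)
        if np.std(v2) == 0:
            raise ValueError("second matrix has zero off-diagonal variance")
        return float(np.corrcoef(v1, v2)[0, 1])

    r_obs = corr_with(d2.values)

    if math.factorial(n) <= n_perm:
        import itertools

        rs = []
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            rs.append(corr_with(d2.values[np.ix_(p, p)]))
        rs = np.array(rs)
        p_val = float(np.mean(rs >= r_obs - 1e-12))
        return MantelResult(r_obs, p_val, len(rs), seed, exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        if corr_with(d2.values[np.ix_(p, p)]) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r_obs, (count + 1) / (n_perm + 1), n_perm, seed)


# ---------------------------------------------------------------------------
# Coefficient of variation + bootstrap
# ---------------------------------------------------------------------------

def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample sd (n−1 denominator) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 values")
    m = v.mean()
    if m <= 0:
        raise ValueError("CV requires a positive mean")
    return float(v.std(ddof=1) / m)


def _boot_cvs(v: np.ndarray, n_boot: int, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """CVs of n_boot with-replacement resamples; invalid resamples redrawn."""
    n = v.size
    idx = rng.integers(0, n, size=(n_boot, n))
    res = v[idx]
    cvs = res.std(axis=1, ddof=1) / res.mean(axis=1)
    bad = ~np.isfinite(cvs) | (res.mean(axis=1) <= 0) | (res.std(axis=1, ddof=1) == 0)
    n_redrawn = 0
    for _ in range(100):
        nb = int(bad.sum())
        if nb == 0:
            break
        n_redrawn += nb
        idx = rng.integers(0, n, size=(nb, n))
        res = v[idx]
        newcv = res.std(axis=1, ddof=1) / res.mean(axis=1)
        cvs[bad] = newcv
        newbad = ~np.isfinite(newcv) | (res.mean(axis=1) <= 0) | (res.std(axis=1, ddof=1) == 0)
        rows = np.nonzero(bad)[0]
        bad = np.zeros_like(bad)
        bad[rows[newbad]] = True
    return cvs, n_redrawn


def bootstrap_cv(
    values: Sequence[float],
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> CvResult:
    """Percentile bootstrap CI for the CV of a replicate set.

    Resamples of size n with replacement; degenerate resamples (non-positive
    mean or zero sd) are redrawn and counted, with a warning if they exceed
    1% of draws.  A constant input has CV 0 with a degenerate (0, 0) CI.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("bootstrap CV needs n >= 3")
    if v.std(ddof=1) == 0:
        return CvResult(0.0, 0.0, 0.0, n_boot, alpha, seed)
    point = cv(v)
    rng = np.random.default_rng(seed)
    cvs, n_redrawn = _boot_cvs(v, n_boot, rng)
    if n_redrawn > 0.01 * n_boot:
        warnings.warn(f"{n_redrawn} of {n_boot} bootstrap resamples were degenerate and redrawn")
    lo, hi = np.quantile(cvs, [alpha / 2, 1 - alpha / 2])
    return CvResult(point, float(lo), float(hi), n_boot, alpha, seed, n_redrawn=n_redrawn)


def bootstrap_cv_difference(
    a: Sequence[float],
    b: Sequence[float],
    n_boot: int = 10000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> CvResult:
    """Percentile bootstrap CI for CV(a) − CV(b), groups resampled independently.

    Reports whether zero is excluded at both the 95% and 90% levels, since
    a contrast can clear the looser bar without clearing the stricter one.
    """
    va = np.asarray(a, dtype=float)
    vb = np.asarray(b, dtype=float)
    if va.size < 3 or vb.size < 3:
        raise ValueError("bootstrap CV difference needs n >= 3 per group")
    point = cv(va) - cv(vb)
    # each group's resampling stream is keyed to its own data so the
    # statistic is exactly antisymmetric in (a, b) for a matched seed
    if seed is None:
        rng_a = np.random.default_rng()
        rng_b = np.random.default_rng()
    else:
        rng_a = np.random.default_rng([int(seed), zlib.crc32(va.tobytes())])
        rng_b = np.random.default_rng([int(seed), zlib.crc32(vb.tobytes())])
    cva, ra = _boot_cvs(va, n_boot, rng_a)
    cvb, rb = _boot_cvs(vb, n_boot, rng_b)
    diffs = cva - cvb
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    lo90, hi90 = np.quantile(diffs, [0.05, 0.95])
    return CvResult(
        point,
        float(lo),
        float(hi),
        n_boot,
        alpha,
        seed,
        excludes_zero_95=bool(lo > 0 or hi < 0),
        excludes_zero_90=bool(lo90 > 0 or hi90 < 0),
        n_redrawn=ra + rb,
    )
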