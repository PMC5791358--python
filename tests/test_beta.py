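"""Morisita-Horn, weighted UniFrac (vs the scikit-bio reference), PCoA."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from filterforensics import (
    DistanceMatrix,
    FeatureTable,
    distance_matrix,
    morisita_horn,
    pcoa,
    read_tree,
    weighted_unifrac,
)
from filterforensics.synthetic import simulate_tree


class TestMorisitaHorn:
    def test_identity_and_disjoint(self):
        assert morisita_horn([3, 1, 2], [3, 1, 2]) == pytest.approx(0.0)
        assert morisita_horn([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_hand_worked_value(self):
        # dx=0.5, dy=1, sum(xy)=1 -> similarity 2/((1.5)*2*1) = 2/3
        assert morisita_horn([1, 1], [1, 0]) == pytest.approx(1 / 3)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            morisita_horn([0, 0], [1, 2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**16),
        scale=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 20, size=8) + 1
        y = rng.integers(0, 20, size=8) + 1
        assert morisita_horn(x * scale, y) == pytest.approx(morisita_horn(x, y))


class TestWeightedUnifrac:
    def test_identical_communities_zero(self):
        tree = read_tree(newick="((A:1,B:2):0.5,C:1.5);")
        x = [3, 1, 6]
        for norm in (True, False):
            assert weighted_unifrac(x, x, tree, ["A", "B", "C"], norm) == pytest.approx(0.0)

    def test_fully_disjoint_two_unit_branches(self):
        tree = read_tree(newick="(A:1,B:1);")
        raw = weighted_unifrac([7, 0], [0, 4], tree, ["A", "B"], normalized=False)
        norm = weighted_unifrac([7, 0], [0, 4], tree, ["A", "B"], normalized=True)
        assert raw == pytest.approx(2.0)
        assert norm == pytest.approx(1.0)

    def test_missing_otu_with_reads_is_error(self):
        tree = read_tree(newick="(A:1,B:1);")
        with pytest.raises(ValueError, match="ZZ"):
            weighted_unifrac([1, 1, 1], [1, 1, 0], tree, ["A", "B", "ZZ"])

    def test_matches_scikit_bio_reference(self, rng):
        """Random 8-leaf tree, 5 random samples: agree with skbio to 1e-8."""
        from skbio import TreeNode
        from skbio.diversity.beta import weighted_unifrac as sk_wu

        otus = [f"L{i}" for i in range(8)]
        ptree = simulate_tree(otus, rng)
        sk_tree = TreeNode.read(io.StringIO(ptree.to_newick()))
        counts = rng.integers(0, 50, size=(5, 8))
        counts[counts.sum(axis=1) == 0, 0] = 1
        for i in range(5):
            for j in range(i + 1, 5):
                for norm in (True, False):
                    mine = weighted_unifrac(counts[i], counts[j], ptree, otus, norm)
                    ref = sk_wu(
                        counts[i], counts[j], taxa=otus, tree=sk_tree, normalized=norm
                    )
                    assert mine == pytest.approx(ref, abs=1e-8)

    def test_star_tree_equals_l1_distance(self, rng):
        """On a star tree with unit branches, raw UniFrac is the L1 distance
        between relative-abundance vectors."""
        n = 6
        newick = "(" + ",".join(f"T{i}:1" for i in range(n)) + ");"
        with pytest.warns(UserWarning, match="midpoint"):
            tree = read_tree(newick=newick)
        # midpoint rooting splits one unit branch; total path structure is kept
        x = rng.integers(1, 30, size=n).astype(float)
        y = rng.integers(1, 30, size=n).astype(float)
        l1 = np.abs(x / x.sum() - y / y.sum()).sum()
        otus = [f"T{i}" for i in range(n)]
        raw = weighted_unifrac(x, y, tree, otus, normalized=False)
        assert raw == pytest.approx(l1, abs=1e-10)

    def test_triangle_inequality_raw(self, rng):
        """Raw weighted UniFrac is a metric: check 1000 random triples."""
        from filterforensics.beta import _TreeIndex, _unifrac_from_proportions

        otus = [f"L{i}" for i in range(16)]
        ptree = simulate_tree(otus, rng)
        idx = _TreeIndex(ptree)
        counts = rng.integers(0, 40, size=(30, 16)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        table = FeatureTable([f"s{i}" for i in range(30)], otus, counts)
        P = idx.branch_proportions(table)
        L = idx.length
        for _ in range(1000):
            a, b, c = rng.choice(30, size=3, replace=False)
            dab = _unifrac_from_proportions(P[a], P[b], L, False)
            dbc = _unifrac_from_proportions(P[b], P[c], L, False)
            dac = _unifrac_from_proportions(P[a], P[c], L, False)
            assert dac <= dab + dbc + 1e-12


class TestDistanceMatrix:
    def test_duplicate_samples_zero_offdiagonal(self):
        t = FeatureTable(["a", "b"], ["x", "y"], np.array([[3.0, 1.0], [3.0, 1.0]]))
        dm = distance_matrix(t, "morisita_horn")
        assert dm.values[0, 1] == pytest.approx(0.0)

    def test_permutation_equivariance(self, rng):
        counts = rng.integers(1, 20, size=(5, 6)).astype(float)
        ids = [f"s{i}" for i in range(5)]
        t = FeatureTable(ids, [f"o{j}" for j in range(6)], counts)
        dm = distance_matrix(t, "morisita_horn")
        perm = [3, 0, 4, 1, 2]
        t2 = t.select_samples([ids[i] for i in perm])
        dm2 = distance_matrix(t2, "morisita_horn")
        np.testing.assert_allclose(dm2.values, dm.values[np.ix_(perm, perm)])

    def test_matrix_equals_looped_pairwise_calls(self, rng):
        otus = [f"L{i}" for i in range(7)]
        ptree = simulate_tree(otus, rng)
        counts = rng.integers(1, 30, size=(7, 7)).astype(float)
        t = FeatureTable([f"s{i}" for i in range(7)], otus, counts)
        dm = distance_matrix(t, "weighted_unifrac_normalized", ptree)
        for i in range(7):
            for j in range(i + 1, 7):
                ref = weighted_unifrac(counts[i], counts[j], ptree, otus, True)
                assert dm.values[i, j] == pytest.approx(ref, abs=1e-12)

    def test_unknown_metric(self):
        t = FeatureTable(["a"], ["x"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="metric"):
            distance_matrix(t, "bray_curtis")


class TestPcoa:
    def test_collinear_points_one_axis(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        D = squareform(pdist(pts))
        ordn = pcoa(DistanceMatrix(["a", "b", "c"], D))
        # PC1 recovers the spacing up to sign; second eigenvalue ~ 0
        pc1 = ordn.coordinates[:, 0]
        assert np.abs(np.diff(np.sort(pc1))) == pytest.approx([1.0, 1.0], abs=1e-9)
        assert abs(ordn.eigenvalues[1]) < 1e-9

    def test_all_zero_matrix(self):
        ordn = pcoa(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
        assert np.allclose(ordn.eigenvalues, 0)
        assert ordn.coordinates.shape[1] == 0

    def test_euclidean_exactness(self, rng):
        pts = rng.normal(size=(8, 2))
        D = squareform(pdist(pts))
        ordn = pcoa(DistanceMatrix([f"s{i}" for i in range(8)], D))
        rec = squareform(pdist(ordn.coordinates[:, :2]))
        np.testing.assert_allclose(rec, D, atol=1e-8)
        # Euclidean input: no meaningful negative eigenvalues
        assert ordn.eigenvalues.min() > -1e-9
        assert not ordn.negative_eigenvalue_correction

    def test_proportion_explained_matches_scikit_bio(self, rng):
        from skbio.stats.ordination import pcoa as sk_pcoa

        pts = rng.normal(size=(6, 3))
        D = squareform(pdist(pts))
        ordn = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], D))
        ref = sk_pcoa(D)
        np.testing.assert_allclose(
            ordn.proportion_explained[:3], ref.proportion_explained.values[:3], atol=1e-9
        )
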