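import itertools

import numpy as np
import pytest

from lowbiome import (
    OtuTable,
    PhyloTree,
    ValidationError,
    average_distance_matrices,
    bray_curtis,
    pcoa,
    permanova,
    weighted_unifrac,
)
from lowbiome.core import DistanceMatrix
from lowbiome.simulate import generate_tree
from conftest import random_table
from _oracles import (
    bray_curtis_oracle,
    pcoa_gram_oracle,
    permanova_exhaustive_p,
    permanova_oracle,
    weighted_unifrac_oracle,
)


class TestBrayCurtis:
    def test_identical_and_disjoint_columns(self):
        t = OtuTable(["a", "b"], ["x", "y", "z"], [[2, 2, 0], [3, 3, 5]])
        dm = bray_curtis(t)
        assert dm["x", "y"] == pytest.approx(0.0)
        t2 = OtuTable(["a", "b"], ["x", "y"], [[4, 0], [0, 7]])
        assert bray_curtis(t2)["x", "y"] == pytest.approx(1.0)

    def test_known_value(self):
        t = OtuTable(["a", "b", "c"], ["x", "y"], [[2, 0], [2, 2], [0, 2]])
        assert bray_curtis(t)["x", "y"] == pytest.approx(0.5)

    def test_all_zero_sample_rejected(self):
        t = OtuTable(["a"], ["x", "y"], [[1, 0]])
        with pytest.raises(ValidationError):
            bray_curtis(t)

    def test_joint_rescaling_invariance(self):
        """Invariant only when BOTH columns are scaled by the same factor."""
        rng = np.random.default_rng(0)
        t = random_table(rng, 5, 2, max_count=30)
        scaled = OtuTable(t.taxon_ids, t.sample_ids, t.counts * 3.0)
        assert bray_curtis(scaled)["s0", "s1"] == pytest.approx(
            bray_curtis(t)["s0", "s1"], abs=1e-12
        )
        uneven = OtuTable(t.taxon_ids, t.sample_ids, t.counts * np.array([1.0, 3.0]))
        assert bray_curtis(uneven)["s0", "s1"] != pytest.approx(
            bray_curtis(t)["s0", "s1"], abs=1e-9
        )


class TestWeightedUnifrac:
    def test_identical_profiles_are_zero(self):
        tree = PhyloTree.from_newick("((a:1,b:1):0.5,c:2):0;")
        t = OtuTable(["a", "b", "c"], ["x", "y"], [[2, 4], [1, 2], [3, 6]])
        for normalized in (False, True):
            assert weighted_unifrac(t, tree, normalized)["x", "y"] == pytest.approx(0.0)

    def test_two_leaf_tree_extremes(self):
        tree = PhyloTree.from_newick("(a:1,b:1):0;")
        t = OtuTable(["a", "b"], ["x", "y"], [[10, 0], [0, 10]])
        assert weighted_unifrac(t, tree, normalized=False)["x", "y"] == pytest.approx(2.0)
        assert weighted_unifrac(t, tree, normalized=True)["x", "y"] == pytest.approx(1.0)

    def test_star_tree_reduces_to_l1(self):
        tree = PhyloTree.from_newick("(a:1,b:1,c:1,d:1):0;")
        rng = np.random.default_rng(1)
        t = random_table(rng, 4, 2, max_count=20)
        t = OtuTable(["a", "b", "c", "d"], t.sample_ids, t.counts)
        p = t.relative_abundance()
        expected = np.abs(p[:, 0] - p[:, 1]).sum()
        assert weighted_unifrac(t, tree)["s0", "s1"] == pytest.approx(expected, abs=1e-12)

    def test_missing_taxon_named(self):
        tree = PhyloTree.from_newick("(a:1,b:1):0;")
        t = OtuTable(["a", "ghost"], ["x", "y"], [[1, 2], [3, 4]])
        with pytest.raises(ValidationError, match="ghost"):
            weighted_unifrac(t, tree)

    @pytest.mark.parametrize("normalized", [False, True])
    def test_matches_branch_enumeration_oracle(self, normalized):
        rng = np.random.default_rng(2)
        for trial in range(25):
            n_taxa = int(rng.integers(2, 6))
            taxa = [f"t{i}" for i in range(n_taxa)]
            tree = generate_tree(taxa, seed=int(rng.integers(1 << 30)))
            t = random_table(rng, n_taxa, 3, max_count=15)
            t = OtuTable(taxa, t.sample_ids, t.counts)
            dm = weighted_unifrac(t, tree, normalized=normalized)
            for a, b in itertools.combinations(range(3), 2):
                expected = weighted_unifrac_oracle(
                    t.counts[:, a], t.counts[:, b], taxa, tree.tree, normalized
                )
                assert dm.values[a, b] == pytest.approx(expected, abs=1e-10)
                if normalized:
                    assert dm.values[a, b] <= 1 + 1e-12


class TestAverageDistanceMatrices:
    def test_mean_and_identity(self):
        a = DistanceMatrix(["x", "y"], [[0, 0.2], [0.2, 0]])
        b = DistanceMatrix(["x", "y"], [[0, 0.4], [0.4, 0]])
        assert average_distance_matrices([a, b])["x", "y"] == pytest.approx(0.3)
        assert average_distance_matrices([a]).values.tolist() == a.values.tolist()

    def test_mismatched_samples_rejected(self):
        a = DistanceMatrix(["x", "y"], [[0, 0.2], [0.2, 0]])
        b = DistanceMatrix(["x", "z"], [[0, 0.2], [0.2, 0]])
        with pytest.raises(ValidationError):
            average_distance_matrices([a, b])


class TestPcoa:
    def test_collinear_points(self):
        dm = DistanceMatrix(["a", "b", "c"], [[0, 1, 2], [1, 0, 1], [2, 1, 0]])
        res = pcoa(dm)
        coords = res.coordinates[:, 0]
        assert abs(coords[0] - coords[2]) == pytest.approx(2.0, abs=1e-9)
        assert abs(coords[0] - coords[1]) == pytest.approx(1.0, abs=1e-9)
        assert res.coordinates.shape[1] == 1  # second axis carries nothing

    def test_euclidean_recovery(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], d))
        recovered = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None, :], axis=2
        )
        np.testing.assert_allclose(recovered, d, atol=1e-9)

    def test_duplicate_samples_coincide(self):
        d = np.array([[0, 0, 1.0], [0, 0, 1.0], [1.0, 1.0, 0]])
        res = pcoa(DistanceMatrix(["a", "a2", "b"], d))
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_eigenvalues_non_increasing_and_proportions(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(7, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(7)], d))
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)
        assert res.proportion_explained.sum() <= 1 + 1e-12

    def test_invalid_axes(self):
        dm = DistanceMatrix(["a", "b"], [[0, 1], [1, 0]])
        with pytest.raises(ValidationError):
            pcoa(dm, n_axes=0)


class TestPermanova:
    @staticmethod
    def _random_dm(rng, n):
        pts = rng.normal(size=(n, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        return DistanceMatrix([f"s{i}" for i in range(n)], d)

    def test_perfect_separation_r2_one(self):
        d = np.zeros((4, 4))
        d[:2, 2:] = 1.0
        d[2:, :2] = 1.0
        dm = DistanceMatrix(["a", "b", "c", "d"], d)
        res = permanova(dm, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}, permutations=99, seed=0)
        assert res.r2 == pytest.approx(1.0)

    def test_matches_direct_oracle(self):
        rng = np.random.default_rng(6)
        dm = self._random_dm(rng, 8)
        grouping = {s: ("g1" if i < 4 else "g2") for i, s in enumerate(dm.sample_ids)}
        res = permanova(dm, grouping, permutations=99, seed=1)
        f, r2 = permanova_oracle(dm.values, [grouping[s] for s in dm.sample_ids])
        assert res.pseudo_f == pytest.approx(f, abs=1e-9)
        assert res.r2 == pytest.approx(r2, abs=1e-9)

    def test_exhaustive_enumeration_p(self):
        """Sampled permutation p agrees with full enumeration on 6 samples."""
        rng = np.random.default_rng(9)
        dm = self._random_dm(rng, 6)
        grouping = {s: ("g1" if i < 3 else "g2") for i, s in enumerate(dm.sample_ids)}
        exact = float(permanova_exhaustive_p(dm.values, [grouping[s] for s in dm.sample_ids]))
        res = permanova(dm, grouping, permutations=9999, seed=2)
        assert res.p_value == pytest.approx(exact, abs=0.02)

    def test_r2_invariant_under_global_rescaling(self):
        rng = np.random.default_rng(10)
        dm = self._random_dm(rng, 8)
        grouping = {s: ("g1" if i % 2 else "g2") for i, s in enumerate(dm.sample_ids)}
        r2a = permanova(dm, grouping, permutations=9, seed=0).r2
        dm2 = DistanceMatrix(dm.sample_ids, dm.values * 7.5)
        r2b = permanova(dm2, grouping, permutations=9, seed=0).r2
        assert r2a == pytest.approx(r2b, abs=1e-12)

    def test_unlabeled_sample_and_single_group_rejected(self):
        dm = DistanceMatrix(["a", "b"], [[0, 1], [1, 0]])
        with pytest.raises(ValidationError):
            permanova(dm, {"a": "g"}, permutations=9, seed=0)
        with pytest.raises(ValidationError):
            permanova(dm, {"a": "g", "b": "g"}, permutations=9, seed=0)

    def test_p_lower_bound(self):
        rng = np.random.default_rng(11)
        dm = self._random_dm(rng, 6)
        grouping = {s: ("g1" if i < 3 else "g2") for i, s in enumerate(dm.sample_ids)}
        res = permanova(dm, grouping, permutations=99, seed=3)
        assert res.p_value >= 1 / 100


class TestSkbioCrossCheck:
    """Dual-route check of the in-package metrics against scikit-bio."""

    def test_weighted_unifrac_against_skbio(self):
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(12)
        taxa = [f"t{i}" for i in range(5)]
        tree = generate_tree(taxa, seed=99)
        t = random_table(rng, 5, 4, max_count=30)
        t = OtuTable(taxa, t.sample_ids, t.counts)
        # skbio computes raw weighted UniFrac on counts
        sk = beta_diversity(
            "weighted_unifrac", t.counts.T.astype(int), ids=t.sample_ids,
            tree=tree.tree, taxa=taxa,
        )
        mine = weighted_unifrac(t, tree, normalized=False)
        np.testing.assert_allclose(mine.values, sk.data, atol=1e-9)

    def test_permanova_against_skbio(self):
        import skbio

        rng = np.random.default_rng(13)
        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(10)]
        labels = ["g1"] * 5 + ["g2"] * 5
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d, ids), grouping=labels, permutations=0
        )
        res = permanova(DistanceMatrix(ids, d), dict(zip(ids, labels)), permutations=9, seed=0)
        assert res.pseudo_f == pytest.approx(sk["test statistic"], abs=1e-9)
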