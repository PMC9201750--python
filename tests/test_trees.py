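"""Tree geometry, covariance construction and trait simulation."""

import numpy as np
import pandas as pd
import pytest

import pcmkit as pk
from pcmkit.trees import TreeError

from conftest import random_tree


def edge_enumeration_covariance(tree: pk.PhyloTree) -> np.ndarray:
    """Brute-force BM covariance: every edge adds its length to all tip
    pairs (including self-pairs) descending from it."""
    n = tree.n_tips
    C = np.zeros((n, n))
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        tips = tree.clade_tips(v)
        C[np.ix_(tips, tips)] += tree.length[v]
    return C


class TestParsing:
    def test_simple_newick(self, three_tip):
        assert sorted(three_tip.tip_labels) == ["A", "B", "C"]
        assert three_tip.height == pytest.approx(2.0)
        assert three_tip.is_ultrametric()

    def test_newick_roundtrip(self):
        rng = np.random.default_rng(5)
        t = random_tree(9, rng)
        t2 = pk.read_tree(t.to_newick())
        assert sorted(t2.tip_labels) == sorted(t.tip_labels)
        C1 = pk.bm_covariance(t).reorder(sorted(t.tip_labels))
        C2 = pk.bm_covariance(t2).reorder(sorted(t.tip_labels))
        np.testing.assert_allclose(C1.values, C2.values, atol=1e-9)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeError):
            pk.read_tree("((A:1,A:1):1,C:2);")

    def test_read_tree_set_nexus_and_subsample(self, tmp_path, tree26):
        ts = pk.pseudo_posterior(tree26, 12, seed=0)
        nex = tmp_path / "trees.nex"
        ts.write(nex, schema="nexus")
        full = pk.read_tree_set(nex, schema="nexus")
        assert len(full) == 12
        assert set(full.tip_labels) == set(tree26.tip_labels)
        sub1 = pk.read_tree_set(nex, schema="nexus", max_trees=5, seed=3)
        sub2 = pk.read_tree_set(nex, schema="nexus", max_trees=5, seed=3)
        assert len(sub1) == 5
        assert [t.to_newick() for t in sub1] == [t.to_newick() for t in sub2]

    def test_inconsistent_tip_sets_rejected(self):
        a = pk.read_tree("((A:1,B:1):1,C:2);")
        b = pk.read_tree("((A:1,B:1):1,D:2);")
        with pytest.raises(TreeError):
            pk.TreeSet(trees=[a, b])


class TestBMCovariance:
    def test_three_tip_values(self, three_tip):
        C = pk.bm_covariance(three_tip).reorder(["A", "B", "C"])
        np.testing.assert_allclose(C.values, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree(self):
        star = pk.read_tree("(A:3,B:3,C:3,D:3);")
        C = pk.bm_covariance(star)
        np.testing.assert_allclose(C.values, 3.0 * np.eye(4))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_edge_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree(8, rng)
        np.testing.assert_allclose(
            pk.bm_covariance(t).values, edge_enumeration_covariance(t), atol=1e-10
        )


class TestOUCovariance:
    def test_bm_limit(self, three_tip):
        V = pk.ou_covariance(three_tip, 1e-8).values
        C = pk.bm_covariance(three_tip).values
        np.testing.assert_allclose(V, C, rtol=1e-5)

    def test_two_tip_closed_form(self, two_tip):
        V = pk.ou_covariance(two_tip, 1.0).values
        assert V[0, 0] == pytest.approx((1 - np.exp(-2)) / 2)
        # fixed-root form: zero shared time from the root means zero covariance
        assert V[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_strong_pull_decorrelates(self, two_tip):
        V = pk.ou_covariance(two_tip, 50.0).values
        assert V[0, 1] / V[0, 0] < 1e-10

    def test_invalid_alpha(self, two_tip):
        with pytest.raises(ValueError):
            pk.ou_covariance(two_tip, 0.0)


class TestEBTransform:
    def test_identity_at_zero(self, three_tip):
        t = pk.eb_transform(three_tip, 0.0)
        np.testing.assert_allclose(t.length, three_tip.length)

    def test_height_closed_form(self, two_tip):
        t = pk.eb_transform(two_tip, -1.0)
        assert t.height == pytest.approx(1 - np.exp(-1))

    def test_telescoping_path_sum(self):
        # the same root-to-tip span, subdivided differently, transforms to
        # the same total length (exp(rT) - 1)/r
        chain = pk.read_tree("((A:0.25,B:0.25):0.75,(C:0.6,D:0.6):0.4);")
        r = -1.3
        t = pk.eb_transform(chain, r)
        expected = (np.exp(r * 1.0) - 1) / r
        for tip in range(t.n_tips):
            total, v = 0.0, tip
            while v != t.root:
                total += t.length[v]
                v = t.parent[v]
            assert total == pytest.approx(expected)

    def test_bm_limit_covariance(self, three_tip):
        V = pk.bm_covariance(pk.eb_transform(three_tip, -1e-8)).values
        np.testing.assert_allclose(V, pk.bm_covariance(three_tip).values, rtol=1e-5)


class TestCovarianceProperties:
    @pytest.mark.parametrize("seed", range(6))
    def test_symmetry_and_cholesky(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = random_tree(10, rng)
        for V in (
            pk.bm_covariance(t).values,
            pk.ou_covariance(t, 0.7).values,
            pk.bm_covariance(pk.eb_transform(t, -0.5)).values,
        ):
            np.testing.assert_allclose(V, V.T, atol=1e-12)
            np.linalg.cholesky(V + 1e-10 * np.eye(len(V)))


class TestSimulateTraits:
    def test_zero_rate_returns_root_state(self, three_tip):
        X = pk.simulate_traits(three_tip, "BM", {"sigma2": 0.0}, ntraits=2,
                               root_state=3.5, seed=0)
        np.testing.assert_allclose(X.to_numpy(), 3.5)

    def test_seeded_reproducibility(self, three_tip):
        a = pk.simulate_traits(three_tip, "OU", {"sigma2": 1.0, "alpha": 1.0}, seed=9)
        b = pk.simulate_traits(three_tip, "OU", {"sigma2": 1.0, "alpha": 1.0}, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_bm_empirical_covariance(self, three_tip):
        reps = 2000
        rng = np.random.default_rng(2)
        sims = np.stack([
            pk.simulate_traits(three_tip, "BM", {"sigma2": 1.0}, seed=rng)
            .loc[["A", "B", "C"]].to_numpy().ravel()
            for _ in range(reps)
        ])
        emp = np.cov(sims.T)
        C = pk.bm_covariance(three_tip).reorder(["A", "B", "C"]).values
        # elementwise MC standard error of a covariance entry ~ sqrt(2) V_ii / sqrt(n)
        se = 3 * np.sqrt((np.outer(np.diag(C), np.diag(C)) + C**2) / reps)
        assert np.all(np.abs(emp - C) < se + 1e-9)

    def test_ou_stationary_variance(self):
        # long two-tip tree: tip variance approaches sigma^2 / (2 alpha)
        t = pk.read_tree("(A:50,B:50);")
        reps = 2000
        rng = np.random.default_rng(3)
        vals = np.array([
            pk.simulate_traits(t, "OU", {"sigma2": 1.0, "alpha": 1.0}, seed=rng)
            .iloc[0, 0] for _ in range(reps)
        ])
        target = 0.5
        assert vals.var() == pytest.approx(target, abs=3 * target * np.sqrt(2 / reps))

    def test_sample_mean_near_root_state(self, three_tip):
        reps = 800
        rng = np.random.default_rng(4)
        m = np.mean([
            pk.simulate_traits(three_tip, "BM", {"sigma2": 1.0},
                               root_state=1.0, seed=rng).to_numpy().mean()
            for _ in range(reps)
        ])
        assert abs(m - 1.0) < 3 * np.sqrt(2.0 / reps)

    def test_non_psd_rate_matrix_rejected(self, three_tip):
        with pytest.raises(ValueError):
            pk.simulate_traits(three_tip, "BM", {"R": [[1.0, 2.0], [2.0, 1.0]]},
                               ntraits=2)
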