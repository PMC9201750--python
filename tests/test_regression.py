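"""Phylogenetic GLS, ridge-penalized multivariate GLS, Wilks MANOVA and
GLS ANOVA."""

import numpy as np
import pandas as pd
import pytest

import pcmkit as pk
from pcmkit.regression import _loocv_criterion, _wilks

from conftest import random_tree


def star_tree(n):
    return pk.read_tree("(" + ",".join(f"s{i}:1" for i in range(n)) + ");")


class TestPGLS:
    @pytest.mark.parametrize("seed", range(10))
    def test_identity_covariance_equals_ols(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        tree = star_tree(n)
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)},
                         index=tree.tip_labels)
        y = pd.Series(rng.normal(size=n), index=tree.tip_labels)
        fit = pk.pgls(tree, y, X, "BM")
        A = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.lstsq(A, y.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients["y"].to_numpy(), beta,
                                   atol=1e-10)

    def test_noiseless_line_exact_under_any_structure(self, tree26):
        rng = np.random.default_rng(1)
        x = pd.DataFrame({"x": rng.normal(size=26)}, index=tree26.tip_labels)
        y = pd.Series(2.0 + 3.0 * x["x"], index=tree26.tip_labels)
        for model, fp in (("BM", None), ("OU", {"alpha": 0.5}), ("EB", {"g": 0.5})):
            fit = pk.pgls(tree26, y, x, model, fp)
            np.testing.assert_allclose(fit.coefficients["y"].to_numpy(),
                                       [2.0, 3.0], atol=1e-8)

    def test_coefficient_ci_coverage_under_bm(self, tree26):
        # nominal 95% CI for the slope should cover the truth ~95% of the time
        rng = np.random.default_rng(2)
        from scipy import stats as st

        x = pd.DataFrame({"x": rng.normal(size=26)}, index=tree26.tip_labels)
        cover = 0
        reps = 300
        tcrit = st.t.ppf(0.975, 26 - 2)
        for rep in range(reps):
            noise = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0},
                                       seed=3000 + rep).iloc[:, 0]
            y = 1.0 + 0.5 * x["x"] + noise
            fit = pk.pgls(tree26, y, x, "BM")
            row = fit.test_stats.loc["x"]
            cover += abs(row["coef"] - 0.5) <= tcrit * row["se"]
        assert cover / reps == pytest.approx(0.95, abs=0.04)

    def test_rank_deficient_design_errors(self, tree26):
        X = pd.DataFrame({"a": np.ones(26), "b": np.ones(26)},
                         index=tree26.tip_labels)
        y = pd.Series(np.arange(26.0), index=tree26.tip_labels)
        with pytest.raises(ValueError):
            pk.pgls(tree26, y, X)


class TestMVGLS:
    def test_no_shrinkage_equals_unpenalized_gls(self, tree26):
        Y = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, ntraits=3, seed=0)
        x = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, seed=1)
        a = pk.mvgls(tree26, Y, x, lam=0.0, method="LOOCV")
        b = pk.mvgls(tree26, Y, x, penalty="none", method="LL")
        np.testing.assert_allclose(a.coefficients.to_numpy(),
                                   b.coefficients.to_numpy(), atol=1e-10)
        np.testing.assert_allclose(a.Sigma, b.Sigma, atol=1e-10)

    def test_full_shrinkage_is_scaled_identity(self, tree26):
        Y = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, ntraits=4, seed=2)
        x = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, seed=3)
        fit = pk.mvgls(tree26, Y, x, lam=1.0)
        np.testing.assert_allclose(
            fit.Sigma, np.trace(fit.Sigma) / 4 * np.eye(4), atol=1e-12)

    def test_loocv_matches_direct_leave_one_out(self):
        rng = np.random.default_rng(4)
        E = rng.normal(size=(10, 3))
        for lam in (0.1, 0.5, 0.9):
            n, p = E.shape
            S = (E.T @ E) / n
            direct = 0.0
            for i in range(n):
                e = E[i]
                S_i = (n * S - np.outer(e, e)) / (n - 1)
                Sig = (1 - lam) * S_i + lam * (np.trace(S_i) / p) * np.eye(p)
                _, ld = np.linalg.slogdet(Sig)
                direct += -0.5 * (p * np.log(2 * np.pi) + ld
                                  + e @ np.linalg.solve(Sig, e))
            assert _loocv_criterion(E, lam) == pytest.approx(direct)

    def test_shrinkage_beats_sample_covariance(self, tree26):
        # ridge target improves Frobenius error to the true Sigma for most
        # replicates in a p=5, n=26 regime
        rng = np.random.default_rng(5)
        p = 5
        A = rng.normal(size=(p, p))
        Sigma_true = A @ A.T / p + 0.5 * np.eye(p)
        wins = 0
        reps = 60
        for rep in range(reps):
            Y = pk.simulate_traits(tree26, "BM", {"R": Sigma_true}, ntraits=p,
                                   seed=700 + rep)
            fit = pk.mvgls(tree26, Y, None, method="LOOCV")
            raw = pk.mvgls(tree26, Y, None, lam=0.0, method="LOOCV")
            # whitened residuals estimate the rate matrix directly
            err_ridge = np.linalg.norm(fit.Sigma - Sigma_true)
            err_raw = np.linalg.norm(raw.Sigma - Sigma_true)
            wins += err_ridge <= err_raw
        assert wins / reps >= 0.6

    def test_p_exceeding_n_requires_ridge(self):
        tree = star_tree(5)
        rng = np.random.default_rng(6)
        Y = pd.DataFrame(rng.normal(size=(5, 6)), index=tree.tip_labels)
        with pytest.raises(ValueError, match="ridge"):
            pk.mvgls(tree, Y, None, penalty="none")


class TestWilksMANOVA:
    def test_wilks_in_unit_interval_and_recombination_invariance(self, tree26):
        rng = np.random.default_rng(7)
        Y, _ = np.linalg.qr(rng.normal(size=(26, 4)))
        Xf = np.column_stack([np.ones(26), rng.normal(size=26)])
        Qf, _ = np.linalg.qr(Xf)
        Qr, _ = np.linalg.qr(np.ones((26, 1)))
        lam = _wilks(Y, Qf, Qr)
        assert 0 < lam <= 1
        T = rng.normal(size=(4, 4))  # nonsingular recombination of responses
        lam2 = _wilks(Y @ T, Qf, Qr)
        assert lam2 == pytest.approx(lam, rel=1e-9)

    def test_huge_separation_reaches_minimal_p(self, tree26):
        rng = np.random.default_rng(8)
        g = pd.Series(["a"] * 13 + ["b"] * 13, index=tree26.tip_labels)
        Y = pd.DataFrame(rng.normal(scale=0.01, size=(26, 3)),
                         index=tree26.tip_labels)
        Y.loc[g == "b"] += 100.0
        res = pk.manova_permutation(tree26, Y, g, n_perm=999, seed=9)
        assert res.p_value == pytest.approx(1.0 / 1000.0)

    def test_single_level_errors(self, tree26):
        Y = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, ntraits=2, seed=10)
        g = pd.Series(["a"] * 26, index=tree26.tip_labels)
        with pytest.raises(ValueError):
            pk.manova_permutation(tree26, Y, g, n_perm=99)

    def test_null_pvalues_roughly_uniform(self, tree26):
        # matched-tree null: permutation p-values should be near-uniform
        from scipy import stats as st

        g = pd.Series(["a"] * 13 + ["b"] * 13, index=tree26.tip_labels)
        ps = []
        for rep in range(100):
            Y = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, ntraits=3,
                                   seed=1100 + rep)
            res = pk.manova_permutation(tree26, Y, g, n_perm=199,
                                        seed=1200 + rep)
            ps.append(res.p_value)
        assert st.kstest(ps, "uniform").pvalue > 0.01


class TestANOVA:
    def test_identity_covariance_matches_hand_anova(self):
        tree = star_tree(6)
        g = pd.Series(["a", "a", "a", "b", "b", "b"], index=tree.tip_labels)
        y = pd.Series([1.0, 2.0, 3.0, 5.0, 6.0, 7.0], index=tree.tip_labels)
        # hand sums of squares: group means 2 and 6, grand mean 4
        ss_between = 3 * (2 - 4) ** 2 + 3 * (6 - 4) ** 2   # 24
        ss_within = sum((v - 2) ** 2 for v in (1, 2, 3)) + \
            sum((v - 6) ** 2 for v in (5, 6, 7))            # 4
        F_hand = (ss_between / 1) / (ss_within / 4)
        res = pk.anova_gls(tree, y, g, "BM")
        assert res.statistic == pytest.approx(F_hand)
        assert res.df == (1, 4)

    def test_massive_separation_tiny_p(self, tree26):
        g = pd.Series(["a"] * 13 + ["b"] * 13, index=tree26.tip_labels)
        y = pd.Series(np.r_[np.zeros(13), np.full(13, 50.0)],
                      index=tree26.tip_labels)
        y += np.random.default_rng(11).normal(scale=0.01, size=26)
        res = pk.anova_gls(tree26, y, g, "BM")
        assert res.p_value < 1e-6


class TestSelectCorrModel:
    def test_single_tree_majority_is_its_best(self, tree26):
        X = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, seed=12)
        Y = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, ntraits=3, seed=13)
        m, votes = pk.select_corr_model([tree26], Y, X)
        assert sum(votes.values()) == 1
        assert votes[m] == 1

    def test_strong_ou_residuals_select_ou(self, tree26):
        ts = pk.TreeSet([tree26.copy() for _ in range(5)])
        alpha = 5.0 / tree26.height
        Y = pk.simulate_traits(tree26, "OU", {"sigma2": 1.0, "alpha": alpha},
                               ntraits=3, seed=14)
        X = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, seed=15)
        m, votes = pk.select_corr_model(list(ts), Y, X)
        assert m == "OU"

    def test_vote_tally_consistency(self, posterior26, tree26):
        Y = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, ntraits=2, seed=16)
        X = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, seed=17)
        m, votes = pk.select_corr_model(list(posterior26), Y, X)
        assert sum(votes.values()) == len(posterior26)
        assert votes[m] == max(votes.values())


class TestCorrelateOverPosterior:
    def test_identical_trees_degenerate_summaries(self, tree26):
        ts = pk.TreeSet([tree26.copy() for _ in range(4)])
        Y = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, ntraits=3, seed=18)
        X = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, seed=19)
        X.columns = ["env"]
        summ = pk.correlate_over_posterior(ts, Y, X, corr_model="BM",
                                           n_perm=99, seed=20)
        row = summ.table.loc["env"]
        assert row["proportion_significant"] in (0.0, 1.0)
        assert row["stat_hi"] - row["stat_lo"] == pytest.approx(0.0, abs=1e-12)

    def test_summary_recomputes_from_records(self, posterior26, tree26):
        y = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, seed=21)
        X = pk.simulate_traits(tree26, "BM", {"sigma2": 1.0}, ntraits=2, seed=22)
        X.columns = ["e1", "e2"]
        summ = pk.correlate_over_posterior(posterior26, y, X, corr_model="BM",
                                           seed=23)
        sub = summ.records[summ.records["predictor"] == "e1"]
        assert summ.table.loc["e1", "proportion_significant"] == pytest.approx(
            (sub["p"] <= 0.05).mean())
        assert summ.table.loc["e1", "stat_mean"] == pytest.approx(sub["stat"].mean())

    def test_planted_effect_recovered(self, tree26):
        # strong planted shape~environment effect on matched trees
        ts = pk.TreeSet([tree26.copy() for _ in range(5)])
        rng = np.random.default_rng(24)
        env = pk.simulate_traits(tree26, "BM", {"sigma2": 0.5}, seed=25)
        env.columns = ["veg"]
        noise = pk.simulate_traits(tree26, "BM", {"sigma2": 0.02}, ntraits=5,
                                   seed=26)
        Y = noise.add(0.10 * env["veg"], axis=0)
        summ = pk.correlate_over_posterior(ts, Y, env, corr_model="BM",
                                           n_perm=199, seed=27)
        assert summ.table.loc["veg", "proportion_significant"] >= 0.8
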