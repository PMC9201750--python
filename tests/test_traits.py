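"""Trait-table preparation: transforms, imputation, averaging, PCA."""

import numpy as np
import pandas as pd
import pytest

import pcmkit as pk
from pcmkit.traits import TraitError, TraitMatrix


@pytest.fixture
def env_table():
    return TraitMatrix(pd.DataFrame(
        {"seasonality": [400.0, 900.0], "min_temp": [-5.0, 2.0],
         "dry_prec": [0.0, 12.0], "ndvi": [0.3, 0.6]},
        index=["sp1", "sp2"],
    ))


class TestEnvLogTransform:
    def test_transform_rules(self, env_table):
        out = pk.env_log_transform(env_table, {
            "seasonality": "divide100_log",
            "min_temp": ("offset_log", 100),
            "dry_prec": "offset_log(1)",
            "ndvi": "plain_log",
        })
        assert out.data.loc["sp1", "seasonality"] == pytest.approx(np.log(4.0))
        assert out.data.loc["sp1", "min_temp"] == pytest.approx(np.log(95.0))
        assert out.data.loc["sp1", "dry_prec"] == pytest.approx(0.0)
        assert out.data.loc["sp2", "ndvi"] == pytest.approx(np.log(0.6))
        assert len(out.transform_log) == 4

    def test_nonpositive_after_adjustment_errors(self, env_table):
        with pytest.raises(TraitError, match="min_temp"):
            pk.env_log_transform(env_table, {"min_temp": "plain_log"})

    def test_transform_invertible_from_log(self, env_table):
        out = pk.env_log_transform(env_table, {"seasonality": "divide100_log"})
        rec = np.exp(out.data["seasonality"]) * 100.0
        np.testing.assert_allclose(rec, env_table.data["seasonality"])


class TestSizeCorrect:
    def test_log_ratio_values(self):
        tm = TraitMatrix(pd.DataFrame({"SVL": [50.0], "AG": [10.0]}, index=["s"]))
        out = pk.size_correct(tm)
        assert out.data.loc["s", "AG"] == pytest.approx(np.log(0.2))
        assert out.data.loc["s", "SVL"] == pytest.approx(np.log(50.0))

    def test_isometry_null(self):
        svl = np.array([40.0, 55.0, 70.0])
        tm = TraitMatrix(pd.DataFrame({"SVL": svl, "AG": 0.3 * svl, "AL": 0.7 * svl},
                                      index=["a", "b", "c"]))
        out = pk.size_correct(tm)
        assert out.data["AG"].std() == pytest.approx(0.0, abs=1e-12)
        assert out.data["AL"].std() == pytest.approx(0.0, abs=1e-12)

    def test_equals_log_difference(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(5, 80, size=(6, 3)),
                          columns=["SVL", "AG", "PW"],
                          index=[f"s{i}" for i in range(6)])
        out = pk.size_correct(TraitMatrix(df))
        np.testing.assert_allclose(out.data["AG"], np.log(df["AG"]) - np.log(df["SVL"]))

    def test_nonpositive_measurement_errors(self):
        tm = TraitMatrix(pd.DataFrame({"SVL": [50.0], "AG": [0.0]}, index=["s"]))
        with pytest.raises(TraitError):
            pk.size_correct(tm)


class TestImputeByRegression:
    def test_noiseless_recovery(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 7.0])
        y = 2.0 * x
        y[4] = np.nan
        tm = TraitMatrix(pd.DataFrame({"x": x, "y": y},
                                      index=[f"s{i}" for i in range(5)]))
        out = pk.impute_by_regression(tm, "y", "x")
        assert out.data.loc["s4", "y"] == pytest.approx(14.0)
        assert out.imputed["y"] == ["s4"]

    def test_no_missing_is_identity(self):
        tm = TraitMatrix(pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 4.0, 6.0]},
                                      index=["a", "b", "c"]))
        out = pk.impute_by_regression(tm, "y", "x")
        pd.testing.assert_frame_equal(out.data, tm.data)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = 1.5 + 0.8 * x + rng.normal(scale=0.3, size=12)
        y[5] = np.nan
        tm = TraitMatrix(pd.DataFrame({"x": x, "y": y},
                                      index=[f"s{i}" for i in range(12)]))
        out = pk.impute_by_regression(tm, "y", "x")
        mask = ~np.isnan(y)
        A = np.column_stack([np.ones(mask.sum()), x[mask]])
        beta = np.linalg.solve(A.T @ A, A.T @ y[mask])
        assert out.data.loc["s5", "y"] == pytest.approx(beta[0] + beta[1] * x[5])

    def test_too_few_pairs_errors(self):
        tm = TraitMatrix(pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, np.nan, np.nan]},
                                      index=["a", "b", "c"]))
        with pytest.raises(TraitError):
            pk.impute_by_regression(tm, "y", "x")


class TestSpeciesMeans:
    def test_grouped_means_match_oracle(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "species": rng.choice(["a", "b", "c"], size=30),
            "v1": rng.normal(size=30), "v2": rng.normal(size=30),
        }).set_index("species")
        out = pk.species_means(TraitMatrix(df))
        for sp in ["a", "b", "c"]:
            np.testing.assert_allclose(
                out.data.loc[sp], df.loc[[sp]].mean(), atol=1e-12)

    def test_singletons_and_pairs(self):
        df = pd.DataFrame({"v": [1.0, 3.0, 5.0]}, index=["a", "a", "b"])
        out = pk.species_means(TraitMatrix(df))
        assert out.data.loc["a", "v"] == pytest.approx(2.0)
        assert out.data.loc["b", "v"] == pytest.approx(5.0)


class TestPCAReduce:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        tm = TraitMatrix(pd.DataFrame({"a": x, "b": 2 * x + 1},
                                      index=[f"s{i}" for i in range(20)]))
        res = pk.pca_reduce(tm, 0.99)
        assert res.n_retained == 1
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_independent_variables_spread(self):
        rng = np.random.default_rng(4)
        tm = TraitMatrix(pd.DataFrame(rng.normal(size=(10000, 3)),
                                      columns=["a", "b", "c"]))
        res = pk.pca_reduce(tm, 0.99)
        assert res.n_retained == 3
        assert np.all(np.abs(res.variance_fraction - 1 / 3) < 0.03)

    def test_loadings_orthonormal_and_reconstruction(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 4)) @ rng.normal(size=(4, 4))
        tm = TraitMatrix(pd.DataFrame(X, columns=list("abcd")))
        res = pk.pca_reduce(tm, 1.0)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-10)
        assert res.variance_fraction.sum() == pytest.approx(1.0, abs=1e-12)
        # scores projected back through all loadings reproduce the scaled data
        assert res.n_retained == 4
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        np.testing.assert_allclose(res.scores.to_numpy() @ L.T, Z, atol=1e-10)

    def test_sign_convention(self):
        rng = np.random.default_rng(6)
        tm = TraitMatrix(pd.DataFrame(rng.normal(size=(30, 5))))
        L = pk.pca_reduce(tm, 1.0).loadings.to_numpy()
        for k in range(L.shape[1]):
            col = L[:, k]
            assert col[np.abs(col).argmax()] > 0

    def test_constant_column_errors(self):
        tm = TraitMatrix(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]}))
        with pytest.raises(TraitError):
            pk.pca_reduce(tm)
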