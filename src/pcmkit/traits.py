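"""Trait-table preparation: log transforms, size correction, imputation,
species averaging and PCA reduction.

The conventions mirror common practice for morphometric + environmental
comparative datasets: everything is analysed on a natural-log scale, linear
body measurements are expressed as log-ratios against snout-vent length
(SVL), specimens are averaged to species after transformation, and blocks of
correlated environmental variables are reduced to the principal-component
axes carrying a target share (default 99%) of the variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitMatrix",
    "PCAResult",
    "read_trait_table",
    "env_log_transform",
    "size_correct",
    "impute_by_regression",
    "species_means",
    "pca_reduce",
]


class TraitError(ValueError):
    """Raised for invalid trait-table input."""


@dataclass
class TraitMatrix:
    """Species-by-variable numeric table with a record of applied transforms."""

    data: pd.DataFrame
    transform_log: list[dict] = field(default_factory=list)
    imputed: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def align_to(self, labels: list[str]) -> "TraitMatrix":
        missing = set(labels) - set(self.data.index)
        if missing:
            raise TraitError(f"species missing from trait table: {sorted(missing)}")
        return TraitMatrix(self.data.loc[list(labels)], list(self.transform_log), dict(self.imputed))

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(self.data.copy(), list(self.transform_log), dict(self.imputed))


@dataclass
class PCAResult:
    scores: pd.DataFrame          # species x retained axes
    loadings: pd.DataFrame        # variables x all axes
    variance_fraction: np.ndarray  # per-axis, sums to 1
    n_retained: int

    @property
    def retained_scores(self) -> pd.DataFrame:
        return self.scores


def read_trait_table(path, species_col: str = "species", sep: str = ",") -> TraitMatrix:
    """Read a CSV/TSV table with one row per specimen or species."""
    df = pd.read_csv(path, sep=sep)
    if species_col not in df.columns:
        raise TraitError(f"missing species column {species_col!r}")
    df[species_col] = df[species_col].astype(str).str.strip().str.replace(" ", "_")
    df = df.set_index(species_col)
    return TraitMatrix(df)


# ---------------------------------------------------------------------------
# Transforms

def _as_matrix(table) -> TraitMatrix:
    return table if isinstance(table, TraitMatrix) else TraitMatrix(table)


def env_log_transform(table, rules: dict[str, object]) -> TraitMatrix:
    """Natural-log transform environmental variables after a pre-adjustment.

    ``rules`` maps variable names to one of:

    * ``"plain_log"`` — ln(x)
    * ``"divide100_log"`` — ln(x / 100), for percentage-scaled variables
      such as temperature seasonality
    * ``("offset_log", c)`` or ``"offset_log(c)"`` — ln(x + c), for
      variables that can be zero or negative (e.g. minimum temperature with
      c = 100, driest-month precipitation with c = 1)
    """
    tm = _as_matrix(table).copy()
    for var, rule in rules.items():
        if var not in tm.data.columns:
            raise TraitError(f"no such variable {var!r}")
        x = tm.data[var].astype(float)
        if isinstance(rule, str) and rule.startswith("offset_log(") and rule.endswith(")"):
            rule = ("offset_log", float(rule[len("offset_log("):-1]))
        if rule == "plain_log":
            adj = x
        elif rule == "divide100_log":
            adj = x / 100.0
        elif isinstance(rule, (tuple, list)) and rule[0] == "offset_log":
            adj = x + float(rule[1])
        else:
            raise TraitError(f"unknown transform rule {rule!r} for {var!r}")
        bad = adj <= 0
        if bad.any():
            where = tm.data.index[bad].tolist()
            raise TraitError(
                f"non-positive value for {var!r} after adjustment at {where}"
            )
        tm.data[var] = np.log(adj)
        tm.transform_log.append({"variable": var, "rule": rule})
    return tm


def size_correct(morph, size_var: str = "SVL", shape_vars: list[str] | None = None) -> TraitMatrix:
    """Express shape variables as log-ratios against body size.

    Each shape variable x becomes ``ln(x / SVL)`` (equivalently
    ``ln x - ln SVL``), which applies the log transform and the size ratio in
    one step; SVL itself is retained as ``ln(SVL)`` body size.
    """
    tm = _as_matrix(morph).copy()
    if size_var not in tm.data.columns:
        raise TraitError(f"missing size variable {size_var!r}")
    if shape_vars is None:
        shape_vars = [c for c in tm.data.columns if c != size_var]
    if not shape_vars:
        raise TraitError("no shape variables to correct")
    cols = [size_var] + list(shape_vars)
    vals = tm.data[cols].astype(float)
    if (vals <= 0).any().any():
        bad = vals.index[(vals <= 0).any(axis=1)].tolist()
        raise TraitError(f"non-positive measurement at {bad}")
    out = pd.DataFrame(index=tm.data.index)
    out[size_var] = np.log(vals[size_var])
    for v in shape_vars:
        out[v] = np.log(vals[v]) - np.log(vals[size_var])
    tm2 = TraitMatrix(out, list(tm.transform_log), dict(tm.imputed))
    tm2.transform_log.append({"rule": "log_ratio_size_correct", "size_var": size_var,
                              "shape_vars": list(shape_vars)})
    return tm2


def impute_by_regression(table, target_var: str, predictor_var: str) -> TraitMatrix:
    """Fill missing values of one variable by OLS on a complete predictor.

    Fits target ~ predictor over rows where both are present and replaces
    the target's missing entries by fitted values; imputed rows are recorded
    in ``imputed`` metadata.  No-op when the target is complete.
    """
    import statsmodels.api as sm

    tm = _as_matrix(table).copy()
    for v in (target_var, predictor_var):
        if v not in tm.data.columns:
            raise TraitError(f"no such variable {v!r}")
    y = tm.data[target_var].astype(float)
    x = tm.data[predictor_var].astype(float)
    if x.isna().any():
        raise TraitError(f"predictor {predictor_var!r} has missing values")
    miss = y.isna()
    if not miss.any():
        return tm
    complete = ~miss
    if complete.sum() < 3:
        raise TraitError("need at least 3 complete pairs for regression imputation")
    fit = sm.OLS(y[complete], sm.add_constant(x[complete])).fit()
    pred = fit.params.iloc[0] + fit.params.iloc[1] * x[miss]
    tm.data.loc[miss, target_var] = pred
    tm.imputed.setdefault(target_var, []).extend(tm.data.index[miss].tolist())
    tm.transform_log.append({
        "rule": "regression_impute", "target": target_var,
        "predictor": predictor_var, "n_imputed": int(miss.sum()),
        "intercept": float(fit.params.iloc[0]), "slope": float(fit.params.iloc[1]),
    })
    return tm


def species_means(specimen_table, species_col: str | None = None) -> TraitMatrix:
    """Arithmetic mean per species per variable (applied after transforms).

    Rows are grouped by ``species_col`` if given, else by the table index.
    Because variables are already on a log scale, averaging here behaves
    like a geometric mean of the raw measurements.
    """
    tm = _as_matrix(specimen_table)
    df = tm.data
    key = df[species_col] if species_col else df.index
    numeric = df.select_dtypes(include=[np.number])
    means = numeric.groupby(key).mean()
    means.index.name = "species"
    return TraitMatrix(means, list(tm.transform_log), dict(tm.imputed))


def pca_reduce(table, var_threshold: float = 0.99) -> PCAResult:
    """Correlation-matrix PCA, retaining the axes covering ``var_threshold``.

    Variables are centred and scaled to unit variance before the
    eigendecomposition, so blocks measured on heterogeneous scales
    contribute equally.  Axis signs are fixed so the largest-magnitude
    loading in each column is positive.
    """
    tm = _as_matrix(table)
    X = tm.values
    n, p = X.shape
    if p < 2 or n < 3:
        raise TraitError("PCA needs >= 2 variables and >= 3 species")
    if not (0 < var_threshold <= 1):
        raise TraitError("var_threshold must be in (0, 1]")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        bad = [tm.variables[j] for j in np.flatnonzero(sd <= 0)]
        raise TraitError(f"constant column(s) cannot be scaled: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    # SVD of the standardised data == eigendecomposition of the correlation matrix
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2 / (n - 1)
    frac = var / var.sum()
    # sign convention: largest |loading| positive per axis
    imax = np.abs(Vt).argmax(axis=1)
    flip = np.sign(Vt[np.arange(Vt.shape[0]), imax])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, : U.shape[1]]
    scores_full = U * s
    n_keep = int(np.searchsorted(np.cumsum(frac), var_threshold - 1e-12) + 1)
    n_keep = min(n_keep, len(frac))
    axes = [f"PC{k+1}" for k in range(len(frac))]
    scores = pd.DataFrame(scores_full[:, :n_keep], index=tm.species, columns=axes[:n_keep])
    loadings = pd.DataFrame(Vt.T, index=tm.variables, columns=axes)
    return PCAResult(scores=scores, loadings=loadings,
                     variance_fraction=frac, n_retained=n_keep)
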