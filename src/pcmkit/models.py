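"""Maximum-likelihood fitting of BM, OU and EB trait-evolution models.

All three models induce a matrix-normal distribution on the species-by-trait
matrix X: ``vec(X) ~ N(vec(1 mu'), R (x) V(theta))`` with ``V`` the tree
covariance (BM: shared path lengths; OU: fixed-root form with pull
``alpha``; EB: ACDC branch transform with rate-decay ``r``), ``R`` the
among-trait rate matrix and ``mu`` the root state.  For a given structural
parameter ``theta`` the mean and rate matrix have closed-form (profiled) ML
estimates, so fitting reduces to a bounded one-dimensional search over
``alpha`` (OU) or ``r`` (EB); BM needs no search at all.

Model comparison uses the small-sample Akaike criterion AICc with n = the
number of species, and Akaike weights; posterior-tree summaries report the
mean and 95% interval of each model's weight across a tree sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .trees import PhyloTree, TreeSet, bm_covariance, eb_transform, ou_covariance

__all__ = [
    "EvoModelFit",
    "ModelComparison",
    "PosteriorModelSummary",
    "fit_model",
    "aicc",
    "akaike_weights",
    "compare_models",
    "compare_over_posterior",
]

MODELS = ("BM", "OU", "EB")


@dataclass
class EvoModelFit:
    model: str
    lnL: float
    k: int
    n: int
    root_mean: np.ndarray        # per-trait ancestral mean
    rate: np.ndarray             # R (p x p); sigma^2 == rate[0, 0] when p == 1
    alpha: float | None = None
    r: float | None = None
    aicc: float = np.nan

    @property
    def sigma2(self) -> float:
        return float(self.rate[0, 0])

    @property
    def n_traits(self) -> int:
        return self.rate.shape[0]


@dataclass
class ModelComparison:
    fits: dict[str, EvoModelFit]
    delta_aicc: dict[str, float]
    weights: dict[str, float]
    best: str


@dataclass
class PosteriorModelSummary:
    per_tree: list[ModelComparison]
    weight_mean_ci: pd.DataFrame     # rows: model; cols: mean, lo, hi
    aicc_mean_sd: pd.DataFrame
    param_mean_sd: pd.DataFrame      # alpha / r across trees
    consensus_best: str
    support_fraction: dict[str, float]
    n_failed: int = 0


# ---------------------------------------------------------------------------
# Likelihood machinery

def _profiled_loglik(V: np.ndarray, X: np.ndarray):
    """Profiled matrix-normal log-likelihood for mean and rate matrix.

    Given the tree covariance ``V`` (unit base rate), the GLS root mean and
    the ML rate matrix follow in closed form; returns (lnL, mu, R).
    """
    n, p = X.shape
    jitter = 0.0
    for _ in range(3):
        try:
            L = np.linalg.cholesky(V + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * np.trace(V) / n)
    else:
        raise np.linalg.LinAlgError("covariance not positive definite after jitter")
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    from scipy.linalg import solve_triangular

    w1 = solve_triangular(L, np.ones((n, 1)), lower=True)
    wX = solve_triangular(L, X, lower=True)
    denom = float((w1.T @ w1).item())
    mu = (w1.T @ wX).ravel() / denom
    E = wX - w1 @ mu[None, :]
    R = (E.T @ E) / n
    sign, logdetR = np.linalg.slogdet(R)
    if sign <= 0:
        return -np.inf, mu, R
    lnL = -0.5 * (n * p * np.log(2 * np.pi) + p * logdetV + n * logdetR + n * p)
    return float(lnL), mu, R


def _model_V(tree: PhyloTree, model: str, theta: float | None) -> np.ndarray:
    if model == "BM":
        return bm_covariance(tree).values
    if model == "OU":
        return ou_covariance(tree, theta).values
    if model == "EB":
        return bm_covariance(eb_transform(tree, theta)).values
    raise ValueError(f"unknown model {model!r}")


def param_count(p: int, model: str) -> int:
    """Free parameters: p root means, p(p+1)/2 rate-matrix entries,
    plus one structural parameter for OU/EB."""
    return p + p * (p + 1) // 2 + (1 if model in ("OU", "EB") else 0)


def _bounded_search(nll, lo: float, hi: float, n_restarts: int = 5,
                    xatol: float = 1e-8):
    """Deterministic bounded 1-D minimisation with interval restarts."""
    edges = np.linspace(lo, hi, n_restarts + 1)
    best_x, best_f = None, np.inf
    for a, b in zip(edges[:-1], edges[1:]):
        res = minimize_scalar(nll, bounds=(a, b), method="bounded",
                              options={"xatol": xatol})
        if res.fun < best_f - 1e-12:
            best_x, best_f = float(res.x), float(res.fun)
    return best_x, best_f


def fit_model(
    tree: PhyloTree,
    traits,
    model: str = "BM",
    optimizer_opts: dict | None = None,
) -> EvoModelFit:
    """Fit one trait-evolution model by ML on one tree.

    ``traits`` is a species-by-trait DataFrame (or TraitMatrix) whose index
    matches the tree's tip labels.  The structural parameter is profiled by
    bounded search: ``alpha`` in [1e-6, 50/height] for OU, ``r`` in
    [-10/height, 0] for EB.  Fixed values can be forced through
    ``optimizer_opts={'alpha': ...}`` / ``{'r': ...}``.
    """
    opts = dict(optimizer_opts or {})
    model = model.upper()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    X, labels = _align_traits(tree, traits)
    n, p = X.shape
    k = param_count(p, model)

    h = tree.height
    if model == "BM":
        theta = None
        lnL, mu, R = _profiled_loglik(_model_V(tree, model, None), X)
    else:
        if model == "OU":
            lo, hi = opts.get("alpha_bounds", (1e-6, 50.0 / h))
            fixed = opts.get("alpha")
        else:
            lo, hi = opts.get("r_bounds", (-10.0 / h, 0.0))
            fixed = opts.get("r")
        if fixed is not None:
            theta = float(fixed)
        else:
            def nll(t):
                try:
                    return -_profiled_loglik(_model_V(tree, model, t), X)[0]
                except np.linalg.LinAlgError:
                    return np.inf
            theta, _ = _bounded_search(nll, lo, hi, opts.get("n_restarts", 5))
        lnL, mu, R = _profiled_loglik(_model_V(tree, model, theta), X)

    fit = EvoModelFit(
        model=model, lnL=lnL, k=k, n=n, root_mean=mu, rate=R,
        alpha=theta if model == "OU" else None,
        r=theta if model == "EB" else None,
    )
    # AICc is undefined (nan) when n <= k + 1; model comparison then refuses
    fit.aicc = aicc(lnL, k, n) if n - k - 1 > 0 else np.nan
    return fit


def _align_traits(tree: PhyloTree, traits):
    from .traits import TraitMatrix

    if isinstance(traits, TraitMatrix):
        df = traits.data
    elif isinstance(traits, pd.DataFrame):
        df = traits
    elif isinstance(traits, pd.Series):
        df = traits.to_frame()
    else:
        df = pd.DataFrame(np.asarray(traits), index=tree.tip_labels)
    missing = set(tree.tip_labels) - set(df.index)
    if missing:
        raise ValueError(f"traits missing for tips: {sorted(missing)}")
    df = df.loc[list(tree.tip_labels)]
    return df.to_numpy(dtype=float), list(df.columns)


# ---------------------------------------------------------------------------
# Information criteria

def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion,
    ``-2 lnL + 2k + 2k(k+1)/(n-k-1)``."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights ``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)`` with
    ``d`` the AICc differences from the best model."""
    a = np.asarray(list(aicc_values), dtype=float)
    if not np.isfinite(a).any():
        raise ValueError("no finite criterion values")
    d = a - np.nanmin(a[np.isfinite(a)])
    w = np.where(np.isfinite(d), np.exp(-0.5 * d), 0.0)
    return w / w.sum()


def compare_models(
    tree: PhyloTree, traits, models=MODELS, optimizer_opts: dict | None = None
) -> ModelComparison:
    """Fit several models on one tree and rank them by AICc weight."""
    fits = {m: fit_model(tree, traits, m, optimizer_opts) for m in models}
    vals = np.array([fits[m].aicc for m in models])
    if np.isnan(vals).any():
        bad = [m for m in models if np.isnan(fits[m].aicc)]
        raise ValueError(f"AICc undefined (n <= k+1) for models: {bad}")
    w = akaike_weights(vals)
    best = min(models, key=lambda m: fits[m].aicc)
    return ModelComparison(
        fits=fits,
        delta_aicc={m: float(fits[m].aicc - fits[best].aicc) for m in models},
        weights={m: float(w[i]) for i, m in enumerate(models)},
        best=best,
    )


def compare_over_posterior(
    treeset: TreeSet, traits, models=MODELS, optimizer_opts: dict | None = None
) -> PosteriorModelSummary:
    """Repeat model comparison on every posterior tree and summarise.

    Reports per-model weight mean with 2.5/97.5 percentile interval, AICc
    mean +/- sd, structural-parameter mean +/- sd, and the consensus best
    model (the model winning the most trees).  Trees whose fit fails are
    skipped and counted.
    """
    per_tree: list[ModelComparison] = []
    n_failed = 0
    for t in treeset:
        try:
            per_tree.append(compare_models(t, traits, models, optimizer_opts))
        except (np.linalg.LinAlgError, ValueError):
            n_failed += 1
    if not per_tree:
        raise RuntimeError("model fitting failed on every tree")

    rows = {}
    aicc_rows = {}
    for m in models:
        w = np.array([c.weights[m] for c in per_tree])
        rows[m] = {"mean": w.mean(), "lo": np.percentile(w, 2.5),
                   "hi": np.percentile(w, 97.5)}
        a = np.array([c.fits[m].aicc for c in per_tree])
        aicc_rows[m] = {"mean": a.mean(), "sd": a.std(ddof=1) if len(a) > 1 else 0.0}
    params = {}
    if "OU" in models:
        al = np.array([c.fits["OU"].alpha for c in per_tree])
        params["alpha"] = {"mean": al.mean(), "sd": al.std(ddof=1) if len(al) > 1 else 0.0}
    if "EB" in models:
        rr = np.array([c.fits["EB"].r for c in per_tree])
        params["r"] = {"mean": rr.mean(), "sd": rr.std(ddof=1) if len(rr) > 1 else 0.0}

    wins = {m: sum(1 for c in per_tree if c.best == m) for m in models}
    consensus = max(models, key=lambda m: (wins[m], -models.index(m)))
    support = {m: wins[m] / len(per_tree) for m in models}
    return PosteriorModelSummary(
        per_tree=per_tree,
        weight_mean_ci=pd.DataFrame(rows).T,
        aicc_mean_sd=pd.DataFrame(aicc_rows).T,
        param_mean_sd=pd.DataFrame(params).T if params else pd.DataFrame(),
        consensus_best=consensus,
        support_fraction=support,
        n_failed=n_failed,
    )
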