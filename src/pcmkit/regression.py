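"""Phylogenetic regression and group tests.

Everything here works in *whitened* space: with ``V`` the tip covariance
implied by a trait-evolution model (BM, OU with pull ``alpha``, or EB with
rate decay ``r``), responses and design are premultiplied by the inverse
Cholesky factor of ``V``, after which ordinary least-squares machinery
applies.  Provided are:

* ``pgls`` — univariate GLS with parametric t/F tests;
* ``mvgls`` — multivariate GLS whose residual covariance can be linearly
  shrunk toward a unit-variance target (ridge "archetype" penalty), with
  the shrinkage weight chosen by leave-one-out cross-validation of the
  penalized Gaussian log-likelihood;
* ``manova_permutation`` — Wilks-lambda MANOVA with a Freedman-Lane
  permutation null on whitened reduced-model residuals;
* ``anova_gls`` — univariate phylogenetic ANOVA with a parametric F test;
* ``select_corr_model`` — majority-vote choice of the correlation structure
  (BM/OU/EB) across a posterior tree sample via per-tree AIC;
* ``correlate_over_posterior`` — phenotype-environment correlation tests
  repeated over the posterior, summarised as the proportion of trees
  supporting each relationship plus means and 95% intervals.

For the EB correlation structure the rate-decay parameter is conventionally
fixed through the present-to-root rate ratio ``g`` (default 0.5, i.e. the
rate halves over the tree height), which pins the structure to a genuine
early burst rather than letting it drift to deceleration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.optimize import minimize_scalar

from .models import _align_traits, _bounded_search
from .trees import (
    PhyloTree,
    TreeSet,
    bm_covariance,
    eb_rate_from_ratio,
    eb_transform,
    ou_covariance,
)

__all__ = [
    "RegressionFit",
    "GroupTestResult",
    "PosteriorGroupTest",
    "EvolCorrSummary",
    "pgls",
    "mvgls",
    "manova_permutation",
    "anova_gls",
    "group_test_over_posterior",
    "select_corr_model",
    "correlate_over_posterior",
]

DEFAULT_EB_RATIO = 0.5   # present/root rate ratio pinning the EB structure
CORR_MODELS = ("BM", "OU", "EB")


@dataclass
class RegressionFit:
    coefficients: pd.DataFrame        # predictors x responses
    corr_model: str
    theta: float | None               # alpha (OU) or r (EB); None for BM
    sigma2: float | None              # univariate residual rate
    Sigma: np.ndarray | None          # multivariate residual covariance
    lambda_ridge: float | None
    lnL: float
    k: int
    n: int
    test_stats: pd.DataFrame | None = None   # per predictor: stat, p
    cv_loglik: float | None = None

    @property
    def aic(self) -> float:
        return -2.0 * self.lnL + 2.0 * self.k


@dataclass
class GroupTestResult:
    statistic: float
    p_value: float
    statistic_name: str               # "wilks" or "F"
    corr_model: str
    n_perm: int | None = None
    df: tuple | None = None
    theta: float | None = None


@dataclass
class PosteriorGroupTest:
    per_tree: pd.DataFrame            # columns: statistic, p_value
    statistic_name: str
    stat_mean_sd: tuple[float, float]
    stat_ci95: tuple[float, float]
    p_mean_sd: tuple[float, float]
    p_ci95: tuple[float, float]
    prop_significant: float
    corr_model: str


@dataclass
class EvolCorrSummary:
    table: pd.DataFrame               # per predictor (and response) summary
    records: pd.DataFrame             # raw per-tree records
    corr_model: str
    threshold: float
    model_votes: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Correlation structures and whitening

def structure_covariance(tree: PhyloTree, corr_model: str,
                         theta: float | None = None) -> np.ndarray:
    corr_model = corr_model.upper()
    if corr_model == "BM":
        return bm_covariance(tree).values
    if corr_model == "OU":
        if theta is None or theta <= 0:
            raise ValueError("OU structure needs alpha > 0")
        return ou_covariance(tree, theta).values
    if corr_model == "EB":
        r = theta if theta is not None else eb_rate_from_ratio(DEFAULT_EB_RATIO, tree.height)
        return bm_covariance(eb_transform(tree, r)).values
    raise ValueError(f"unknown correlation structure {corr_model!r}")


def _whitener(V: np.ndarray) -> np.ndarray:
    n = V.shape[0]
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(V + 1e-10 * np.trace(V) / n * np.eye(n))
    return L


def _whiten(L: np.ndarray, M: np.ndarray) -> np.ndarray:
    return solve_triangular(L, M, lower=True)


def _design(tree: PhyloTree, X, add_intercept: bool = True):
    """Assemble a design matrix aligned to tip order; returns (matrix, names)."""
    if X is None:
        return np.ones((tree.n_tips, 1)), ["intercept"]
    if isinstance(X, pd.Series):
        X = X.to_frame()
    if isinstance(X, pd.DataFrame):
        missing = set(tree.tip_labels) - set(X.index)
        if missing:
            raise ValueError(f"design missing species: {sorted(missing)}")
        M = X.loc[list(tree.tip_labels)].to_numpy(dtype=float)
        names = list(X.columns)
    else:
        M = np.atleast_2d(np.asarray(X, dtype=float))
        if M.shape[0] != tree.n_tips:
            M = M.T
        names = [f"x{j+1}" for j in range(M.shape[1])]
    if add_intercept:
        M = np.column_stack([np.ones(M.shape[0]), M])
        names = ["intercept"] + names
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("rank-deficient design matrix")
    return M, names


def _profile_theta(tree: PhyloTree, corr_model: str, nll_given_V, fixed: dict | None,
                   eb_default: str = "ratio"):
    """Resolve the structural parameter: fixed value, fixed g-ratio, or ML.

    ``eb_default`` controls what an unconstrained EB structure does:
    ``"ratio"`` pins the present/root rate ratio at ``DEFAULT_EB_RATIO``
    (the univariate correlation-structure convention), ``"profile"``
    maximises over the rate-decay parameter.
    """
    fixed = fixed or {}
    corr_model = corr_model.upper()
    if corr_model == "BM":
        return None
    h = tree.height
    if corr_model == "OU":
        if "alpha" in fixed:
            return float(fixed["alpha"])
        lo, hi = 1e-6, 50.0 / h
    else:  # EB
        if "r" in fixed:
            return float(fixed["r"])
        if "g" in fixed:
            return eb_rate_from_ratio(float(fixed["g"]), h)
        if fixed.get("profile_r") or eb_default == "profile":
            lo, hi = -10.0 / h, 0.0
        else:
            return eb_rate_from_ratio(DEFAULT_EB_RATIO, h)
    def nll(t):
        try:
            return nll_given_V(structure_covariance(tree, corr_model, t))
        except np.linalg.LinAlgError:
            return np.inf
    # theta precision well below any downstream sensitivity; keeps the
    # nested (theta, lambda) search cheap
    theta, _ = _bounded_search(nll, lo, hi, 3, xatol=1e-4 * (hi - lo))
    return theta


# ---------------------------------------------------------------------------
# Univariate PGLS

def pgls(tree: PhyloTree, y, X, corr_model: str = "BM",
         fixed_params: dict | None = None, add_intercept: bool = True) -> RegressionFit:
    """Univariate phylogenetic GLS with parametric per-coefficient t tests.

    The structural parameter of the correlation structure is taken from
    ``fixed_params`` (``alpha``, ``r`` or rate-ratio ``g``) or, for OU,
    profiled by ML; EB defaults to the fixed g = 0.5 convention.
    """
    yv, _ = _align_traits(tree, y)
    if yv.shape[1] != 1:
        raise ValueError("pgls is univariate; use mvgls for multivariate responses")
    yv = yv.ravel()
    M, names = _design(tree, X, add_intercept)
    n, q = M.shape

    def nll_given_V(V):
        L = _whitener(V)
        wy, wM = _whiten(L, yv[:, None]).ravel(), _whiten(L, M)
        beta, *_ = np.linalg.lstsq(wM, wy, rcond=None)
        rss = float(np.sum((wy - wM @ beta) ** 2))
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        return 0.5 * (n * np.log(2 * np.pi * rss / n) + logdetV + n)

    theta = _profile_theta(tree, corr_model, nll_given_V, fixed_params)
    V = structure_covariance(tree, corr_model, theta)
    L = _whitener(V)
    wy, wM = _whiten(L, yv[:, None]).ravel(), _whiten(L, M)
    XtX = wM.T @ wM
    beta = np.linalg.solve(XtX, wM.T @ wy)
    resid = wy - wM @ beta
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    logdetV = 2.0 * np.log(np.diag(L)).sum()
    lnL = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdetV + n)
    dof = n - q
    s2 = rss / dof if dof > 0 else np.nan
    se = np.sqrt(s2 * np.diag(np.linalg.inv(XtX)))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    k = q + 1 + (1 if corr_model.upper() in ("OU", "EB") and _theta_free(corr_model, fixed_params) else 0)
    coeffs = pd.DataFrame({"y": beta}, index=names)
    tests = pd.DataFrame({"coef": beta, "se": se, "t": tvals,
                          "F": tvals**2, "p": pvals}, index=names)
    return RegressionFit(
        coefficients=coeffs, corr_model=corr_model.upper(), theta=theta,
        sigma2=sigma2_ml, Sigma=None, lambda_ridge=None, lnL=float(lnL),
        k=k, n=n, test_stats=tests,
    )


def _theta_free(corr_model: str, fixed_params: dict | None,
                eb_default: str = "ratio") -> bool:
    fixed_params = fixed_params or {}
    m = corr_model.upper()
    if m == "OU":
        return "alpha" not in fixed_params
    if m == "EB":
        if "r" in fixed_params or "g" in fixed_params:
            return False
        return bool(fixed_params.get("profile_r")) or eb_default == "profile"
    return False


# ---------------------------------------------------------------------------
# Multivariate GLS with ridge shrinkage

def _loocv_criterion(E: np.ndarray, lam) -> np.ndarray | float:
    """Leave-one-out penalized Gaussian log-likelihood of whitened residuals.

    Each residual row is scored under the shrunk covariance estimated from
    the other rows: ``Sigma_-i = (1-lam) S_-i + lam tr(S_-i)/p I`` with
    ``S_-i`` the ML covariance of the remaining rows.  Evaluated for a
    vector of shrinkage weights at once: writing ``Sigma_-i`` as a scaled
    eigenbasis term plus a rank-1 downdate of ``e_i e_i'`` lets the
    determinant lemma and Sherman-Morrison give every leave-one-out solve
    in O(p) per row.
    """
    lams = np.atleast_1d(np.asarray(lam, dtype=float))
    n, p = E.shape
    S = (E.T @ E) / n
    d, Q = np.linalg.eigh(S)
    d = np.clip(d, 0.0, None)
    F2 = (E @ Q) ** 2                      # (n, p) squared coords in eigenbasis
    norm2 = F2.sum(axis=1)                 # |e_i|^2
    c = (n * d.sum() - norm2) / ((n - 1) * p)   # tr(S_-i)/p
    out = np.empty(len(lams))
    for j, l in enumerate(lams):
        a = (1.0 - l) * n / (n - 1.0)
        g = (1.0 - l) / (n - 1.0)
        denom = a * d[None, :] + l * c[:, None]      # (n, p)
        if np.any(denom <= 0):
            out[j] = -np.inf
            continue
        q = (F2 / denom).sum(axis=1)
        one_minus = 1.0 - g * q
        if np.any(one_minus <= 0):
            out[j] = -np.inf
            continue
        logdet = np.log(denom).sum(axis=1) + np.log(one_minus)
        quad = q / one_minus
        out[j] = float(np.sum(-0.5 * (p * np.log(2 * np.pi) + logdet + quad)))
    return out if np.ndim(lam) else float(out[0])


def _best_lambda(E: np.ndarray, grid_size: int = 41) -> tuple[float, float]:
    grid = np.linspace(0.0, 1.0, grid_size)
    scores = _loocv_criterion(E, grid)
    j = int(np.nanargmax(scores))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, grid_size - 1)]
    if hi > lo:
        res = minimize_scalar(lambda l: -_loocv_criterion(E, float(l)),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        if -res.fun >= scores[j]:
            return float(res.x), float(-res.fun)
    return float(grid[j]), float(scores[j])


def mvgls(tree: PhyloTree, Y, X, corr_model: str = "BM",
          penalty: str = "ridge_arch", target: str = "unitVariance",
          fixed_params: dict | None = None, lam: float | None = None,
          method: str = "LOOCV", add_intercept: bool = True) -> RegressionFit:
    """Multivariate phylogenetic GLS with optional ridge-shrunk residual
    covariance.

    With ``penalty='ridge_arch'`` the residual covariance is
    ``(1 - lam) S + lam (tr S / p) I`` — a linear shrink toward a scaled
    identity ("unit variance") target — with ``lam`` (and, for OU/EB with a
    free parameter, the structural parameter) chosen to maximise the
    leave-one-out cross-validated penalized log-likelihood
    (``method='LOOCV'``).  ``method='LL'`` uses the plain ML covariance
    (``lam = 0``) and profiles the structural parameter by ML; use it for
    AIC-based structure selection.
    """
    Yv, resp_names = _align_traits(tree, Y)
    n, p = Yv.shape
    M, names = _design(tree, X, add_intercept)
    q = M.shape[1]
    if penalty not in ("none", "ridge_arch"):
        raise ValueError(f"unknown penalty {penalty!r}")
    if target != "unitVariance":
        raise ValueError(f"unknown shrinkage target {target!r}")
    if penalty == "none" and p >= n - q:
        raise ValueError("p >= n with penalty='none'; use penalty='ridge_arch'")

    def resid_for_V(V):
        L = _whitener(V)
        wY, wM = _whiten(L, Yv), _whiten(L, M)
        B, *_ = np.linalg.lstsq(wM, wY, rcond=None)
        return L, wY, wM, B, wY - wM @ B

    def ml_lnL(V):
        L, wY, wM, B, E = resid_for_V(V)
        S = (E.T @ E) / n
        sign, logdetS = np.linalg.slogdet(S)
        if sign <= 0:
            return -np.inf, None
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        lnL = -0.5 * (n * p * np.log(2 * np.pi) + p * logdetV + n * logdetS + n * p)
        return lnL, (L, wY, wM, B, E)

    if method == "LL" or penalty == "none":
        theta = _profile_theta(tree, corr_model,
                               lambda V: -ml_lnL(V)[0], fixed_params,
                               eb_default="profile")
        V = structure_covariance(tree, corr_model, theta)
        lnL, parts = ml_lnL(V)
        L, wY, wM, B, E = parts
        lam_hat = 0.0 if lam is None else float(lam)
        S = (E.T @ E) / n
        Sigma = (1 - lam_hat) * S + lam_hat * (np.trace(S) / p) * np.eye(p)
        cv = None
    elif method == "LOOCV":
        def cv_for_V(V):
            _, _, _, _, E = resid_for_V(V)
            if lam is not None:
                return _loocv_criterion(E, lam), float(lam)
            l, s = _best_lambda(E)
            return s, l
        theta = _profile_theta(tree, corr_model,
                               lambda V: -cv_for_V(V)[0], fixed_params,
                               eb_default="profile")
        V = structure_covariance(tree, corr_model, theta)
        L, wY, wM, B, E = resid_for_V(V)
        cv, lam_hat = cv_for_V(V)
        S = (E.T @ E) / n
        Sigma = (1 - lam_hat) * S + lam_hat * (np.trace(S) / p) * np.eye(p)
        # penalized Gaussian log-likelihood at the chosen covariance
        sign, logdetSig = np.linalg.slogdet(Sigma)
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        quad = float(np.trace(np.linalg.solve(Sigma, E.T @ E)))
        lnL = -0.5 * (n * p * np.log(2 * np.pi) + p * logdetV + n * logdetSig + quad)
    else:
        raise ValueError(f"unknown method {method!r}")

    k = q * p + p * (p + 1) // 2 + (
        1 if _theta_free(corr_model, fixed_params, eb_default="profile") else 0)
    coeffs = pd.DataFrame(B, index=names, columns=resp_names)
    return RegressionFit(
        coefficients=coeffs, corr_model=corr_model.upper(), theta=theta,
        sigma2=None, Sigma=Sigma, lambda_ridge=float(lam_hat), lnL=float(lnL),
        k=k, n=n, test_stats=None, cv_loglik=cv,
    )


# ---------------------------------------------------------------------------
# Wilks-lambda permutation tests

def _wilks(wY: np.ndarray, Qf: np.ndarray, Qr: np.ndarray) -> float:
    """det(E_full) / det(E_reduced) from orthonormal design bases."""
    Rf = wY - Qf @ (Qf.T @ wY)
    Rr = wY - Qr @ (Qr.T @ wY)
    Ef = Rf.T @ Rf
    Er = Rr.T @ Rr
    s1, ld1 = np.linalg.slogdet(Ef)
    s2, ld2 = np.linalg.slogdet(Er)
    if s1 <= 0 or s2 <= 0:
        raise np.linalg.LinAlgError("singular residual cross-product")
    return float(np.exp(ld1 - ld2))


def _permutation_wilks(wY, wXf, wXr, n_perm, rng):
    """Freedman-Lane permutation p-value for the full-vs-reduced contrast.

    Rows of the whitened reduced-model residuals are permuted, the reduced
    fit is added back, and Wilks lambda is recomputed; smaller lambda means
    a stronger effect, so the p-value counts permutations with
    ``lambda* <= lambda_obs``.
    """
    Qf, _ = np.linalg.qr(wXf)
    Qr, _ = np.linalg.qr(wXr)
    lam_obs = _wilks(wY, Qf, Qr)
    F0 = Qr @ (Qr.T @ wY)
    R0 = wY - F0
    n = wY.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        lam_p = _wilks(F0 + R0[perm], Qf, Qr)
        if lam_p <= lam_obs + 1e-12:
            count += 1
    return lam_obs, (1.0 + count) / (n_perm + 1.0)


def _group_design(tree: PhyloTree, group) -> tuple[np.ndarray, np.ndarray, list]:
    if isinstance(group, pd.Series):
        g = group.loc[list(tree.tip_labels)]
    else:
        g = pd.Series(np.asarray(group), index=tree.tip_labels)
    levels = sorted(pd.unique(g))
    if len(levels) < 2:
        raise ValueError("group factor needs at least 2 levels")
    counts = g.value_counts()
    small = [l for l in levels if counts[l] < 2]
    if small:
        warnings.warn(f"group level(s) with < 2 species: {small}")
    dummies = np.column_stack([(g == l).to_numpy(float) for l in levels[1:]])
    return dummies, g.to_numpy(), levels


def manova_permutation(tree: PhyloTree, Y, group, corr_model: str = "BM",
                       n_perm: int = 999, seed=None,
                       fixed_params: dict | None = None) -> GroupTestResult:
    """Phylogenetic MANOVA: Wilks lambda with a permutation null.

    The whitened responses are tested for a group-mean difference against
    the intercept-only model; the null distribution comes from permuting
    whitened reduced-model residuals (Freedman-Lane), so phylogenetic
    signal in the residuals is respected under the null.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Yv, _ = _align_traits(tree, Y)
    dummies, _, _ = _group_design(tree, group)

    fit = mvgls(tree, Y, pd.DataFrame(dummies, index=tree.tip_labels),
                corr_model=corr_model, fixed_params=fixed_params, method="LOOCV")
    V = structure_covariance(tree, corr_model, fit.theta)
    L = _whitener(V)
    wY = _whiten(L, Yv)
    n = Yv.shape[0]
    Xf = np.column_stack([np.ones(n), dummies])
    Xr = np.ones((n, 1))
    wXf, wXr = _whiten(L, Xf), _whiten(L, Xr)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam_obs, pval = _permutation_wilks(wY, wXf, wXr, n_perm, rng)
    return GroupTestResult(statistic=lam_obs, p_value=pval, statistic_name="wilks",
                           corr_model=corr_model.upper(), n_perm=n_perm,
                           theta=fit.theta)


def anova_gls(tree: PhyloTree, y, group, corr_model: str = "BM",
              fixed_params: dict | None = None) -> GroupTestResult:
    """Univariate phylogenetic ANOVA: GLS F test of the group factor."""
    yv, _ = _align_traits(tree, y)
    yv = yv.ravel()
    dummies, _, levels = _group_design(tree, group)
    fit = pgls(tree, y, pd.DataFrame(dummies, index=tree.tip_labels,
                                     columns=[f"g_{l}" for l in levels[1:]]),
               corr_model=corr_model, fixed_params=fixed_params)
    V = structure_covariance(tree, corr_model, fit.theta)
    L = _whitener(V)
    n = len(yv)
    g = len(levels)
    Xf = np.column_stack([np.ones(n), dummies])
    Xr = np.ones((n, 1))
    wy = _whiten(L, yv[:, None]).ravel()
    wXf, wXr = _whiten(L, Xf), _whiten(L, Xr)
    rss_f = _rss(wy, wXf)
    rss_r = _rss(wy, wXr)
    df1, df2 = g - 1, n - g
    F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    p = float(stats.f.sf(F, df1, df2))
    return GroupTestResult(statistic=float(F), p_value=p, statistic_name="F",
                           corr_model=corr_model.upper(), df=(df1, df2),
                           theta=fit.theta)


def _rss(wy, wX):
    beta, *_ = np.linalg.lstsq(wX, wy, rcond=None)
    r = wy - wX @ beta
    return float(r @ r)


def group_test_over_posterior(treeset: TreeSet, Y, group, corr_model: str = "BM",
                              n_perm: int = 999, seed=None,
                              fixed_params: dict | None = None,
                              threshold: float = 0.05) -> PosteriorGroupTest:
    """Group test (MANOVA if multivariate, ANOVA if univariate) per posterior
    tree, with mean +/- sd and 95% percentile intervals across trees."""
    Yv, _ = _align_traits(treeset[0], Y)
    multivariate = Yv.shape[1] > 1
    base = 0 if seed is None else int(seed)
    rows = []
    for i, t in enumerate(treeset):
        if multivariate:
            res = manova_permutation(t, Y, group, corr_model, n_perm=n_perm,
                                     seed=np.random.default_rng([base, i]),
                                     fixed_params=fixed_params)
        else:
            res = anova_gls(t, Y, group, corr_model, fixed_params=fixed_params)
        rows.append({"tree": i, "statistic": res.statistic, "p_value": res.p_value})
    df = pd.DataFrame(rows).set_index("tree")
    s, p = df["statistic"].to_numpy(), df["p_value"].to_numpy()
    return PosteriorGroupTest(
        per_tree=df,
        statistic_name="wilks" if multivariate else "F",
        stat_mean_sd=(float(s.mean()), float(s.std(ddof=1)) if len(s) > 1 else 0.0),
        stat_ci95=(float(np.percentile(s, 2.5)), float(np.percentile(s, 97.5))),
        p_mean_sd=(float(p.mean()), float(p.std(ddof=1)) if len(p) > 1 else 0.0),
        p_ci95=(float(np.percentile(p, 2.5)), float(np.percentile(p, 97.5))),
        prop_significant=float((p <= threshold).mean()),
        corr_model=corr_model.upper(),
    )


# ---------------------------------------------------------------------------
# Structure selection and posterior correlation summaries

def select_corr_model(trees, Y, X, candidates=CORR_MODELS,
                      fixed_params: dict | None = None) -> tuple[str, dict[str, int]]:
    """Choose the correlation structure by per-tree AIC majority vote.

    For each tree every candidate structure is fitted (ML) to the regression
    and ranked by AIC; the structure winning the most trees is returned,
    ties breaking toward the simpler model in the order BM > OU > EB.
    """
    if isinstance(trees, PhyloTree):
        trees = [trees]
    Yv, _ = _align_traits(trees[0], Y)
    multivariate = Yv.shape[1] > 1
    votes = {m: 0 for m in candidates}
    for t in trees:
        aics = {}
        for m in candidates:
            fp = (fixed_params or {}).get(m)
            try:
                if multivariate:
                    f = mvgls(t, Y, X, corr_model=m, method="LL",
                              penalty="ridge_arch", fixed_params=fp)
                else:
                    f = pgls(t, Y, X, corr_model=m, fixed_params=fp)
                aics[m] = f.aic
            except (np.linalg.LinAlgError, ValueError):
                aics[m] = np.inf
        best = min(candidates, key=lambda m: (round(aics[m], 9), candidates.index(m)))
        votes[best] += 1
    winner = max(candidates, key=lambda m: (votes[m], -candidates.index(m)))
    return winner, votes


def correlate_over_posterior(treeset: TreeSet, Y, X, threshold: float = 0.05,
                             corr_model: str | None = None,
                             mode: str = "per_axis", n_perm: int = 199,
                             seed=None,
                             fixed_params: dict | None = None) -> EvolCorrSummary:
    """Phenotype-environment evolutionary correlations over a posterior
    tree sample.

    The correlation structure (BM/OU/EB) is chosen once per comparison by
    AIC majority vote across the trees unless ``corr_model`` is given.  For
    each predictor axis (``mode='per_axis'``, the default) or for the joint
    design (``mode='joint'``), every tree yields a test: multivariate
    responses use ridge-penalized GLS with a Freedman-Lane Wilks
    permutation test; a univariate response uses PGLS with parametric
    t-based tests (statistic reported as F = t^2).  The summary reports,
    per predictor, the proportion of trees with p <= ``threshold`` and the
    mean and 2.5/97.5 percentiles of the statistic, p-value and slope.
    """
    Yv, resp_names = _align_traits(treeset[0], Y)
    multivariate = Yv.shape[1] > 1
    if isinstance(X, pd.Series):
        X = X.to_frame()
    pred_names = list(X.columns)
    base = 0 if seed is None else int(seed)

    votes: dict[str, int] = {}
    if corr_model is None:
        corr_model, votes = select_corr_model(list(treeset), Y, X,
                                              fixed_params=fixed_params)
    fp = (fixed_params or {}).get(corr_model) if fixed_params and corr_model in (fixed_params or {}) else fixed_params

    designs = ([(p_, X[[p_]]) for p_ in pred_names] if mode == "per_axis"
               else [("joint", X)])
    records = []
    n_failed = 0
    for i, t in enumerate(treeset):
        for name, Xd in designs:
            try:
                rec = _correlate_one(t, Y, Xd, corr_model, fp, multivariate,
                                     n_perm, np.random.default_rng([base, i]))
            except (np.linalg.LinAlgError, ValueError):
                n_failed += 1
                continue
            for r in rec:
                r.update({"tree": i, "predictor": name if mode == "per_axis" else r["predictor"]})
                records.append(r)
    rec_df = pd.DataFrame(records)
    if rec_df.empty:
        raise RuntimeError("all per-tree correlation fits failed")

    rows = []
    for (pred,), sub in rec_df.groupby(["predictor"]):
        rows.append({
            "predictor": pred,
            "proportion_significant": float((sub["p"] <= threshold).mean()),
            "stat_mean": float(sub["stat"].mean()),
            "stat_lo": float(np.percentile(sub["stat"], 2.5)),
            "stat_hi": float(np.percentile(sub["stat"], 97.5)),
            "p_mean": float(sub["p"].mean()),
            "p_lo": float(np.percentile(sub["p"], 2.5)),
            "p_hi": float(np.percentile(sub["p"], 97.5)),
            "coef_mean": float(sub["coef"].mean()),
            "coef_lo": float(np.percentile(sub["coef"], 2.5)),
            "coef_hi": float(np.percentile(sub["coef"], 97.5)),
            "statistic": "wilks" if multivariate else "F",
            "n_trees": int(sub["tree"].nunique()),
        })
    table = pd.DataFrame(rows).set_index("predictor")
    return EvolCorrSummary(table=table, records=rec_df, corr_model=corr_model,
                           threshold=threshold, model_votes=votes)


def _correlate_one(tree, Y, Xd, corr_model, fp, multivariate, n_perm, rng):
    """One tree x one predictor design; returns a list of record dicts."""
    pred_cols = list(Xd.columns)
    if multivariate:
        fit = mvgls(tree, Y, Xd, corr_model=corr_model, fixed_params=fp,
                    method="LOOCV")
        V = structure_covariance(tree, corr_model, fit.theta)
        L = _whitener(V)
        Yv, _ = _align_traits(tree, Y)
        M, _ = _design(tree, Xd, add_intercept=True)
        wY, wXf = _whiten(L, Yv), _whiten(L, M)
        out = []
        for j, pcol in enumerate(pred_cols, start=1):
            keep = [c for c in range(M.shape[1]) if c != j]
            lam, pval = _permutation_wilks(wY, wXf, wXf[:, keep], n_perm, rng)
            # slope summarised as the mean coefficient magnitude across responses
            coef = float(fit.coefficients.loc[pcol].mean())
            out.append({"predictor": pcol, "stat": lam, "p": pval, "coef": coef,
                        "theta": fit.theta, "lambda": fit.lambda_ridge})
        return out
    fit = pgls(tree, Y, Xd, corr_model=corr_model, fixed_params=fp)
    out = []
    for pcol in pred_cols:
        row = fit.test_stats.loc[pcol]
        out.append({"predictor": pcol, "stat": float(row["F"]), "p": float(row["p"]),
                    "coef": float(row["coef"]), "theta": fit.theta, "lambda": np.nan})
    return out
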