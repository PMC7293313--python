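"""Gaussian random-intercept linear mixed models by profiled (RE)ML.

The model is

    y = X b + Z u + e,   u ~ N(0, sigma2_alpha I_q),   e ~ N(0, sigma2_eps I_n)

with a single grouping factor (one random intercept per group, here one
per seal). Both variance components are profiled out analytically: for a
given variance ratio ``lam = sigma2_alpha / sigma2_eps`` the marginal
covariance is ``sigma2_eps * W(lam)`` with ``W = I + lam Z Z'`` block
diagonal by group, so GLS estimates, the profiled residual variance and
the (restricted) log-likelihood are all closed-form. The optimisation is
then a one-dimensional search over ``log(lam)``, which is fast enough to
run thousands of parametric-bootstrap refits, and accurate enough to
match method-of-moments variance components on balanced designs to
near machine precision.

Every estimate is deterministic given the data; the only randomness in
this module is in :func:`simulate_response`, which takes an explicit
NumPy generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = ["LMMFit", "fit_random_intercept", "ols_loglik", "simulate_response"]

_LOG_LAM_LO = -16.0
_LOG_LAM_HI = 16.0


@dataclass
class LMMFit:
    """A fitted random-intercept model.

    Coefficients are reported only for linearly independent columns of
    the requested design; aliased columns (e.g. a device factor fully
    confounded with year) are dropped and listed in ``dropped_terms``.
    """

    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    fe_names: list[str]
    sigma2_alpha: float
    sigma2_eps: float
    loglik: float
    reml: bool
    n_obs: int
    k_fixed: int
    group_labels: np.ndarray
    blups: np.ndarray            # one predicted intercept per group
    fitted_fixed: np.ndarray     # X b
    resid_marginal: np.ndarray   # y - X b
    resid_conditional: np.ndarray  # y - X b - Z u_hat
    cov_params: np.ndarray
    boundary: bool               # sigma2_alpha estimated at zero
    dropped_terms: list[str] = field(default_factory=list)
    _X: np.ndarray | None = None
    _group_idx: np.ndarray | None = None

    @property
    def lam(self) -> float:
        if self.sigma2_eps == 0:
            return 0.0
        return self.sigma2_alpha / self.sigma2_eps

    def var_fixed_predictor(self) -> float:
        """Sample variance of the fixed-effect linear predictor."""
        if self.fitted_fixed.size < 2:
            return 0.0
        return float(np.var(self.fitted_fixed, ddof=1))

    def wald_F(self, cols: list[int]) -> tuple[float, int]:
        """Wald F statistic for the joint null that the given
        coefficients are zero; returns (F, df1)."""
        idx = np.asarray(cols, dtype=int)
        beta = self.params[idx]
        V = self.cov_params[np.ix_(idx, idx)]
        df1 = len(idx)
        stat = float(beta @ np.linalg.solve(V, beta)) / df1
        return stat, df1


def _design_rank_filter(X: np.ndarray, names: list[str]):
    """Greedily keep a maximal linearly independent subset of columns,
    preserving order (earlier columns win)."""
    n, p = X.shape
    keep: list[int] = []
    # incremental QR via Gram matrix; p is small (<= ~15) in this package
    for j in range(p):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-8 * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
    dropped = [names[j] for j in range(p) if j not in keep]
    return X[:, keep], [names[j] for j in keep], dropped


class _Profile:
    """Pre-computed sufficient statistics for the profiled likelihood."""

    def __init__(self, X: np.ndarray, y: np.ndarray, group_idx: np.ndarray, n_groups: int):
        self.X = X
        self.y = y
        self.gi = group_idx
        self.n, self.p = X.shape
        self.G = n_groups
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ng = np.bincount(group_idx, minlength=n_groups).astype(float)
        self.Sx = np.zeros((n_groups, self.p))
        for j in range(self.p):
            self.Sx[:, j] = np.bincount(group_idx, weights=X[:, j], minlength=n_groups)
        self.Sy = np.bincount(group_idx, weights=y, minlength=n_groups)

    def gls(self, lam: float):
        c = lam / (1.0 + lam * self.ng)
        A = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
        b = self.Xty - self.Sx.T @ (c * self.Sy)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
        ywy = self.yty - float(c @ (self.Sy**2))
        rss = max(ywy - float(beta @ b), 1e-300)
        logdetW = float(np.sum(np.log1p(lam * self.ng)))
        return A, beta, rss, logdetW

    def neg2ll(self, lam: float, reml: bool) -> float:
        A, _, rss, logdetW = self.gls(lam)
        n, p = self.n, self.p
        if reml:
            df = n - p
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf
            return df * np.log(2.0 * np.pi * rss / df) + logdetW + logdetA + df
        return n * np.log(2.0 * np.pi * rss / n) + logdetW + n


def fit_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    *,
    reml: bool = True,
    fe_names: list[str] | None = None,
) -> LMMFit:
    """Fit ``y = X b + (1 | group) + e`` by REML (default) or ML.

    Parameters
    ----------
    X : (n, p) design matrix, including the intercept column.
    y : (n,) response.
    groups : (n,) group labels (any hashable dtype).
    reml : restricted maximum likelihood if True, else full ML
        (use ML when likelihoods must be comparable across different
        fixed-effect structures, e.g. for information criteria).
    fe_names : optional column names for the coefficient table.

    Raises
    ------
    ValueError on shape mismatch or fewer than two groups.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(groups) != len(y):
        raise ValueError("X, y and groups must have matching first dimensions")
    labels, gi = np.unique(np.asarray(groups), return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups for a random intercept")
    names = fe_names if fe_names is not None else [f"x{j}" for j in range(X.shape[1])]
    X, names, dropped = _design_rank_filter(X, list(names))
    if X.shape[1] >= len(y):
        raise ValueError("more fixed-effect columns than observations")

    prof = _Profile(X, y, gi, len(labels))

    res = optimize.minimize_scalar(
        lambda t: prof.neg2ll(np.exp(t), reml),
        bounds=(_LOG_LAM_LO, _LOG_LAM_HI),
        method="bounded",
        options={"xatol": 1e-12},
    )
    cand = [(prof.neg2ll(0.0, reml), 0.0), (res.fun, float(np.exp(res.x)))]
    n2ll, lam = min(cand, key=lambda t: t[0])
    boundary = lam < 1e-10
    if boundary:
        lam = 0.0

    A, beta, rss, _ = prof.gls(lam)
    dof = prof.n - prof.p if reml else prof.n
    sigma2_eps = rss / dof
    sigma2_alpha = lam * sigma2_eps
    cov = sigma2_eps * np.linalg.inv(A)
    bse = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bse > 0, beta / bse, np.inf)
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    fitted = X @ beta
    rmarg = y - fitted
    shrink = lam / (1.0 + lam * prof.ng)
    blups = shrink * np.bincount(gi, weights=rmarg, minlength=prof.G)
    rcond = rmarg - blups[gi]

    return LMMFit(
        params=beta,
        bse=bse,
        pvalues=pvals,
        fe_names=names,
        sigma2_alpha=sigma2_alpha,
        sigma2_eps=sigma2_eps,
        loglik=-0.5 * n2ll,
        reml=reml,
        n_obs=prof.n,
        k_fixed=prof.p,
        group_labels=labels,
        blups=blups,
        fitted_fixed=fitted,
        resid_marginal=rmarg,
        resid_conditional=rcond,
        cov_params=cov,
        boundary=boundary,
        dropped_terms=dropped,
        _X=X,
        _group_idx=gi,
    )


def ols_loglik(X: np.ndarray, y: np.ndarray) -> float:
    """ML log-likelihood of the fixed-effects-only Gaussian model, used
    as the null in the boundary likelihood-ratio test for a variance
    component."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    n = len(y)
    return -0.5 * (n * np.log(2.0 * np.pi * rss / n) + n)


def simulate_response(fit: LMMFit, rng: np.random.Generator) -> np.ndarray:
    """Draw a new response vector from the fitted model (fresh random
    intercepts and residuals), for parametric bootstrapping."""
    u = rng.normal(0.0, np.sqrt(max(fit.sigma2_alpha, 0.0)), size=len(fit.group_labels))
    e = rng.normal(0.0, np.sqrt(max(fit.sigma2_eps, 0.0)), size=fit.n_obs)
    return fit.fitted_fixed + u[fit._group_idx] + e
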