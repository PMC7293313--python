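"""Across-year repeatability of resting HRV.

Repeatability (the intraclass correlation from an LMM with individual
as a random intercept) is

    R = sigma2_alpha / (sigma2_alpha + sigma2_eps),

estimated by REML with the number of seasonal measures per individual
as a fixed covariate — sampling effort can correlate with the trait, so
it is adjusted for, mirroring common practice for repeatability from
unbalanced field data. Uncertainty comes from a parametric bootstrap
(simulate from the fitted model, refit, percentile interval); the
significance test is a likelihood-ratio test of the random effect
against the fixed-effects-only model, with the null distribution an
equal mixture of a point mass at zero and chi-square(1) because the
variance is tested on its boundary.

A per-individual analogue ``Ri = sigma2_alpha / (sigma2_alpha + s2_i)``
replaces the population residual variance with the sample variance
``s2_i`` of individual *i*'s conditional residuals — how consistent
that one seal is, relative to how different seals are from each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import LMMFit, fit_random_intercept, ols_loglik, simulate_response

__all__ = ["RepeatabilityResult", "estimate_repeatability", "individual_Ri"]


@dataclass
class RepeatabilityResult:
    R: float
    se: float
    ci: tuple[float, float]
    lrt_p: float
    n_boot: int
    Ri: dict = field(default_factory=dict)
    sigma2_alpha: float = np.nan
    sigma2_eps: float = np.nan
    n_ids: int = 0
    n_obs: int = 0
    boundary: bool = False
    boot_R: np.ndarray | None = None
    fit: LMMFit | None = None

    def to_dict(self) -> dict:
        return dict(R=self.R, se=self.se, ci_lower=self.ci[0], ci_upper=self.ci[1],
                    lrt_p=self.lrt_p, n_boot=self.n_boot,
                    sigma2_alpha=self.sigma2_alpha, sigma2_eps=self.sigma2_eps,
                    n_ids=self.n_ids, n_obs=self.n_obs, boundary=self.boundary)


def _ratio(fit: LMMFit) -> float:
    tot = fit.sigma2_alpha + fit.sigma2_eps
    return float(fit.sigma2_alpha / tot) if tot > 0 else 0.0


def estimate_repeatability(table: pd.DataFrame, *,
                           response: str = "resting_hrv_ms",
                           id_col: str = "id",
                           min_seasons: int = 2,
                           n_boot: int = 1000,
                           seed: int = 0) -> RepeatabilityResult:
    """Population repeatability of a seal-season trait table.

    Rows from individuals with fewer than ``min_seasons`` measures are
    excluded (single measures carry no within-individual information).
    Requires at least two qualifying individuals.
    """
    counts = table.groupby(id_col)[response].transform("count")
    sub = table[counts >= min_seasons].copy()
    ids = sub[id_col].to_numpy()
    if len(np.unique(ids)) < 2:
        raise ValueError("need >= 2 individuals with repeat measures")
    y = sub[response].to_numpy(dtype=float)
    n_measures = sub.groupby(id_col)[response].transform("count").to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(y), n_measures])

    fit = fit_random_intercept(X, y, ids, reml=True,
                               fe_names=["intercept", "n_measures"])
    R = _ratio(fit)

    # boundary LRT: ML mixed fit vs fixed-effects-only model
    fit_ml = fit_random_intercept(X, y, ids, reml=False)
    ll0 = ols_loglik(X, y)
    lrt = max(0.0, 2.0 * (fit_ml.loglik - ll0))
    lrt_p = 1.0 if lrt <= 0 else 0.5 * float(stats.chi2.sf(lrt, df=1))

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        yb = simulate_response(fit, rng)
        fb = fit_random_intercept(X, yb, ids, reml=True)
        boot[b] = _ratio(fb)
    se = float(np.std(boot, ddof=1)) if n_boot > 1 else np.nan
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5))) \
        if n_boot > 1 else (np.nan, np.nan)

    return RepeatabilityResult(
        R=R, se=se, ci=ci, lrt_p=lrt_p, n_boot=n_boot,
        Ri=individual_Ri(fit),
        sigma2_alpha=fit.sigma2_alpha, sigma2_eps=fit.sigma2_eps,
        n_ids=len(fit.group_labels), n_obs=fit.n_obs,
        boundary=fit.boundary, boot_R=boot, fit=fit,
    )


def individual_Ri(fit: LMMFit) -> dict:
    """Per-individual repeatability from conditional residuals.

    ``Ri = sigma2_alpha / (sigma2_alpha + s2_i)`` with ``s2_i`` the
    sample variance of individual i's conditional (BLUP-adjusted)
    residuals. Individuals with a single measure are excluded — one
    residual has no variance.
    """
    out: dict = {}
    gi = fit._group_idx
    for g, label in enumerate(fit.group_labels):
        r = fit.resid_conditional[gi == g]
        if len(r) < 2:
            continue
        s2 = float(np.var(r, ddof=1))
        denom = fit.sigma2_alpha + s2
        out[label] = float(fit.sigma2_alpha / denom) if denom > 0 else 0.0
    return out
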