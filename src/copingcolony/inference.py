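"""Mixed-model inference: all-subsets AICc selection with nested
pruning, variance-explained decomposition, and year contrasts.

For each of eight standardised responses (the four mass proxies MPPM,
MDML, PDMG, MTE and their log-transformed annual deviance moduli) a
global Gaussian random-intercept model is dredged: every subset of the
global fixed terms respecting marginality (the HRV-by-year interaction
only with both main effects) is fitted by maximum likelihood — ML, not
REML, because likelihoods must be comparable across different
fixed-effect structures — and ranked by small-sample AICc. Models
within six AICc units of the best form a preliminary confidence set,
which is then pruned: any model containing a simpler nested model that
matches or beats its AICc is discarded, so extra terms must pay their
way. The best model is refitted by REML for reported coefficients,
marginal/conditional R-squared, and per-term semipartial R-squared with
parametric-bootstrap intervals.

Kruskal-Wallis rank-sum tests provide the nonparametric year contrasts
for the daily mass-change rates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import LMMFit, fit_random_intercept, simulate_response

__all__ = [
    "ModelSpec", "ModelFit", "ConfidenceSet", "GroupTestResult",
    "RESPONSES", "GLOBAL_TERMS", "build_candidate_set", "build_design",
    "fit_lmm", "aicc", "confidence_set", "akaike_weights",
    "r2_decomposition", "kruskal_wallis", "run_analysis", "AnalysisConfig",
]

GLOBAL_TERMS = ("hrv", "birthdate", "pup_sex", "year", "device", "mppm", "hrv:year")

#: response name -> (standardised column in the analysis table, uses MPPM covariate)
RESPONSES = {
    "MPPM": ("z_mppm", False),
    "MDML": ("z_mdml", True),
    "PDMG": ("z_pdmg", True),
    "MTE": ("z_mte", True),
    "dev_MPPM": ("zlog_dev_mppm", False),
    "dev_MDML": ("zlog_dev_mdml", True),
    "dev_PDMG": ("zlog_dev_pdmg", True),
    "dev_MTE": ("zlog_dev_mte", True),
}

_TERM_ORDER = {t: i for i, t in enumerate(GLOBAL_TERMS)}


@dataclass(frozen=True)
class ModelSpec:
    response: str
    fixed_terms: tuple[str, ...] = ()

    def __post_init__(self):
        terms = tuple(sorted(set(self.fixed_terms), key=_TERM_ORDER.get))
        object.__setattr__(self, "fixed_terms", terms)
        if "hrv:year" in terms and not {"hrv", "year"} <= set(terms):
            raise ValueError("hrv:year requires both hrv and year (marginality)")

    def label(self) -> str:
        return " + ".join(self.fixed_terms) if self.fixed_terms else "Null"

    def nests_within(self, other: "ModelSpec") -> bool:
        """True when self's terms are a proper subset of other's."""
        return set(self.fixed_terms) < set(other.fixed_terms)


@dataclass
class ModelFit:
    spec: ModelSpec
    fit: LMMFit
    k_params: int
    aicc: float
    delta_aicc: float = np.nan
    weight: float = np.nan
    converged: bool = True

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.fit.fe_names,
            "estimate": self.fit.params,
            "se": self.fit.bse,
            "p": self.fit.pvalues,
        })


@dataclass
class ConfidenceSet:
    retained: list[ModelFit]
    pruned: list[dict]          # {model, reason, displaced_by}
    null_fit: ModelFit | None = None

    def labels(self) -> list[str]:
        return [m.spec.label() for m in self.retained]


@dataclass
class GroupTestResult:
    chi2: float
    df: int
    p: float


# ---------------------------------------------------------------------------
# candidate enumeration


def global_terms_for(response: str) -> tuple[str, ...]:
    """The global fixed-term set for a response; post-partum mass is not
    offered as a predictor of itself or of its own deviance modulus."""
    uses_mppm = RESPONSES[response][1] if response in RESPONSES else True
    return GLOBAL_TERMS if uses_mppm else tuple(t for t in GLOBAL_TERMS if t != "mppm")


def build_candidate_set(global_spec: ModelSpec) -> list[ModelSpec]:
    """All subsets of the global fixed terms respecting marginality,
    null model included, in a deterministic order (by size, then term
    order)."""
    terms = global_spec.fixed_terms
    specs = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            if "hrv:year" in combo and not {"hrv", "year"} <= set(combo):
                continue
            specs.append(ModelSpec(global_spec.response, combo))
    specs.sort(key=lambda s: (len(s.fixed_terms),
                              tuple(_TERM_ORDER[t] for t in s.fixed_terms)))
    return specs


# ---------------------------------------------------------------------------
# design matrices


_COVARIATE_COLS = {"hrv": "hrv_z", "birthdate": "birthdate_z", "mppm": "mppm_z"}


def _factor_dummies(table: pd.DataFrame, col: str, prefix: str):
    """Treatment-coded dummies, reference = first sorted level."""
    levels = sorted(table[col].unique())
    cols, names = [], []
    for lev in levels[1:]:
        cols.append((table[col] == lev).to_numpy(dtype=float))
        names.append(f"{prefix}[{lev}]")
    return cols, names


def build_design(table: pd.DataFrame, terms: tuple[str, ...]):
    """Design matrix (with intercept) for a term set; factors use
    treatment contrasts with the first sorted level (earliest year,
    Firstbeat-before-Polar alphabetical aside: device reference is
    Polar) as baseline."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["intercept"]
    for t in terms:
        if t in _COVARIATE_COLS:
            cols.append(table[_COVARIATE_COLS[t]].to_numpy(dtype=float))
            names.append(t)
        elif t == "pup_sex":
            c, nm = _factor_dummies(table, "pup_sex", "pup_sex")
            cols += c
            names += nm
        elif t == "year":
            c, nm = _factor_dummies(table, "year", "year")
            cols += c
            names += nm
        elif t == "device":
            # Polar (the earlier device generation) as the reference level
            levels = sorted(table["device"].unique())
            ref = "Polar" if "Polar" in levels else levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((table["device"] == lev).to_numpy(dtype=float))
                names.append(f"device[{lev}]")
        elif t == "hrv:year":
            hrv = table["hrv_z"].to_numpy(dtype=float)
            c, nm = _factor_dummies(table, "year", "hrv:year")
            cols += [hrv * cc for cc in c]
            names += nm
        else:
            raise ValueError(f"unknown term {t!r}")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# fitting, AICc, confidence sets


def fit_lmm(spec: ModelSpec, table: pd.DataFrame, *, criterion: str = "ML",
            response_col: str | None = None) -> ModelFit:
    """Fit one candidate random-intercept model.

    ``criterion`` is "ML" for selection-comparable likelihoods or
    "REML" for reported coefficients. ``k_params`` counts the linearly
    independent fixed coefficients plus both variance components.
    """
    if response_col is None:
        response_col = RESPONSES[spec.response][0]
    sub = table.dropna(subset=[response_col])
    X, names = build_design(sub, spec.fixed_terms)
    y = sub[response_col].to_numpy(dtype=float)
    fit = fit_random_intercept(X, y, sub["id"].to_numpy(), reml=(criterion == "REML"),
                               fe_names=names)
    k = fit.k_fixed + 2
    return ModelFit(spec=spec, fit=fit, k_params=k,
                    aicc=aicc(fit.loglik, k, fit.n_obs))


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion,
    ``-2 ll + 2k + 2k(k+1)/(n-k-1)``."""
    if k >= n - 1:
        raise ValueError("AICc undefined: k >= n - 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs: np.ndarray) -> np.ndarray:
    """Weights over the full candidate set."""
    d = aiccs - np.min(aiccs)
    w = np.exp(-0.5 * d)
    return w / w.sum()


def _sort_key(m: ModelFit):
    # AICc ties broken by fewer parameters (requested terms count too:
    # an aliased factor adds no rank but still loses the tie), then by
    # term order
    return (m.aicc, m.k_params, len(m.spec.fixed_terms),
            tuple(_TERM_ORDER[t] for t in m.spec.fixed_terms))


def confidence_set(fits: list[ModelFit], *, delta_max: float = 6.0,
                   prune_nested: bool = True) -> ConfidenceSet:
    """AICc confidence set with nested-model pruning.

    Step 1 retains fits with delta AICc <= ``delta_max`` of the best.
    Step 2 discards any retained model for which some *simpler nested*
    model in the preliminary set has AICc less than or equal to its own
    — a more complex model must beat everything nested within it. The
    rule is evaluated against the preliminary set for every model, so
    the result is independent of processing order. The null model's fit
    is reported alongside even when not retained.
    """
    ok = [m for m in fits if m.converged]
    if not ok:
        raise ValueError("no converged fits")
    ok = sorted(ok, key=_sort_key)
    best = ok[0]
    for m in ok:
        m.delta_aicc = m.aicc - best.aicc
    ws = akaike_weights(np.array([m.aicc for m in ok]))
    for m, w in zip(ok, ws):
        m.weight = float(w)

    prelim = [m for m in ok if m.delta_aicc <= delta_max]
    retained, pruned = [], []
    for m in prelim:
        displacer = None
        if prune_nested:
            for m2 in prelim:
                if m2.spec.nests_within(m.spec) and m2.aicc <= m.aicc:
                    displacer = m2
                    break
        if displacer is None or m is best:
            retained.append(m)
        else:
            pruned.append(dict(model=m.spec.label(), reason="nested_simpler_model",
                               displaced_by=displacer.spec.label()))
    null_fit = next((m for m in ok if not m.spec.fixed_terms), None)
    return ConfidenceSet(retained=retained, pruned=pruned, null_fit=null_fit)


# ---------------------------------------------------------------------------
# variance explained


def _term_columns(fit: LMMFit, terms: tuple[str, ...]) -> dict[str, list[int]]:
    """Map each model term to its coefficient indices (intercept
    excluded)."""
    out: dict[str, list[int]] = {}
    for t in terms:
        if t in _COVARIATE_COLS:
            pre = {t}
            idx = [i for i, nm in enumerate(fit.fe_names) if nm in pre]
        else:
            idx = [i for i, nm in enumerate(fit.fe_names)
                   if nm.startswith(f"{t}[")]
        if idx:
            out[t] = idx
    return out


def _semipartial(fit: LMMFit, cols: list[int]) -> float:
    F, df1 = fit.wald_F(cols)
    df2 = fit.n_obs - fit.k_fixed
    return float(df1 * F / (df1 * F + df2))


def r2_decomposition(mfit: ModelFit, *, n_boot: int = 0, seed: int = 0) -> dict:
    """Marginal/conditional R-squared and per-term semipartial R-squared.

    ``r2_marginal = var_f / (var_f + s2_alpha + s2_eps)`` with ``var_f``
    the sample variance of the fixed-effect predictor;
    ``r2_conditional`` adds the ID variance to the numerator;
    ``id_variance_share`` is the percent of stochastic (non-fixed)
    variance attributed to ID. Per-term values use the Wald-F
    formulation ``df1 F / (df1 F + df2)`` with ``df2 = n - k_fixed`` —
    a documented simplification of adjusted-df semipartial R-squared —
    with percentile CIs from a parametric bootstrap when requested.
    """
    fit = mfit.fit
    var_f = fit.var_fixed_predictor() if mfit.spec.fixed_terms else 0.0
    tot = var_f + fit.sigma2_alpha + fit.sigma2_eps
    r2m = var_f / tot if tot > 0 else 0.0
    r2c = (var_f + fit.sigma2_alpha) / tot if tot > 0 else 0.0
    stoch = fit.sigma2_alpha + fit.sigma2_eps
    id_share = 100.0 * fit.sigma2_alpha / stoch if stoch > 0 else 0.0

    term_cols = _term_columns(fit, mfit.spec.fixed_terms)
    terms = {t: {"r2": _semipartial(fit, cols)} for t, cols in term_cols.items()}

    if n_boot > 0 and term_cols:
        rng = np.random.default_rng(seed)
        X = fit._X
        draws: dict[str, list[float]] = {t: [] for t in term_cols}
        for _ in range(n_boot):
            yb = simulate_response(fit, rng)
            fb = fit_random_intercept(X, yb, fit.group_labels[fit._group_idx],
                                      reml=fit.reml, fe_names=fit.fe_names)
            for t, cols in term_cols.items():
                draws[t].append(_semipartial(fb, cols))
        for t in term_cols:
            lo, hi = np.percentile(draws[t], [2.5, 97.5])
            terms[t]["ci"] = (float(lo), float(hi))

    return dict(r2_marginal=float(r2m), r2_conditional=float(r2c),
                id_variance_share=float(id_share), terms=terms)


# ---------------------------------------------------------------------------
# nonparametric year contrasts


def kruskal_wallis(values, groups) -> GroupTestResult:
    """Tie-corrected Kruskal-Wallis H against chi-square with
    (groups - 1) df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        raise ValueError("all values identical: H undefined under tie correction")
    h, p = stats.kruskal(*samples)
    return GroupTestResult(chi2=float(h), df=len(labels) - 1, p=float(p))


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class AnalysisConfig:
    responses: tuple[str, ...] = tuple(RESPONSES)
    delta_aicc_max: float = 6.0
    prune_nested: bool = True
    n_boot_r2: int = 200
    seed: int = 0
    test_hrv_birthdate_interaction: bool = True


def _hrv_birthdate_variant(best: ModelFit, table: pd.DataFrame,
                           response_col: str) -> dict | None:
    """Refit the best model with an added HRV-by-birthdate interaction
    column and compare AICc (only sensible when both main effects are
    retained)."""
    terms = set(best.spec.fixed_terms)
    if not {"hrv", "birthdate"} <= terms:
        return None
    sub = table.dropna(subset=[response_col])
    X, names = build_design(sub, best.spec.fixed_terms)
    inter = (sub["hrv_z"] * sub["birthdate_z"]).to_numpy(dtype=float)
    X2 = np.column_stack([X, inter])
    fit2 = fit_random_intercept(X2, sub[response_col].to_numpy(dtype=float),
                                sub["id"].to_numpy(), reml=False,
                                fe_names=names + ["hrv:birthdate"])
    a2 = aicc(fit2.loglik, fit2.k_fixed + 2, fit2.n_obs)
    return dict(aicc_with_interaction=float(a2), aicc_without=float(best.aicc),
                interaction_improves=bool(a2 < best.aicc))


def run_analysis(table: pd.DataFrame, config: AnalysisConfig | None = None) -> dict:
    """Full inference over all responses of a merged analysis table.

    Returns a machine-readable report: per response, the candidate
    count, the confidence set (labels, df, AICc, delta, weight), the
    null-model row, the best model's REML coefficient table, R-squared
    block, optional HRV-by-birthdate variant comparison; plus
    Kruskal-Wallis year tests for the daily mass-change rates. One
    response failing records an error without aborting the rest.
    """
    config = config or AnalysisConfig()
    report: dict = {"responses": {}, "kruskal_wallis": {}}

    for resp in config.responses:
        try:
            col = RESPONSES[resp][0]
            gspec = ModelSpec(resp, global_terms_for(resp))
            candidates = build_candidate_set(gspec)
            fits = [fit_lmm(s, table, criterion="ML") for s in candidates]
            cs = confidence_set(fits, delta_max=config.delta_aicc_max,
                                prune_nested=config.prune_nested)
            best = cs.retained[0]
            best_reml = fit_lmm(best.spec, table, criterion="REML")
            r2 = r2_decomposition(best_reml, n_boot=config.n_boot_r2,
                                  seed=config.seed)
            entry = dict(
                n_candidates=len(candidates),
                confidence_set=[dict(model=m.spec.label(), df=m.k_params,
                                     aicc=float(m.aicc),
                                     delta_aicc=float(m.delta_aicc),
                                     weight=float(m.weight))
                                for m in cs.retained],
                pruned=cs.pruned,
                null_model=dict(model="Null", df=cs.null_fit.k_params,
                                aicc=float(cs.null_fit.aicc),
                                delta_aicc=float(cs.null_fit.delta_aicc),
                                weight=float(cs.null_fit.weight)),
                best_model=dict(
                    model=best.spec.label(),
                    coefficients=best_reml.coef_table().to_dict("records"),
                    **r2,
                ),
            )
            if config.test_hrv_birthdate_interaction:
                variant = _hrv_birthdate_variant(best, table, col)
                if variant is not None:
                    entry["hrv_birthdate_interaction"] = variant
            report["responses"][resp] = entry
        except Exception as exc:  # response-level isolation
            report["responses"][resp] = {"error": f"{type(exc).__name__}: {exc}"}

    for metric in ("mdml", "pdmg"):
        try:
            kw = kruskal_wallis(table[metric].to_numpy(),
                                table["year"].to_numpy())
            report["kruskal_wallis"][metric.upper()] = dict(
                chi2=kw.chi2, df=kw.df, p=kw.p)
        except Exception as exc:
            report["kruskal_wallis"][metric.upper()] = {
                "error": f"{type(exc).__name__}: {exc}"}
    return report
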