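import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from copingcolony.inference import (GLOBAL_TERMS, RESPONSES, AnalysisConfig,
                                    ModelFit, ModelSpec, aicc,
                                    build_candidate_set, build_design,
                                    confidence_set, fit_lmm,
                                    global_terms_for, kruskal_wallis,
                                    r2_decomposition, run_analysis)


# ---------------------------------------------------------------------------
# oracles

def enumerate_subsets_oracle(terms):
    """Independent power-set enumeration with the marginality filter."""
    out = set()
    for mask in range(2 ** len(terms)):
        combo = frozenset(t for i, t in enumerate(terms) if mask >> i & 1)
        if "hrv:year" in combo and not {"hrv", "year"} <= combo:
            continue
        out.add(combo)
    return out


def kw_oracle(values, groups):
    """Tie-corrected Kruskal-Wallis H from the rank formula."""
    values = np.asarray(values, dtype=float)
    ranks = stats.rankdata(values)
    N = len(values)
    h = 0.0
    for g in np.unique(groups):
        r = ranks[np.asarray(groups) == g]
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(values, return_counts=True)
    ties = np.sum(counts**3 - counts)
    return h / (1.0 - ties / (N**3 - N))


def prune_oracle(entries, delta_max=6.0):
    """Brute-force confidence set on (terms, aicc) tuples: keep models
    within delta_max of the minimum, then discard any with a nested
    simpler model at equal-or-lower AICc."""
    best = min(a for _, a in entries)
    prelim = [(t, a) for t, a in entries if a - best <= delta_max]
    keep = []
    for t, a in prelim:
        if not any(set(t2) < set(t) and a2 <= a for t2, a2 in prelim):
            keep.append((t, a))
    return {frozenset(t) for t, _ in keep}


# ---------------------------------------------------------------------------


class TestCandidateEnumeration:
    def test_interaction_marginality_example(self):
        specs = build_candidate_set(ModelSpec("MDML", ("hrv", "year", "hrv:year")))
        labels = {s.fixed_terms for s in specs}
        assert labels == {(), ("hrv",), ("year",), ("hrv", "year"),
                          ("hrv", "year", "hrv:year")}

    def test_single_term_gives_two_models(self):
        assert len(build_candidate_set(ModelSpec("MDML", ("hrv",)))) == 2

    def test_mppm_not_a_predictor_of_itself(self):
        for resp in ("MPPM", "dev_MPPM"):
            specs = build_candidate_set(ModelSpec(resp, global_terms_for(resp)))
            assert all("mppm" not in s.fixed_terms for s in specs)

    def test_matches_powerset_oracle_on_all_global_models(self):
        """Exhaustive check over every subset of the full 7-term global
        model used as a global specification."""
        for r in range(len(GLOBAL_TERMS) + 1):
            for gterms in itertools.combinations(GLOBAL_TERMS, r):
                if "hrv:year" in gterms and not {"hrv", "year"} <= set(gterms):
                    continue
                got = {frozenset(s.fixed_terms)
                       for s in build_candidate_set(ModelSpec("MDML", gterms))}
                assert got == enumerate_subsets_oracle(gterms)

    def test_marginality_violation_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("MDML", ("hrv:year",))


class TestAicc:
    def test_arithmetic_example(self):
        # n=10, k=3, ll=-20: AIC = 46, small-sample correction adds 4
        assert aicc(-20.0, 3, 10) == pytest.approx(50.0)

    def test_limits_to_aic_for_large_n(self):
        assert aicc(-20.0, 3, 10**7) == pytest.approx(46.0, abs=1e-4)

    def test_penalty_monotone_in_k(self):
        assert aicc(-20.0, 4, 30) > aicc(-20.0, 3, 30)

    def test_undefined_when_k_too_large(self):
        with pytest.raises(ValueError):
            aicc(-20.0, 9, 10)


def _mock_fit(terms, a, response="MDML"):
    m = ModelFit(spec=ModelSpec(response, terms), fit=None,
                 k_params=len(terms) + 3, aicc=a)
    return m


class TestConfidenceSet:
    def test_delta_window_without_nesting(self):
        fits = [_mock_fit(("hrv",), 100.0), _mock_fit(("birthdate",), 103.33),
                _mock_fit(("pup_sex",), 107.0)]
        cs = confidence_set(fits)
        assert cs.labels() == ["hrv", "birthdate"]

    def test_complex_model_pruned_by_nested_simpler(self):
        fits = [_mock_fit((), 100.0), _mock_fit(("hrv",), 101.0)]
        cs = confidence_set(fits)
        assert cs.labels() == ["Null"]
        assert cs.pruned[0]["displaced_by"] == "Null"

    def test_single_model_retained(self):
        cs = confidence_set([_mock_fit(("hrv",), 50.0)])
        assert cs.labels() == ["hrv"]

    def test_null_reported_even_when_outside_window(self):
        fits = [_mock_fit(("hrv",), 100.0), _mock_fit((), 140.0)]
        cs = confidence_set(fits)
        assert cs.labels() == ["hrv"]
        assert cs.null_fit.delta_aicc == pytest.approx(40.0)

    def test_matches_brute_force_oracle_on_random_sets(self):
        """Random AICc landscapes over all candidate subsets of up to
        the full 7-term global model: retained sets match the oracle
        exactly, under any input order."""
        rng = np.random.default_rng(0)
        for trial in range(30):
            r = rng.integers(1, len(GLOBAL_TERMS) + 1)
            gterms = tuple(rng.permutation(GLOBAL_TERMS)[:r])
            if "hrv:year" in gterms and not {"hrv", "year"} <= set(gterms):
                gterms = tuple(t for t in gterms if t != "hrv:year")
            specs = build_candidate_set(ModelSpec("MDML", gterms))
            aiccs = rng.uniform(100, 115, len(specs))
            fits = [_mock_fit(s.fixed_terms, a) for s, a in zip(specs, aiccs)]
            order = rng.permutation(len(fits))
            cs = confidence_set([fits[i] for i in order])
            got = {frozenset(m.spec.fixed_terms) for m in cs.retained}
            oracle = prune_oracle([(s.fixed_terms, a)
                                   for s, a in zip(specs, aiccs)])
            assert got == oracle


class TestR2:
    def test_arithmetic_decomposition(self):
        # var_f=1, s2_alpha=1, s2_eps=2 -> R2m=0.25, R2c=0.5, id=33.3%
        class FakeFit:
            sigma2_alpha, sigma2_eps = 1.0, 2.0
            reml = True
            def var_fixed_predictor(self):
                return 1.0
        mf = ModelFit(spec=ModelSpec("MDML", ("hrv",)), fit=FakeFit(),
                      k_params=4, aicc=0.0)
        FakeFit.fe_names = ["intercept", "hrv"]
        FakeFit.params = np.array([0.0, 1.0])
        FakeFit.cov_params = np.eye(2)
        FakeFit.n_obs, FakeFit.k_fixed = 100, 2
        FakeFit.wald_F = lambda self, cols: (1.0, len(cols))
        out = r2_decomposition(mf)
        assert out["r2_marginal"] == pytest.approx(0.25)
        assert out["r2_conditional"] == pytest.approx(0.50)
        assert out["id_variance_share"] == pytest.approx(100 / 3)

    def test_null_model_marginal_zero(self, analysis_table):
        mf = fit_lmm(ModelSpec("MDML", ()), analysis_table, criterion="REML")
        out = r2_decomposition(mf)
        assert out["r2_marginal"] == 0.0
        assert 0 <= out["r2_conditional"] <= 1

    def test_semipartial_matches_squared_correlation(self):
        """Single predictor, no group structure: semipartial R2 equals
        the squared Pearson correlation."""
        rng = np.random.default_rng(3)
        n = 400
        x = rng.normal(size=n)
        y = 0.6 * x + rng.normal(size=n)
        tab = pd.DataFrame(dict(
            id=[f"i{j}" for j in range(n)], year=2013, pup_sex="F",
            device="Polar", hrv_z=x, birthdate_z=0.0, mppm_z=0.0, resp=y))
        mf = fit_lmm(ModelSpec("MDML", ("hrv",)), tab, criterion="REML",
                     response_col="resp")
        out = r2_decomposition(mf)
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert out["terms"]["hrv"]["r2"] == pytest.approx(r2, abs=1e-3)

    def test_bootstrap_ci_brackets_point_estimate(self, analysis_table):
        mf = fit_lmm(ModelSpec("dev_MDML", ("hrv", "birthdate")),
                     analysis_table, criterion="REML")
        out = r2_decomposition(mf, n_boot=50, seed=1)
        for t in out["terms"].values():
            lo, hi = t["ci"]
            assert lo <= hi


class TestFitLmm:
    def test_zero_id_variance_matches_ols(self):
        rng = np.random.default_rng(4)
        n = 300
        tab = pd.DataFrame(dict(
            id=[f"i{j}" for j in range(n)], year=2013, pup_sex="F",
            device="Polar", hrv_z=rng.normal(size=n), birthdate_z=0.0,
            mppm_z=0.0))
        tab["resp"] = 1.0 + 0.5 * tab["hrv_z"] + rng.normal(0, 1, n)
        mf = fit_lmm(ModelSpec("MDML", ("hrv",)), tab, criterion="ML",
                     response_col="resp")
        X = np.column_stack([np.ones(n), tab["hrv_z"]])
        beta = np.linalg.lstsq(X, tab["resp"], rcond=None)[0]
        assert mf.fit.params == pytest.approx(beta, abs=1e-4)

    def test_refit_deterministic(self, analysis_table):
        a = fit_lmm(ModelSpec("MDML", ("year", "mppm")), analysis_table)
        b = fit_lmm(ModelSpec("MDML", ("year", "mppm")), analysis_table)
        assert a.aicc == b.aicc
        assert np.array_equal(a.fit.params, b.fit.params)

    def test_treatment_coding_reference_levels(self, analysis_table):
        X, names = build_design(analysis_table, ("year", "device", "pup_sex"))
        assert "year[2013]" not in names and "device[Polar]" not in names
        assert any(n.startswith("year[") for n in names)
        assert "device[Firstbeat]" in names


class TestKruskalWallis:
    def test_hand_computed_example(self):
        res = kruskal_wallis([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert res.chi2 == pytest.approx(3.857, abs=1e-3)
        assert res.df == 1

    def test_label_permutation_invariant(self):
        v = [3.0, 1.0, 4.0, 1.5, 9.0, 2.6]
        a = kruskal_wallis(v, ["x", "y", "x", "y", "x", "y"])
        b = kruskal_wallis(v, ["y", "x", "y", "x", "y", "x"])
        assert a.chi2 == pytest.approx(b.chi2)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([5.0] * 6, [0, 0, 0, 1, 1, 1])

    def test_agrees_with_rank_formula_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            k = rng.integers(2, 5)
            sizes = rng.integers(3, 8, k)
            vals = np.concatenate([
                np.round(rng.normal(10 * g, 3, s), 1)
                for g, s in enumerate(sizes)])
            groups = np.repeat(np.arange(k), sizes)
            if np.all(vals == vals[0]):
                continue
            res = kruskal_wallis(vals, groups)
            assert res.chi2 == pytest.approx(kw_oracle(vals, groups), abs=1e-10)


class TestRunAnalysis:
    def test_report_structure_covers_all_responses(self, analysis_table):
        report = run_analysis(analysis_table,
                              AnalysisConfig(n_boot_r2=0, seed=0))
        assert set(report["responses"]) == set(RESPONSES)
        for resp, entry in report["responses"].items():
            assert "error" not in entry, f"{resp}: {entry.get('error')}"
            assert entry["confidence_set"][0]["delta_aicc"] == 0.0
            assert entry["null_model"]["model"] == "Null"
        assert set(report["kruskal_wallis"]) == {"MDML", "PDMG"}

    def test_birthdate_only_signal_selected(self):
        """Colonies where birthdate is the only driver of post-partum
        mass select a birthdate-containing best MPPM model in most
        replicates (selection consistency)."""
        from copingcolony import ColonySimParams, simulate_colony
        from copingcolony import hrv as hrvmod
        from copingcolony import metrics
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            params = ColonySimParams(seed=7000 + rep, mass_intercept_sd=2.0,
                                     mppm_birthdate_slope=-12.0,
                                     mppm_resid_sd=4.0)
            caps, hrvt, _ = simulate_colony(params)
            perf = metrics.performance_table(caps)
            table = metrics.build_analysis_table(
                perf, hrvmod.individual_hrv_table(hrvt))
            report = run_analysis(table, AnalysisConfig(
                responses=("MPPM",), n_boot_r2=0))
            best = report["responses"]["MPPM"]["confidence_set"][0]["model"]
            if "birthdate" in best:
                hits += 1
        assert hits >= int(0.8 * n_rep)
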