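# copingcolony

Resting heart-rate-variability (HRV) analysis of stress-coping styles in
capital-breeding colonies, built for lactating grey seals but applicable
to any system where millisecond inter-beat-interval (IBI) telemetry,
behavioural ethogram logs, and repeat capture masses are collected.

## The scientific problem

Stress-coping styles span a proactive–reactive axis: proactive animals
are routine-bound and sympathetically dominated (low resting HRV),
reactive animals are environmentally responsive and parasympathetically
dominated (high resting HRV). Because a fasting, colony-breeding mother
finances lactation entirely from stored reserves, her daily mass loss
rate (MDML) measures reproductive expenditure and her pup's daily mass
gain rate (PDMG) the short-term fitness return. The question this
package's analysis chain answers: do reactive mothers *differ on
average* from proactive mothers in these metrics, or do they merely
*vary more* around the annual population mean — a heteroscedastic
signature detected through the annual deviance modulus
`dev_x(i) = |x_i − mean(x, same year)|`?

The chain, each stage a tested module:

1. **IBI cleaning** (`copingcolony.ibi`) — local-median artefact
   correction (extra beats merged, missed beats interpolated; duration
   conserved), detection of uncorrectable flats and stairs,
   segmentation into non-overlapping 300-s windows, and retention of
   windows with ≥ 95 % Resting IBIs, no locomotion/aggression, and
   ≤ 5 % flats/stairs.
2. **Resting HRV** (`copingcolony.hrv`) — RMSSD
   `sqrt(mean((IBI_{i+1} − IBI_i)^2))` per retained window; seasonal
   resting HRV is the median window RMSSD, individual HRV the median
   across seasons.
3. **Repeatability** (`copingcolony.repeatability`) — the intraclass
   correlation `R = σ²_α / (σ²_α + σ²_ε)` from a random-intercept LMM
   (REML, number of measures as a fixed covariate), with parametric
   bootstrap CIs, a boundary likelihood-ratio test (½χ²₁ mixture), and
   per-individual `R_i = σ²_α / (σ²_α + s²_i)`.
4. **Mass metrics** (`copingcolony.metrics`) — maternal post-partum
   mass (MPPM), MDML, PDMG, mass transfer efficiency (MTE =
   MDML/PDMG), and their annual deviance moduli.
5. **Model inference** (`copingcolony.inference`) — for eight
   standardised responses, all-subsets AICc selection over Gaussian
   random-intercept models (ML likelihoods; marginality respected for
   the HRV×year interaction), a ΔAICc ≤ 6 confidence set pruned of
   complex models beaten by their nested simpler versions, REML refits
   with marginal/conditional R², and Kruskal–Wallis year contrasts.
6. **Synthetic data** (`copingcolony.synthetic`) — IBI traces,
   artefact injection, and whole-colony generators with known ground
   truth (true RMSSD, true repeatability, true heteroscedastic slope),
   so every stage has a parameter-recovery test with no data download.

## Worked example

```python
import copingcolony as cc
from copingcolony import hrv as hrvmod, metrics
from copingcolony.inference import AnalysisConfig, run_analysis

captures, hrv_seasons, truth = cc.simulate_colony(cc.ColonySimParams(seed=7))
print(f"{len(captures)} mother-year rows, {captures['id'].nunique()} mothers; "
      f"true repeatability {truth.true_repeatability:.2f}")

rep = cc.estimate_repeatability(hrv_seasons, n_boot=1000, seed=7)
print(f"R = {rep.R:.3f} +/- {rep.se:.3f}, CI = {rep.ci[0]:.3f}-{rep.ci[1]:.3f}, "
      f"LRT p = {rep.lrt_p:.2g}  (n = {rep.n_obs} seasons, {rep.n_ids} mothers)")

perf = metrics.performance_table(captures)
table = metrics.build_analysis_table(perf, hrvmod.individual_hrv_table(hrv_seasons))
report = run_analysis(table, AnalysisConfig(n_boot_r2=0, seed=7))
for resp in ("MPPM", "dev_MDML"):
    best = report["responses"][resp]["confidence_set"][0]
    print(f"{resp}: best model = {best['model']} "
          f"(AICc {best['aicc']:.1f}, weight {best['weight']:.2f})")
coefs = {c["term"]: c for c in
         report["responses"]["dev_MDML"]["best_model"]["coefficients"]}
c = coefs["hrv"]
print(f"dev_MDML HRV coefficient = {c['estimate']:.3f} "
      f"(SE {c['se']:.3f}, p = {c['p']:.4f})")
```

prints, for this seed:

```
87 mother-year rows, 57 mothers; true repeatability 0.63
R = 0.601 +/- 0.126, CI = 0.308-0.790, LRT p = 0.00025  (n = 55 seasons, 25 mothers)
MPPM: best model = birthdate (AICc 211.4, weight 0.41)
dev_MDML: best model = hrv + device (AICc 243.4, weight 0.28)
dev_MDML HRV coefficient = 0.255 (SE 0.101, p = 0.0119)
```

Reading this: across-year resting HRV is strongly repeatable (the
bootstrap CI excludes zero and the boundary LRT is significant), mass
at parturition is driven by birth date rather than coping style, and
the HRV coefficient in the MDML-deviance model is positive and
significant — reactive (high-HRV) mothers sit further from the annual
mean expenditure than proactive mothers, the heteroscedastic pattern
the generator encodes (`resid_log_sd_hrv_slope > 0`).

A command-line interface mirrors the library
(`copingcolony simulate colony`, `process`, `hrv`, `repeatability`,
`metrics`, `models`, `run`); `copingcolony run --seed 5 --out DIR`
chains every stage on synthetic data and writes a provenance manifest.

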