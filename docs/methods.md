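# Methods

This note documents the models, the numerical choices, and the design
decisions behind `copingcolony`, in the order the pipeline runs.

## IBI cleaning

Heart-rate monitors on free-ranging animals miss beats (two true
intervals fuse into one ~double-length IBI) and generate spurious beats
(one interval splits into short pieces). The correction filter compares
each IBI with the median `m` of up to 10 surrounding beats (an 11-beat
window with the centre excluded, so an artefact cannot mask itself):

* an IBI above `1.3·m` (or above 3000 ms) is interpreted as `k =
  round(ibi/m)` missed beats and replaced by `k` equal sub-intervals;
* an IBI below `0.7·m` (or below 250 ms) is merged with whichever
  neighbour brings the sum closest to `m`, provided the sum lands back
  inside the acceptance band.

Both moves conserve total trace duration exactly, which is the
invariant that makes windowing downstream well-defined. The filter is a
fixed point: a second pass changes nothing (tested). The band factors
0.7/1.3, the 11-beat window and the absolute 250–3000 ms bounds are
conventional RR-series cleaning settings and are configurable
(`CleaningConfig`); the corrected-beat fraction is tracked per window
and traces with more than 5 % corrected beats are flagged for
window-level exclusion. Whether the published 5 % artefact threshold
counts corrected beats as well as flats/stairs is ambiguous, so the two
fractions are tracked and filtered separately.

**Flats and stairs** — runs of invariant IBIs and monotone ramps with
near-constant step, the signature of device-side error concealment —
cannot be corrected, only flagged. Defaults: flats are exact equality
at the 1-ms device precision with run length ≥ 3; stairs allow a ±2 ms
step wobble with run length ≥ 4. On benign quantized white noise these
definitions flag short chance runs in most windows (median ≈ 1 % of
beats), but the flagged fraction never approaches the 5 % drop
threshold, so clean data is not discarded (tested); the thresholds are
deliberately conservative about what they *remove*, not about what
they *mark*.

**Windowing** — non-overlapping half-open 300-s windows; each IBI
belongs to the window containing the time of the R-peak that ends it
(a beat ending exactly on a boundary belongs to the following window);
trailing partial windows are discarded. Recording gaps larger than 5 s
split the trace into segments that are windowed independently from
zero, so telemetry dropouts cannot masquerade as long IBIs.

**Retention** — a window is kept iff ≥ 95 % of its IBIs are labelled
Resting, none carry a high-energy state (Locomotion, Aggression),
≤ 5 % sit in flat/stair runs, and ≤ 5 % were corrected. States are
resolved at each IBI's end time; sub-second behavioural transitions
within a beat are ignored, matching the granularity of video-decoded
ethograms.

## Resting HRV

RMSSD over the window's successive differences (never spanning window
boundaries); seasonal resting HRV is the median window RMSSD, the
individual's across-year HRV the median of seasonal values. Medians of
even counts are midpoints of the two central values. Seasons with
fewer than 3 retained windows are kept but flagged `insufficient`;
excluding them is a caller-side switch, since 3 windows is the minimum
the sampling design tolerates.

## Repeatability

`estimate_repeatability` fits `hrv ~ n_measures + (1 | id)` by REML,
restricted to individuals with ≥ 2 seasons, and reports
`R = σ²_α/(σ²_α + σ²_ε)`. The number-of-measures covariate guards
against sampling effort correlating with the trait. Uncertainty is a
parametric bootstrap (simulate from the fitted model, refit, percentile
2.5/97.5; default 1000 draws, seeded); significance is a likelihood
ratio test of the mixed ML fit against the fixed-effects-only ML fit
with the null an equal mixture of a point mass at 0 and χ²₁, because
the variance is tested on its boundary. Per-individual repeatability
uses conditional (BLUP-adjusted) residuals: `R_i = σ²_α/(σ²_α + s²_i)`
— "how consistent this seal is, relative to how different seals are
from each other". Conditional rather than marginal residuals are the
natural reading of within-individual scatter; the choice is isolated
in `individual_Ri` and switchable by passing a different fit.

### The LMM engine

All mixed models are Gaussian random intercepts with a single grouping
factor, so the package fits them with a dedicated profiled solver
(`lmm.py`): for a variance ratio `λ = σ²_α/σ²_ε` the marginal
covariance is block diagonal, GLS and the profiled (restricted)
likelihood are closed-form, and the fit is a one-dimensional bounded
search over `log λ` (tolerance 1e-12, boundary `λ = 0` checked
explicitly). This makes the ~20k bootstrap refits in the test suite
cheap, is exactly deterministic, and reproduces ANOVA
method-of-moments variance components on balanced designs to 1e-6
relative (tested). statsmodels `MixedLM` — the general-purpose
implementation — serves as an independent cross-check in the tests,
never as the implementation. Aliased design columns (e.g. a device
factor fully confounded with year) are dropped greedily in column
order and recorded on the fit. Coefficient p-values are Wald z tests.

## Mass metrics

From two captures at days ~3 and ~14–16 of lactation:
`MDML = (cap1_mass − cap2_mass)/Δdays`, `PDMG` likewise for the pup,
`MPPM = cap1_mass + MDML · (cap1_date − birthdate)` (linear
extrapolation to parturition), `MTE = MDML/PDMG` (missing when the pup
did not gain). The annual deviance modulus is `|x_i − mean(x, year)|`;
a singleton year gives 0 and a degenerate flag. Modelling responses are
z-standardised with the sample (n−1) SD over the whole table; deviance
moduli are natural-log-transformed first with offset ε = 0.01 (moduli
can be exactly zero), then z-standardised — raw scale, log, z, in that
order.

## Model inference

Eight responses (four metrics + four deviance moduli), global fixed
terms {HRV, birthdate, pup sex, year, device, MPPM, HRV×year} with
random intercept per mother. MPPM is not offered as a predictor of
itself or of its own deviance modulus. HRV enters as the individual's
across-year median (z), not the seasonal value, to avoid confounding
the ID random effect. Candidates are all subsets respecting
marginality (interaction only with both main effects): 80 models, 40
for the MPPM responses.

* **Likelihoods**: ML for AICc comparison across fixed-effect
  structures (REML likelihoods are not comparable there); REML refit
  of retained models for reported coefficients.
* **AICc**: `−2ℓ + 2k + 2k(k+1)/(n−k−1)` with `k` counting linearly
  independent fixed coefficients plus both variance components.
* **Confidence set**: ΔAICc ≤ 6, then Richards-style pruning — a model
  is discarded when some simpler model nested within it (evaluated
  against the whole preliminary set, hence order-independent) has
  equal-or-lower AICc. Ties break by fewer parameters, then fewer
  requested terms (so an aliased extra factor loses), then term order.
  Akaike weights are normalised over the full candidate set. The null
  model's row is always reported for comparison.
* **R²**: marginal `σ²_f/(σ²_f+σ²_α+σ²_ε)` with `σ²_f` the sample
  variance of the fixed predictor; conditional adds `σ²_α`; the ID
  variance share `σ²_α/(σ²_α+σ²_ε)` is reported as a percentage.
  Per-term semipartial R² uses the Wald-F form
  `df₁F/(df₁F + df₂)`, `df₂ = n − k_fixed` — a documented
  simplification of adjusted-denominator-df semipartial R² — with
  percentile CIs from a seeded parametric bootstrap.
* **Year contrasts**: tie-corrected Kruskal–Wallis tests of the raw
  daily rates by year (scipy implementation, validated against the
  rank formula to 1e-10).
* Where HRV and birthdate are both retained, an HRV×birthdate variant
  of the best model is refitted and its AICc reported alongside.

## Synthetic data: what it emulates, and what it does not

`IBISimParams` draws beats around a mean IBI (default 900 ms) with
white or AR(1) noise; with white noise of SD `s` the true RMSSD is
`s·√2`, with AR(1) coefficient φ it is `s·√(2(1−φ))`. The noise family
is a stand-in — nothing is claimed about real seal IBI dynamics.
Behaviour is an alternating Resting/active two-state renewal process
with exponential bout lengths (defaults 600 s resting / 120 s active,
matching a > 60 % resting activity budget). IBIs are quantized to
whole milliseconds as devices report them.

`ArtefactSpec` injects missed beats (adjacent IBIs merged), extra
beats (an IBI split in two), flats and stairs, each ledgered with its
output position; merges and splits conserve duration to the
millisecond.

`ColonySimParams` defaults encode the target study design: 57 mothers
over 5 seasons, presence probability 0.30 with every mother appearing
at least once (E[rows] ≈ 95, ~25 multi-season mothers), latent
individual resting HRV lognormal (μ = log 20 ms, σ = 0.45 — RMSSD is
positive and right-skewed), season-to-season wobble set so the true
across-year repeatability is 0.63, retained-window counts lognormal
around a median of 32 clipped to [3, 333]. Masses are generated on the
kg scale (MPPM ≈ 185 ± 18 kg individual intercept, 86–88 % ID share;
MDML ≈ 3.2, PDMG ≈ 1.8 kg/day with year effects peaking in season 3)
and capture masses are back-computed from the generated rates, so the
metric arithmetic round-trips exactly against stored truth.

The headline mechanism is the residual-SD model
`log sd = a + b·z(HRV)` shared by the daily rates, with defaults
`a = log 0.55`, `b = 0.6`. These were calibrated jointly with the
fixed-effect slopes (MPPM 0.35/0.28 kg·day⁻¹ per SD) so that (i) the
within-year variance decomposition of MDML resembles the target
analysis (fixed-effects R² ≈ 0.35–0.45, realized HRV coefficients in
the deviance models ≈ 0.31–0.34 on the z scale) and (ii) the
heteroscedastic signal is detectable at the study's sample size in
≥ 80 % of replicates while slope-zero colonies stay at the nominal 5 %
false-positive rate. Note the information ceiling here: the deviance
modulus folds the residual through `log|N(0,σ)|`, whose SD (≈ 1.11)
does not shrink with effect size, so at n ≈ 95 a log-SD slope of 0.4
yields only ~50 % detection power no matter how clean the rest of the
generator is; 0.6 is the weakest slope with comfortable power at this
design.

`hrv_family="gaussian"` draws the latent trait from a normal with the
same mean and variance. This is the correctly specified case for
validating the REML estimator, and the recovery and coverage tests use
it. A documented limitation found while building those tests: with the
lognormal family, 25 sampled individuals give a mean repeatability
estimate ≈ 0.04 below the population truth — ≈ 0.015 of that is the
ordinary Jensen bias of the variance-ratio estimator (present under
Gaussian truth too) and the rest is finite-sample attenuation from the
skewed trait distribution. Passing recovery tests under the Gaussian
family therefore does not certify unbiasedness for strongly skewed
real traits; for real data this argues for reporting bootstrap CIs,
which remain well-calibrated (coverage ≈ 95 % in both families).

The generator does not simulate at-sea foraging, weather, pup
behaviour, observer error in ethogram decoding, or device-specific
artefact spectra; device type is assigned deterministically by year
(first two seasons Polar, later Firstbeat), which makes it aliased
with year in the models — exactly the collinearity structure the
selection machinery must survive (aliased columns dropped, ties
resolved toward the simpler model).

## Problem sizes in the test suite

Recovery tests run 100 simulated colonies (≈ 95 rows each) with
200-draw bootstraps, 50 IBI traces for the RMSSD closed form, and 10
corrupted traces for the round-trip check; the full suite completes in
about a minute on one core. These sizes give Monte-Carlo error
comfortably inside the asserted tolerances (e.g. SE of the mean
repeatability over 100 colonies ≈ 0.011 against a 0.03 band) while
keeping the suite fast; `scripts/acceptance.py` uses the full
1000-draw bootstrap at the single-colony scale.

## Known limitations

* One grouping factor only; no random slopes, no non-Gaussian
  families, no multi-trait repeatability.
* RMSSD is the only HRV index (no SDNN, pNN50, or spectral measures).
* Semipartial R² uses the simplified `df₂ = n − k_fixed`; adjusted
  denominator degrees of freedom would shift CIs slightly for small n.
* The deviance modulus confounds residual-SD effects with any
  unmodelled mean-structure misfit; the simulation shows the intended
  signal dominates under the default calibration, not under arbitrary
  ones.
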