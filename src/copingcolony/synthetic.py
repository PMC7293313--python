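"""Synthetic heart-rate telemetry and breeding-colony data with known truth.

Three generators cover the full analysis chain:

* :func:`simulate_ibi_trace` — one seal-season inter-beat-interval (IBI)
  trace with an accompanying behavioural ethogram log. Beats are drawn
  around a mean IBI with white or AR(1) noise; the behaviour log is an
  alternating Resting/active two-state renewal process with
  exponential bout lengths, reflecting the mostly-resting activity
  budget of a fasting breeding female.
* :func:`inject_artefacts` — telemetry corruption: missed beats (two
  adjacent IBIs merged into their sum), spurious extra beats (one IBI
  split in two), plus uncorrectable "flats" (runs of invariant IBIs)
  and "stairs" (monotone ramps), each logged in a ledger.
* :func:`simulate_colony` — a multi-year colony of mothers with latent
  individual resting HRV (lognormal across individuals, so positive and
  right-skewed), season-to-season wobble that sets the true across-year
  repeatability, and mass metrics whose residual standard deviation
  scales log-linearly with standardised HRV — the heteroscedastic
  signal the downstream deviance-modulus models are built to detect.

All generators are deterministic given (params, seed): each logical
component draws from its own stream spawned from the master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IBISimParams",
    "ArtefactSpec",
    "ColonySimParams",
    "GroundTruth",
    "simulate_ibi_trace",
    "inject_artefacts",
    "simulate_colony",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class IBISimParams:
    """Settings for one synthetic IBI trace.

    With white noise of standard deviation ``noise_sd`` the true window
    RMSSD is ``noise_sd * sqrt(2)``; with AR(1) noise of coefficient
    ``phi`` it is ``noise_sd * sqrt(2 * (1 - phi))``.
    """

    mean_ibi: float = 900.0          # ms
    noise_sd: float = 15.0           # ms
    noise_model: str = "white"       # "white" | "ar1"
    ar1_coef: float = 0.0
    duration: float = 3000.0         # s
    rest_bout_mean: float = 600.0    # s
    active_bout_mean: float = 120.0  # s
    active_states: tuple[str, ...] = ("Alert", "Comfort", "Nursing")
    quantize_ms: bool = True         # devices report whole milliseconds
    seed: int = 0

    def validate(self) -> None:
        if self.mean_ibi <= 0:
            raise ValueError("mean_ibi must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.rest_bout_mean <= 0 or self.active_bout_mean <= 0:
            raise ValueError("bout means must be positive")
        if self.noise_model not in ("white", "ar1"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if not (0.0 <= self.ar1_coef < 1.0):
            raise ValueError("ar1_coef must be in [0, 1)")


@dataclass
class ArtefactSpec:
    """Corruption plan for :func:`inject_artefacts`."""

    p_missed_beat: float = 0.0
    p_extra_beat: float = 0.0
    n_flats: int = 0
    flat_len: int = 5
    n_stairs: int = 0
    stair_len: int = 6
    stair_step: float = 15.0  # ms
    seed: int = 0

    def validate(self, n_beats: int) -> None:
        for p in (self.p_missed_beat, self.p_extra_beat):
            if not (0.0 <= p <= 1.0):
                raise ValueError("artefact probabilities must be in [0, 1]")
        if self.flat_len < 2 or self.stair_len < 2:
            raise ValueError("run lengths must be >= 2")
        if self.n_flats * self.flat_len + self.n_stairs * self.stair_len > n_beats:
            raise ValueError("requested flat/stair runs exceed trace length")


@dataclass
class ColonySimParams:
    """Generative settings for a multi-year breeding colony.

    Defaults emulate the study design the package targets: 57 mothers
    followed over 5 breeding seasons with roughly a third sampled each
    year (about 95 mother-year rows, about 25 mothers with repeat
    seasons), latent resting HRV repeatable across years at R = 0.63,
    and kg-scale mass metrics whose year profile peaks in the third
    season. ``hrv_within_sd=None`` resolves to the value implying
    ``target_repeatability``.
    """

    n_ids: int = 57
    n_years: int = 5
    p_present: float = 0.30
    # latent individual resting HRV (ms), lognormal across individuals
    # by default (RMSSD is positive and right-skewed); "gaussian" draws
    # a normal latent with the same mean and variance, the correctly
    # specified case for validating the Gaussian REML estimator
    hrv_mu: float = math.log(20.0)
    hrv_sigma: float = 0.45
    hrv_family: str = "lognormal"
    hrv_within_sd: float | None = None
    target_repeatability: float = 0.63
    # maternal post-partum mass (kg)
    mppm_mean: float = 185.0
    mass_intercept_sd: float = 18.0
    mppm_birthdate_slope: float = -5.0  # kg per standardised day
    mppm_resid_sd: float = 7.0
    # daily rates (kg/day)
    mdml_intercept: float = 3.2
    pdmg_intercept: float = 1.8
    year_effects: tuple[float, ...] = (0.0, 0.2, 0.6, 0.25, 0.1)
    birthdate_slope: float = 0.10        # kg/day per standardised day
    mppm_slope_mdml: float = 0.35        # kg/day per standardised kg
    mppm_slope_pdmg: float = 0.28
    # residual SD model: log(sd) = a + b * z(HRV), shared by MDML/PDMG;
    # calibrated so the heteroscedastic residual carries the bulk of
    # within-year rate variation and the coping-style signal is
    # detectable at the study's sample size
    resid_log_sd_intercept: float = math.log(0.55)
    resid_log_sd_hrv_slope: float = 0.6
    # schedule
    birthdate_mean_doy: float = 318.0
    birthdate_sd: float = 9.0
    cap1_offset_days: int = 3
    cap2_offset_days: int = 14
    pup_birth_mass_mean: float = 15.0
    pup_birth_mass_sd: float = 1.2
    first_year: int = 2013
    n_polar_years: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_ids < 2:
            raise ValueError("n_ids must be >= 2")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if not (0.0 < self.p_present <= 1.0):
            raise ValueError("p_present must be in (0, 1]")
        if len(self.year_effects) < self.n_years:
            raise ValueError("year_effects shorter than n_years")
        for name in ("hrv_sigma", "mass_intercept_sd", "mppm_resid_sd",
                     "birthdate_sd", "pup_birth_mass_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hrv_within_sd is not None and self.hrv_within_sd < 0:
            raise ValueError("hrv_within_sd must be non-negative")
        if not (0.0 < self.target_repeatability < 1.0):
            raise ValueError("target_repeatability must be in (0, 1)")
        if self.hrv_family not in ("lognormal", "gaussian"):
            raise ValueError(f"unknown hrv_family {self.hrv_family!r}")

    def between_individual_hrv_var(self) -> float:
        s2 = self.hrv_sigma**2
        return (math.exp(s2) - 1.0) * math.exp(2.0 * self.hrv_mu + s2)

    def resolved_within_sd(self) -> float:
        """Season-to-season SD; if unset, the value implying the target
        across-year repeatability given the lognormal between-ID
        variance."""
        if self.hrv_within_sd is not None:
            return self.hrv_within_sd
        vb = self.between_individual_hrv_var()
        r = self.target_repeatability
        return math.sqrt(vb * (1.0 - r) / r)

    def true_repeatability(self) -> float:
        vb = self.between_individual_hrv_var()
        w = self.resolved_within_sd()
        return vb / (vb + w**2)


@dataclass
class GroundTruth:
    """What the generator knows that the analysis must recover."""

    true_rmssd: float | None = None
    latent_hrv: pd.Series | None = None
    true_repeatability: float | None = None
    fixed_coefs: dict = field(default_factory=dict)
    resid_log_sd_coefs: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# IBI trace + behaviour log


def _behaviour_log(params: IBISimParams, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    t = 0.0
    resting = True
    while t < params.duration:
        mean = params.rest_bout_mean if resting else params.active_bout_mean
        length = rng.exponential(mean)
        end = min(t + length, params.duration)
        state = "Resting" if resting else str(rng.choice(params.active_states))
        rows.append((t, end, state))
        t = end
        resting = not resting
    return pd.DataFrame(rows, columns=["start_s", "end_s", "state"])


def simulate_ibi_trace(params: IBISimParams):
    """Generate one clean seal-season IBI trace and its ethogram log.

    Returns ``(trace, behaviour_log, truth)`` where ``trace`` is an
    :class:`~copingcolony.ibi.IBITrace`, the log partitions
    ``[0, duration]`` into alternating Resting/active bouts, and
    ``truth`` carries the closed-form RMSSD of the noise process.
    """
    from .ibi import IBITrace  # local import to avoid a cycle

    params.validate()
    master = np.random.default_rng(params.seed)
    rng_beats, rng_beh = master.spawn(2)

    n_guess = int(params.duration * 1000.0 / params.mean_ibi * 1.2) + 16
    if params.noise_model == "white" or params.ar1_coef == 0.0:
        noise = rng_beats.normal(0.0, params.noise_sd, size=n_guess)
        true_rmssd = params.noise_sd * math.sqrt(2.0)
    else:
        phi = params.ar1_coef
        innov = rng_beats.normal(0.0, params.noise_sd * math.sqrt(1 - phi**2), size=n_guess)
        noise = np.empty(n_guess)
        noise[0] = rng_beats.normal(0.0, params.noise_sd)
        for i in range(1, n_guess):
            noise[i] = phi * noise[i - 1] + innov[i]
        true_rmssd = params.noise_sd * math.sqrt(2.0 * (1 - phi))
    ibis = params.mean_ibi + noise
    ibis = np.clip(ibis, 1.0, None)
    if params.quantize_ms:
        ibis = np.round(ibis)
    cum = np.cumsum(ibis) / 1000.0
    n_keep = int(np.searchsorted(cum, params.duration, side="right"))
    while n_keep >= len(ibis):  # rare: noise made beats long enough to run out
        extra = rng_beats.normal(0.0, params.noise_sd, size=256) + params.mean_ibi
        if params.quantize_ms:
            extra = np.round(np.clip(extra, 1.0, None))
        ibis = np.concatenate([ibis, extra])
        cum = np.cumsum(ibis) / 1000.0
        n_keep = int(np.searchsorted(cum, params.duration, side="right"))
    ibis = ibis[:n_keep]

    trace = IBITrace.from_ibis(ibis, seal_id="SIM", year=0)
    log = _behaviour_log(params, rng_beh)
    truth = GroundTruth(true_rmssd=true_rmssd)
    return trace, log, truth


# ---------------------------------------------------------------------------
# artefact injection


def inject_artefacts(trace, spec: ArtefactSpec):
    """Corrupt a clean trace; returns ``(corrupted_trace, ledger)``.

    A missed beat merges two adjacent IBIs into their sum; an extra
    beat splits one IBI in two — both conserve total duration. Flat and
    stair runs overwrite IBI values in place. The ledger (DataFrame)
    records every event with its position in the *output* trace.
    """
    from .ibi import IBITrace

    if trace.corrections:
        raise ValueError("inject_artefacts expects an uncorrected trace")
    ibis = list(trace.ibi_ms)
    spec.validate(len(ibis))
    rng = np.random.default_rng(spec.seed)
    ledger: list[dict] = []

    # merges/splits, processed in descending index order so earlier
    # positions stay valid
    n0 = len(ibis)
    u = rng.random(n0)
    missed = set(np.nonzero(u < spec.p_missed_beat)[0].tolist())
    u2 = rng.random(n0)
    extra = set(np.nonzero(u2 < spec.p_extra_beat)[0].tolist())
    extra -= missed
    # a merge consumes index i and i+1: drop conflicting selections
    missed = {i for i in missed if i + 1 < n0 and (i + 1) not in missed and i + 1 not in extra}
    events = sorted(
        [(i, "missed_beat") for i in missed] + [(i, "extra_beat") for i in extra],
        reverse=True,
    )
    for i, kind in events:
        if kind == "missed_beat":
            merged = ibis[i] + ibis[i + 1]
            ledger.append({"kind": "missed_beat", "index": i,
                           "original": (ibis[i], ibis[i + 1]), "value": merged})
            ibis[i : i + 2] = [merged]
        else:
            f = rng.uniform(0.35, 0.65)
            a = ibis[i] * f
            ledger.append({"kind": "extra_beat", "index": i,
                           "original": (ibis[i],), "value": (a, ibis[i] - a)})
            ibis[i : i + 1] = [a, ibis[i] - a]

    # flats and stairs on the post-merge/split array, non-overlapping
    taken: set[int] = set()

    def _free_start(run_len: int) -> int | None:
        for _ in range(200):
            s = int(rng.integers(0, max(len(ibis) - run_len, 1)))
            if all(j not in taken for j in range(s - 1, s + run_len + 1)):
                taken.update(range(s, s + run_len))
                return s
        return None

    for _ in range(spec.n_flats):
        s = _free_start(spec.flat_len)
        if s is None:
            continue
        v = round(ibis[s])
        for j in range(s, s + spec.flat_len):
            ibis[j] = float(v)
        ledger.append({"kind": "flat", "index": s, "length": spec.flat_len, "value": v})
    for _ in range(spec.n_stairs):
        s = _free_start(spec.stair_len)
        if s is None:
            continue
        sign = 1.0 if rng.random() < 0.5 else -1.0
        base = round(ibis[s])
        for j in range(spec.stair_len):
            ibis[s + j] = float(base + sign * spec.stair_step * j)
        ledger.append({"kind": "stair", "index": s, "length": spec.stair_len,
                       "value": base, "step": sign * spec.stair_step})

    out = IBITrace.from_ibis(np.asarray(ibis, dtype=float),
                             seal_id=trace.seal_id, year=trace.year)
    ledger_df = pd.DataFrame(ledger, columns=["kind", "index", "length",
                                              "original", "value", "step"])
    return out, ledger_df


# ---------------------------------------------------------------------------
# colony


def simulate_colony(params: ColonySimParams):
    """Generate (capture_table, hrv_table, truth) for a breeding colony.

    Capture dates and masses are back-computed from the generated daily
    rates, so the downstream rate/post-partum-mass arithmetic
    round-trips exactly against the stored truth.
    """
    params.validate()
    master = np.random.default_rng(params.seed)
    rng_presence, rng_hrv, rng_mass, rng_sched = master.spawn(4)

    ids = [f"F{i:03d}" for i in range(1, params.n_ids + 1)]
    years = [params.first_year + j for j in range(params.n_years)]

    present = rng_presence.random((params.n_ids, params.n_years)) < params.p_present
    for i in range(params.n_ids):  # every known mother appears at least once
        if not present[i].any():
            present[i, int(rng_presence.integers(params.n_years))] = True

    if params.hrv_family == "lognormal":
        latent = np.exp(rng_hrv.normal(params.hrv_mu, params.hrv_sigma,
                                       size=params.n_ids))
    else:  # gaussian with the same mean and between-individual variance
        mean = math.exp(params.hrv_mu + params.hrv_sigma**2 / 2.0)
        latent = rng_hrv.normal(mean,
                                math.sqrt(params.between_individual_hrv_var()),
                                size=params.n_ids)
        latent = np.clip(latent, 0.5, None)
    within_sd = params.resolved_within_sd()
    ind_mass = rng_mass.normal(0.0, params.mass_intercept_sd, size=params.n_ids)
    pup_sexes = rng_sched.choice(["F", "M"], size=(params.n_ids, params.n_years))

    z_hrv = (latent - latent.mean()) / latent.std(ddof=1)

    cap_rows, hrv_rows = [], []
    for i, sid in enumerate(ids):
        for j, year in enumerate(years):
            if not present[i, j]:
                continue
            bd = float(np.round(rng_sched.normal(params.birthdate_mean_doy,
                                                 params.birthdate_sd)))
            zbd = (bd - params.birthdate_mean_doy) / params.birthdate_sd
            season_hrv = max(latent[i] + rng_hrv.normal(0.0, within_sd), 0.5)
            n_windows = int(np.clip(np.round(np.exp(rng_hrv.normal(math.log(32.0), 1.0))),
                                    3, 333))

            mppm = (params.mppm_mean + ind_mass[i]
                    + params.mppm_birthdate_slope * zbd
                    + rng_mass.normal(0.0, params.mppm_resid_sd))
            zm = (mppm - params.mppm_mean) / max(params.mass_intercept_sd, 1e-9)
            resid_sd = math.exp(params.resid_log_sd_intercept
                                + params.resid_log_sd_hrv_slope * z_hrv[i])
            mdml = (params.mdml_intercept + params.year_effects[j]
                    + params.birthdate_slope * zbd
                    + params.mppm_slope_mdml * zm
                    + rng_mass.normal(0.0, resid_sd))
            pup_birth = rng_mass.normal(params.pup_birth_mass_mean,
                                        params.pup_birth_mass_sd)
            pdmg_mean = (params.pdmg_intercept + params.year_effects[j] * 0.75
                         + params.birthdate_slope * 0.7 * zbd
                         + params.mppm_slope_pdmg * zm)
            # extreme negative pup-growth draws would imply a negative
            # late-lactation pup mass; redraw the rare offending residual
            for _ in range(50):
                pdmg = pdmg_mean + rng_mass.normal(0.0, resid_sd)
                if pup_birth + pdmg * params.cap2_offset_days > 1.0:
                    break

            cap1 = bd + params.cap1_offset_days
            cap2 = bd + params.cap2_offset_days
            cap1_mass = mppm - mdml * params.cap1_offset_days
            cap2_mass = mppm - mdml * params.cap2_offset_days
            pup1 = pup_birth + pdmg * params.cap1_offset_days
            pup2 = pup_birth + pdmg * params.cap2_offset_days
            device = "Polar" if j < params.n_polar_years else "Firstbeat"

            cap_rows.append(dict(id=sid, year=year, birthdate_doy=bd,
                                 pup_sex=pup_sexes[i, j], device=device,
                                 cap1_date=cap1, cap1_mass_kg=cap1_mass,
                                 cap2_date=cap2, cap2_mass_kg=cap2_mass,
                                 pup1_mass_kg=pup1, pup2_mass_kg=pup2))
            hrv_rows.append(dict(id=sid, year=year,
                                 resting_hrv_ms=season_hrv,
                                 n_windows=n_windows,
                                 insufficient_flag=n_windows < 3))

    captures = pd.DataFrame(cap_rows)
    hrv_table = pd.DataFrame(hrv_rows)
    truth = GroundTruth(
        latent_hrv=pd.Series(latent, index=ids, name="latent_hrv_ms"),
        true_repeatability=params.true_repeatability(),
        fixed_coefs=dict(
            mppm_birthdate_slope=params.mppm_birthdate_slope,
            mdml_intercept=params.mdml_intercept,
            pdmg_intercept=params.pdmg_intercept,
            year_effects=tuple(params.year_effects[: params.n_years]),
            birthdate_slope=params.birthdate_slope,
            mppm_slope_mdml=params.mppm_slope_mdml,
            mppm_slope_pdmg=params.mppm_slope_pdmg,
        ),
        resid_log_sd_coefs=(params.resid_log_sd_intercept,
                            params.resid_log_sd_hrv_slope),
    )
    return captures, hrv_table, truth
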