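"""Maternal-expenditure mass metrics and their annual deviance moduli.

For a capital breeder that fasts through lactation, two captures (early
and late) give four proxies of expenditure and short-term fitness:

* MPPM — maternal post-partum mass (kg): first-capture mass
  extrapolated back to the parturition date using the daily loss rate.
* MDML — maternal daily mass loss rate (kg/day).
* PDMG — pup daily mass gain rate (kg/day).
* MTE — mass transfer efficiency, the ratio MDML : PDMG (defined only
  when the pup gained mass).

The deviance modulus ``|x_i - mean(x, same year)|`` measures how far a
mother sits from her cohort's annual mean — the response that carries
the coping-style heteroscedasticity signal. Modelling responses are
standardised (z); deviance moduli are log-transformed first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "daily_rates",
    "maternal_postpartum_mass",
    "mass_transfer_efficiency",
    "annual_deviance_modulus",
    "transform_response",
    "performance_table",
    "build_analysis_table",
]

DEFAULT_LOG_OFFSET = 0.01


def daily_rates(rec) -> tuple[float, float]:
    """(MDML, PDMG) in kg/day from a capture record (mapping or row
    with cap1_date, cap2_date, cap?_mass_kg, pup?_mass_kg)."""
    span = float(rec["cap2_date"]) - float(rec["cap1_date"])
    if span <= 0:
        raise ValueError("cap2_date must be after cap1_date")
    mdml = (float(rec["cap1_mass_kg"]) - float(rec["cap2_mass_kg"])) / span
    pdmg = (float(rec["pup2_mass_kg"]) - float(rec["pup1_mass_kg"])) / span
    return mdml, pdmg


def maternal_postpartum_mass(rec, mdml: float) -> float:
    """Mass at parturition: first-capture mass plus the loss accrued
    between birth and first capture at the daily loss rate."""
    lag = float(rec["cap1_date"]) - float(rec["birthdate_doy"])
    if lag < 0:
        raise ValueError("cap1_date before birthdate")
    return float(rec["cap1_mass_kg"]) + mdml * lag


def mass_transfer_efficiency(mdml: float, pdmg: float) -> float:
    """MDML / PDMG; NaN when the pup did not gain mass."""
    if pdmg <= 0:
        return float("nan")
    return mdml / pdmg


def annual_deviance_modulus(df: pd.DataFrame, col: str,
                            year_col: str = "year") -> pd.Series:
    """Per-record |value - annual mean| for one metric; a singleton
    year gives 0 (degenerate — flagged by :func:`performance_table`)."""
    annual_mean = df.groupby(year_col)[col].transform("mean")
    return (df[col] - annual_mean).abs()


def transform_response(values, kind: str = "z",
                       eps: float = DEFAULT_LOG_OFFSET) -> np.ndarray:
    """Standardise a response over the whole analysis table.

    ``z``: (x - mean) / sd with the sample (n-1) standard deviation.
    ``log_then_z``: z applied to log(x + eps); the offset keeps exact
    zeros (a record equal to its annual mean) finite.
    """
    x = np.asarray(values, dtype=float)
    if kind == "log_then_z":
        if np.any(x < 0):
            raise ValueError("log transform requires non-negative values")
        x = np.log(x + eps)
    elif kind != "z":
        raise ValueError(f"unknown transform {kind!r}")
    mask = np.isfinite(x)
    sd = np.std(x[mask], ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zero variance: cannot standardise")
    return (x - np.mean(x[mask])) / sd


def performance_table(captures: pd.DataFrame,
                      eps: float = DEFAULT_LOG_OFFSET) -> pd.DataFrame:
    """One row per mother-year with the four proxies, their annual
    deviance moduli, and degenerate-year flags."""
    rows = []
    for _, rec in captures.iterrows():
        mdml, pdmg = daily_rates(rec)
        mppm = maternal_postpartum_mass(rec, mdml)
        rows.append(dict(id=rec["id"], year=int(rec["year"]),
                         birthdate_doy=float(rec["birthdate_doy"]),
                         pup_sex=rec["pup_sex"], device=rec["device"],
                         mppm=mppm, mdml=mdml, pdmg=pdmg,
                         mte=mass_transfer_efficiency(mdml, pdmg)))
    perf = pd.DataFrame(rows)
    year_sizes = perf.groupby("year")["id"].transform("count")
    perf["degenerate_year"] = year_sizes == 1
    for col in ("mppm", "mdml", "pdmg", "mte"):
        perf[f"dev_{col}"] = annual_deviance_modulus(perf, col)
    return perf


def build_analysis_table(perf: pd.DataFrame, individual_hrv: pd.DataFrame,
                         eps: float = DEFAULT_LOG_OFFSET) -> pd.DataFrame:
    """Merge performance metrics with individual across-year HRV and add
    the standardised modelling columns.

    Raw responses get ``z_`` columns; deviance moduli get ``zlog_``
    columns (log then z, matching the transform order used downstream).
    Continuous covariates (HRV, birthdate, MPPM) get ``_z`` suffixes.
    """
    table = perf.merge(individual_hrv[["id", "hrv_ms"]], on="id", how="inner")
    for col in ("hrv_ms", "birthdate_doy", "mppm"):
        table[col.replace("_ms", "").replace("_doy", "") + "_z"] = transform_response(table[col], "z")
    for col in ("mppm", "mdml", "pdmg", "mte"):
        table[f"z_{col}"] = transform_response(table[col], "z")
        table[f"zlog_dev_{col}"] = transform_response(table[f"dev_{col}"],
                                                      "log_then_z", eps=eps)
    return table
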