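"""Time-domain heart-rate-variability metrics and their aggregation.

RMSSD — the root mean square of successive differences between
inter-beat intervals — is the single HRV index used throughout: it is
parasympathetically driven, robust under free-running field conditions,
and easy to interpret. Window RMSSDs aggregate to a seal-season resting
HRV (median over retained 300-s windows) and then to an individual
across-year value (median over seasons).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["rmssd", "SealSeasonHRV", "IndividualHRV", "season_resting_hrv",
           "across_year_hrv", "individual_hrv_table"]

MIN_WINDOWS_SUFFICIENT = 3


def rmssd(ibis) -> float:
    """RMSSD of an ordered IBI sequence (ms).

    ``sqrt(mean((ibi[i+1] - ibi[i])**2))`` over the n-1 successive
    differences. Differences never span window boundaries — callers
    pass one window's beats at a time.
    """
    x = np.asarray(ibis, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("rmssd requires at least two IBIs")
    if np.any(x <= 0):
        raise ValueError("all IBIs must be positive")
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))


@dataclass
class SealSeasonHRV:
    seal_id: str
    year: int
    resting_hrv: float      # ms, median window RMSSD
    n_windows: int
    window_rmssd: list
    insufficient: bool      # fewer than 3 retained windows
    missing_reason: str = ""


@dataclass
class IndividualHRV:
    seal_id: str
    hrv: float  # ms, median of seasonal values
    n_years: int


def season_resting_hrv(window_rmssds, seal_id: str, year: int) -> SealSeasonHRV:
    """Median RMSSD over a seal-season's retained windows.

    Zero retained windows yields a missing-value record with a reason;
    fewer than three is kept but flagged insufficient.
    """
    vals = [float(v) for v in window_rmssds if np.isfinite(v)]
    if not vals:
        return SealSeasonHRV(seal_id, year, np.nan, 0, [], True,
                             missing_reason="no_retained_windows")
    return SealSeasonHRV(seal_id, year, float(np.median(vals)), len(vals),
                         vals, insufficient=len(vals) < MIN_WINDOWS_SUFFICIENT)


def across_year_hrv(seasons: list[SealSeasonHRV]) -> IndividualHRV:
    """Median of an individual's seasonal resting-HRV values."""
    if not seasons:
        raise ValueError("need at least one season")
    vals = [s.resting_hrv for s in seasons if np.isfinite(s.resting_hrv)]
    if not vals:
        raise ValueError("no non-missing seasonal values")
    sid = seasons[0].seal_id
    return IndividualHRV(sid, float(np.median(vals)), n_years=len(vals))


def individual_hrv_table(season_table: pd.DataFrame,
                         id_col: str = "id",
                         value_col: str = "resting_hrv_ms") -> pd.DataFrame:
    """Collapse a seal-season HRV table to one across-year median row
    per individual: columns (id, hrv_ms, n_years)."""
    g = season_table.groupby(id_col)[value_col]
    out = pd.DataFrame({"hrv_ms": g.median(), "n_years": g.count()})
    return out.reset_index().rename(columns={id_col: "id"})
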