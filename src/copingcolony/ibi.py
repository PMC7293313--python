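"""Inter-beat-interval (IBI) trace cleaning, windowing and retention filters.

Raw heart-rate telemetry from animal-borne monitors contains artefacts:
missed beats (two true intervals fused into one long IBI), spurious
extra beats (one interval split into short pieces), and uncorrectable
shapes — "flats" (runs of invariant IBIs) and "stairs" (monotone ramps
with near-constant step) produced by device error-correction firmware.

The pipeline here is:

1. :func:`correct_artefacts` — a local-median filter deletes extra
   beats (merging extreme-short IBIs with a neighbour) and interpolates
   missed beats (splitting extreme-long IBIs into equal parts). Both
   operations conserve total trace duration.
2. :func:`detect_flat_stair_runs` — flags flat and stair runs, which
   cannot be corrected, only filtered.
3. :func:`segment_windows` — non-overlapping 300-second windows,
   half-open, with beats assigned by the time of the R-peak that ends
   them; recording gaps split the trace into segments windowed
   independently.
4. :func:`annotate_and_filter` — joins an ethogram behaviour log and
   retains only windows that are >= 95% Resting, contain no high-energy
   (disqualifying) states, and have <= 5% flats/stairs and a small
   corrected-beat fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "IBITrace",
    "CleaningConfig",
    "RunAnnotation",
    "AnalysisWindow",
    "correct_artefacts",
    "detect_flat_stair_runs",
    "segment_windows",
    "annotate_and_filter",
    "process_trace",
    "windows_qc_frame",
]

DROP_NO_BEHAVIOUR = "no_behaviour"
DROP_LOW_RESTING = "low_resting"
DROP_DISQUALIFYING = "disqualifying_state"
DROP_FLAT_STAIR = "flat_stair"
DROP_EXCESS_CORRECTED = "excess_corrected"


@dataclass
class IBITrace:
    """One seal-season sequence of inter-beat intervals.

    ``end_time_s`` is the cumulative time of the R-peak ending each
    interval; by construction successive end-time differences equal
    ``ibi_ms / 1000``.
    """

    seal_id: str
    year: int
    end_time_s: np.ndarray
    ibi_ms: np.ndarray
    corrections: list[dict] = field(default_factory=list)
    corrected_mask: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    @classmethod
    def from_ibis(cls, ibis, seal_id: str = "?", year: int = 0,
                  start_s: float = 0.0) -> "IBITrace":
        ibis = np.asarray(ibis, dtype=float)
        if len(ibis) and ibis.min() <= 0:
            raise ValueError("all IBIs must be positive")
        end = start_s + np.cumsum(ibis) / 1000.0
        return cls(seal_id=seal_id, year=year, end_time_s=end, ibi_ms=ibis)

    @property
    def n_beats(self) -> int:
        return len(self.ibi_ms)

    @property
    def duration_s(self) -> float:
        return float(self.ibi_ms.sum() / 1000.0)

    def validate(self) -> None:
        if np.any(self.ibi_ms <= 0):
            raise ValueError("all IBIs must be positive")
        if np.any(np.diff(self.end_time_s) <= 0):
            raise ValueError("end times must be strictly increasing")
        dt = np.diff(self.end_time_s, prepend=self.end_time_s[0] - self.ibi_ms[0] / 1000.0)
        if np.max(np.abs(dt - self.ibi_ms / 1000.0)) > 1e-6:
            raise ValueError("end-time increments must equal ibi_ms/1000")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.end_time_s, "ibi_ms": self.ibi_ms})


@dataclass
class CleaningConfig:
    """Thresholds for cleaning and retention.

    The 0.95 resting and 0.05 flat/stair fractions are the standard
    resting-HRV retention rules for field telemetry; the
    correction-filter settings (11-beat local median, 0.7/1.3 factors,
    250–3000 ms absolute bounds) are this package's documented
    equivalent of proprietary device-side correction software.
    """

    ibi_min_ms: float = 250.0
    ibi_max_ms: float = 3000.0
    local_window: int = 11
    short_factor: float = 0.7
    long_factor: float = 1.3
    flat_min_run: int = 3
    flat_tol_ms: float = 0.0
    stair_min_run: int = 4
    stair_step_tol_ms: float = 2.0
    max_corrected_fraction: float = 0.05
    resting_min_fraction: float = 0.95
    flatstair_max_fraction: float = 0.05
    disqualifying_states: frozenset = frozenset({"Locomotion", "Aggression"})
    window_s: float = 300.0
    gap_split_s: float = 5.0

    def validate(self) -> None:
        if not (0.0 < self.short_factor < 1.0 < self.long_factor):
            raise ValueError("need 0 < short_factor < 1 < long_factor")
        for name in ("max_corrected_fraction", "resting_min_fraction",
                     "flatstair_max_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.flat_min_run < 2 or self.stair_min_run < 2:
            raise ValueError("minimum run lengths must be >= 2")


@dataclass(frozen=True)
class RunAnnotation:
    kind: str          # "flat" | "stair"
    start_index: int
    length: int


@dataclass
class AnalysisWindow:
    """One 300-s analysis window with its QC fractions."""

    window_index: int
    start_s: float
    end_s: float
    beat_indices: np.ndarray
    resting_fraction: float = np.nan
    disqualifying_fraction: float = np.nan
    flatstair_fraction: float = np.nan
    corrected_fraction: float = np.nan
    rmssd_ms: float = np.nan
    retained: bool = False
    drop_reason: str = ""


# ---------------------------------------------------------------------------
# artefact correction


def _local_median(values: list[float], i: int, window: int) -> float:
    half = window // 2
    lo = max(0, i - half)
    hi = min(len(values), i + half + 1)
    neigh = values[lo:i] + values[i + 1 : hi]
    if not neigh:
        return values[i]
    return float(np.median(neigh))


def correct_artefacts(trace: IBITrace, cfg: CleaningConfig | None = None) -> IBITrace:
    """Delete spurious extra beats and interpolate missed beats.

    Each IBI is compared with the median of its neighbours (the centre
    beat excluded so the artefact cannot mask itself). An extreme-long
    IBI is split into ``round(ibi / median)`` equal sub-intervals; an
    extreme-short IBI is merged with whichever adjacent beat brings the
    sum closest to the local median, provided the sum lands inside the
    acceptance band. Both moves conserve total duration exactly.

    Traces shorter than the local window are returned unchanged with a
    ``"too_short_for_correction"`` flag; traces where the corrected
    fraction exceeds ``max_corrected_fraction`` get an
    ``"excess_corrected"`` flag for window-level exclusion.
    """
    cfg = cfg or CleaningConfig()
    cfg.validate()
    if trace.n_beats < cfg.local_window:
        out = replace(trace)
        out.flags = trace.flags + ["too_short_for_correction"]
        out.corrected_mask = np.zeros(trace.n_beats, dtype=bool)
        return out

    work = list(map(float, trace.ibi_ms))
    flagged = [bool(b) for b in (trace.corrected_mask
                                 if trace.corrected_mask is not None
                                 else np.zeros(trace.n_beats, dtype=bool))]
    ledger: list[dict] = list(trace.corrections)
    n_corrected_events = 0

    i = 0
    while i < len(work):
        v = work[i]
        m = _local_median(work, i, cfg.local_window)
        lo, hi = cfg.short_factor * m, cfg.long_factor * m
        if v > hi or v > cfg.ibi_max_ms:
            k = int(round(v / m))
            if k >= 2:
                part = v / k
                ledger.append({"index": i, "kind": "interpolated_missed_beat",
                               "original": (v,), "n_parts": k})
                work[i : i + 1] = [part] * k
                flagged[i : i + 1] = [True] * k
                n_corrected_events += 1
                i += k
                continue
        elif v < lo or v < cfg.ibi_min_ms:
            best = None  # (|sum - m|, neighbour_index)
            for j in (i - 1, i + 1):
                if 0 <= j < len(work):
                    s = v + work[j]
                    if lo <= s <= hi and s <= cfg.ibi_max_ms:
                        cand = (abs(s - m), j)
                        if best is None or cand < best:
                            best = cand
            if best is not None:
                j = best[1]
                a, b = (work[j], v) if j < i else (v, work[j])
                k = min(i, j)
                ledger.append({"index": k, "kind": "merged_extra_beat",
                               "original": (a, b)})
                work[k : k + 2] = [a + b]
                flagged[k : k + 2] = [True]
                n_corrected_events += 1
                i = max(k - 1, 0)  # re-examine around the merge
                continue
        i += 1

    out = IBITrace.from_ibis(np.asarray(work), seal_id=trace.seal_id,
                             year=trace.year,
                             start_s=float(trace.end_time_s[0] - trace.ibi_ms[0] / 1000.0))
    out.corrections = ledger
    out.corrected_mask = np.asarray(flagged, dtype=bool)
    out.flags = list(trace.flags)
    corrected_fraction = float(out.corrected_mask.mean()) if out.n_beats else 0.0
    if corrected_fraction > cfg.max_corrected_fraction:
        out.flags.append("excess_corrected")
    return out


# ---------------------------------------------------------------------------
# flats and stairs


def detect_flat_stair_runs(trace: IBITrace, cfg: CleaningConfig | None = None) -> list[RunAnnotation]:
    """Find maximal flat and stair runs.

    A flat is a maximal run of >= ``flat_min_run`` IBIs equal within
    ``flat_tol_ms`` of the run's first value. A stair is a maximal
    strictly monotone run of >= ``stair_min_run`` IBIs whose successive
    differences agree within ``stair_step_tol_ms``.
    """
    cfg = cfg or CleaningConfig()
    x = np.asarray(trace.ibi_ms, dtype=float)
    runs: list[RunAnnotation] = []
    n = len(x)

    i = 0
    while i < n:
        j = i + 1
        while j < n and abs(x[j] - x[i]) <= cfg.flat_tol_ms:
            j += 1
        if j - i >= cfg.flat_min_run:
            runs.append(RunAnnotation("flat", i, j - i))
        i = j if j > i + 1 else i + 1

    if n >= 2:
        d = np.diff(x)
        i = 0
        while i < n - 1:
            if d[i] == 0:
                i += 1
                continue
            sign = np.sign(d[i])
            j = i + 1
            while (j < n - 1 and np.sign(d[j]) == sign
                   and abs(d[j] - d[j - 1]) <= cfg.stair_step_tol_ms):
                j += 1
            run_len = j - i + 1  # beats spanned by diffs i..j-1
            if run_len >= cfg.stair_min_run:
                runs.append(RunAnnotation("stair", i, run_len))
                i = j
            else:
                i += 1
    return runs


def flatstair_mask(n_beats: int, runs: list[RunAnnotation]) -> np.ndarray:
    mask = np.zeros(n_beats, dtype=bool)
    for r in runs:
        mask[r.start_index : r.start_index + r.length] = True
    return mask


# ---------------------------------------------------------------------------
# windowing


def _segments(trace: IBITrace, gap_split_s: float) -> list[np.ndarray]:
    """Indices of beats in each continuous recording segment; a gap is a
    jump in end-times exceeding the beat's own IBI by > gap_split_s."""
    if trace.n_beats == 0:
        return []
    dt = np.diff(trace.end_time_s)
    excess = dt - trace.ibi_ms[1:] / 1000.0
    breaks = np.nonzero(excess > gap_split_s)[0] + 1
    return np.split(np.arange(trace.n_beats), breaks)


def segment_windows(trace: IBITrace, window_s: float = 300.0,
                    gap_split_s: float = 5.0) -> list[AnalysisWindow]:
    """Cut the trace into non-overlapping half-open windows of
    ``window_s`` seconds, restarting at zero for each continuous
    recording segment. Beats belong to the window containing the time
    of the R-peak that ends them; a beat ending exactly on a boundary
    belongs to the following window. Trailing partial windows are
    discarded.
    """
    windows: list[AnalysisWindow] = []
    widx = 0
    for seg in _segments(trace, gap_split_s):
        first = seg[0]
        seg_start = trace.end_time_s[first] - trace.ibi_ms[first] / 1000.0
        rel_end = trace.end_time_s[seg] - seg_start
        seg_duration = rel_end[-1]
        n_complete = int(np.floor(seg_duration / window_s + 1e-9))
        if n_complete < 1:
            continue
        k = np.floor(rel_end / window_s + 1e-9).astype(int)
        for w in range(n_complete):
            members = seg[k == w]
            windows.append(AnalysisWindow(
                window_index=widx,
                start_s=seg_start + w * window_s,
                end_s=seg_start + (w + 1) * window_s,
                beat_indices=members,
            ))
            widx += 1
    return windows


# ---------------------------------------------------------------------------
# behavioural annotation + retention


def label_states(trace: IBITrace, log: pd.DataFrame) -> np.ndarray:
    """State active at each IBI's end time; time not covered by the log
    is labelled ``Unknown``. Intervals are treated as [start, end)."""
    labels = np.full(trace.n_beats, "Unknown", dtype=object)
    if log is None or len(log) == 0:
        return labels
    log = log.sort_values("start_s").reset_index(drop=True)
    starts = log["start_s"].to_numpy(dtype=float)
    ends = log["end_s"].to_numpy(dtype=float)
    states = log["state"].to_numpy(dtype=object)
    pos = np.searchsorted(starts, trace.end_time_s, side="right") - 1
    ok = (pos >= 0) & (trace.end_time_s < ends[np.clip(pos, 0, len(ends) - 1)])
    labels[ok] = states[pos[ok]]
    return labels


def annotate_and_filter(windows: list[AnalysisWindow], log: pd.DataFrame,
                        runs: list[RunAnnotation], cfg: CleaningConfig,
                        trace: IBITrace) -> list[AnalysisWindow]:
    """Fill QC fractions and the retained flag for every window.

    A window is retained iff resting_fraction >= ``resting_min_fraction``,
    no disqualifying (high-energy) state occurs, flatstair_fraction <=
    ``flatstair_max_fraction`` and corrected fraction <=
    ``max_corrected_fraction``. The first failing rule, in that priority
    order (behaviour coverage checked first), becomes the drop reason.
    """
    cfg.validate()
    labels = label_states(trace, log)
    fs_mask = flatstair_mask(trace.n_beats, runs)
    corr = (trace.corrected_mask if trace.corrected_mask is not None
            else np.zeros(trace.n_beats, dtype=bool))
    trace_excess = DROP_EXCESS_CORRECTED if "excess_corrected" in trace.flags else ""

    for w in windows:
        members = w.beat_indices
        n = len(members)
        if n == 0:
            w.retained = False
            w.drop_reason = DROP_NO_BEHAVIOUR
            continue
        lab = labels[members]
        w.resting_fraction = float(np.mean(lab == "Resting"))
        w.disqualifying_fraction = float(np.mean(np.isin(lab, list(cfg.disqualifying_states))))
        w.flatstair_fraction = float(fs_mask[members].mean())
        w.corrected_fraction = float(corr[members].mean())
        if np.all(lab == "Unknown"):
            w.retained, w.drop_reason = False, DROP_NO_BEHAVIOUR
        elif w.resting_fraction < cfg.resting_min_fraction:
            w.retained, w.drop_reason = False, DROP_LOW_RESTING
        elif w.disqualifying_fraction > 0:
            w.retained, w.drop_reason = False, DROP_DISQUALIFYING
        elif w.flatstair_fraction > cfg.flatstair_max_fraction:
            w.retained, w.drop_reason = False, DROP_FLAT_STAIR
        elif w.corrected_fraction > cfg.max_corrected_fraction or trace_excess:
            w.retained, w.drop_reason = False, DROP_EXCESS_CORRECTED
        else:
            w.retained, w.drop_reason = True, ""
    return windows


def process_trace(trace: IBITrace, log: pd.DataFrame,
                  cfg: CleaningConfig | None = None) -> tuple[IBITrace, list[AnalysisWindow]]:
    """Full cleaning chain: correct, detect runs, window, annotate, and
    compute per-window RMSSD. Returns (corrected trace, windows)."""
    from .hrv import rmssd

    cfg = cfg or CleaningConfig()
    corrected = correct_artefacts(trace, cfg)
    runs = detect_flat_stair_runs(corrected, cfg)
    windows = segment_windows(corrected, cfg.window_s, cfg.gap_split_s)
    annotate_and_filter(windows, log, runs, cfg, corrected)
    for w in windows:
        if len(w.beat_indices) >= 2:
            w.rmssd_ms = rmssd(corrected.ibi_ms[w.beat_indices])
    return corrected, windows


def windows_qc_frame(windows: list[AnalysisWindow]) -> pd.DataFrame:
    """Per-window QC report."""
    return pd.DataFrame([
        dict(window_index=w.window_index,
             start_s=w.start_s, end_s=w.end_s, n_beats=len(w.beat_indices),
             resting_fraction=w.resting_fraction,
             disqualifying_fraction=w.disqualifying_fraction,
             flatstair_fraction=w.flatstair_fraction,
             corrected_fraction=w.corrected_fraction,
             rmssd_ms=w.rmssd_ms, retained=w.retained, drop_reason=w.drop_reason)
        for w in windows
    ])
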