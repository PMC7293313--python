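import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from copingcolony.ibi import (DROP_FLAT_STAIR, DROP_LOW_RESTING,
                              DROP_NO_BEHAVIOUR, CleaningConfig, IBITrace,
                              annotate_and_filter, correct_artefacts,
                              detect_flat_stair_runs, process_trace,
                              segment_windows)
from tests.conftest import pattern_trace


def brute_force_runs(x, cfg):
    """O(n^2) oracle: test every subsequence for the flat/stair
    definitions and keep the maximal qualifying ones (exact-equality
    flats, i.e. flat_tol_ms = 0)."""
    x = [float(v) for v in x]
    n = len(x)
    found = set()
    for i in range(n):
        for j in range(i + cfg.flat_min_run - 1, n):
            seg = x[i : j + 1]
            if all(v == seg[0] for v in seg):
                maximal = (i == 0 or x[i - 1] != x[i]) and \
                          (j == n - 1 or x[j + 1] != x[j])
                if maximal:
                    found.add(("flat", i, j - i + 1))

    def stair_ok(i, j):  # beats i..j inclusive
        dd = [x[t + 1] - x[t] for t in range(i, j)]
        if not dd or dd[0] == 0:
            return False
        if any(np.sign(d) != np.sign(dd[0]) for d in dd):
            return False
        return all(abs(dd[t] - dd[t - 1]) <= cfg.stair_step_tol_ms
                   for t in range(1, len(dd)))

    for i in range(n):
        for j in range(i + cfg.stair_min_run - 1, n):
            if stair_ok(i, j):
                extend_left = i > 0 and stair_ok(i - 1, j)
                extend_right = j < n - 1 and stair_ok(i, j + 1)
                if not extend_left and not extend_right:
                    found.add(("stair", i, j - i + 1))
    return sorted(found)


class TestCorrectArtefacts:
    def test_clean_trace_untouched(self):
        trace = IBITrace.from_ibis(pattern_trace(100))
        out = correct_artefacts(trace)
        assert np.array_equal(out.ibi_ms, trace.ibi_ms)
        assert out.corrections == []

    def test_extra_beat_pair_merged(self):
        ibis = [800, 800, 800, 800, 800, 400, 400, 800, 800, 800, 800, 800]
        out = correct_artefacts(IBITrace.from_ibis(ibis))
        assert list(out.ibi_ms) == [800.0] * 11
        assert out.duration_s == pytest.approx(sum(ibis) / 1000)
        kinds = [c["kind"] for c in out.corrections]
        assert kinds == ["merged_extra_beat"]

    def test_missed_beat_interpolated(self):
        ibis = [800.0] * 6 + [1600.0] + [800.0] * 6
        out = correct_artefacts(IBITrace.from_ibis(ibis))
        assert list(out.ibi_ms) == [800.0] * 14
        assert out.corrections[0]["kind"] == "interpolated_missed_beat"
        assert out.duration_s == pytest.approx(sum(ibis) / 1000)

    def test_short_trace_flagged_not_corrected(self):
        trace = IBITrace.from_ibis([800.0] * 5)
        out = correct_artefacts(trace)
        assert "too_short_for_correction" in out.flags
        assert np.array_equal(out.ibi_ms, trace.ibi_ms)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_duration_conserved_and_idempotent(self, seed):
        """Correction conserves total duration to the millisecond and
        is a fixed point: a second pass changes nothing."""
        from copingcolony import ArtefactSpec, IBISimParams, inject_artefacts, \
            simulate_ibi_trace
        trace, _, _ = simulate_ibi_trace(IBISimParams(duration=120, seed=seed))
        bad, _ = inject_artefacts(trace, ArtefactSpec(
            p_missed_beat=0.02, p_extra_beat=0.02, seed=seed))
        once = correct_artefacts(bad)
        assert once.duration_s == pytest.approx(bad.duration_s, abs=1e-9)
        twice = correct_artefacts(once)
        assert np.allclose(twice.ibi_ms, once.ibi_ms)


class TestRunDetection:
    def test_flat_example(self):
        x = [800, 800, 800, 800, 800, 810, 795]
        runs = detect_flat_stair_runs(IBITrace.from_ibis(x), CleaningConfig())
        assert [(r.kind, r.start_index, r.length) for r in runs] == [("flat", 0, 5)]

    def test_stair_example(self):
        x = [800, 820, 700, 710, 720, 730, 810, 790, 815]
        runs = detect_flat_stair_runs(IBITrace.from_ibis(x), CleaningConfig())
        stair = [r for r in runs if r.kind == "stair"]
        assert [(r.start_index, r.length) for r in stair] == [(2, 4)]

    @given(st.lists(st.integers(70, 76), min_size=5, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_brute_force_oracle(self, vals):
        x = [10.0 * v for v in vals]  # 700-760 ms, coarse grid => runs occur
        cfg = CleaningConfig()
        got = sorted({(r.kind, r.start_index, r.length)
                      for r in detect_flat_stair_runs(IBITrace.from_ibis(x), cfg)})
        assert got == brute_force_runs(x, cfg)

    def test_white_noise_never_breaches_retention_threshold(self):
        """Quantized white noise (sd 20 ms) produces only short chance
        runs: the flat/stair fraction stays at or below the 5% drop
        threshold in every 300-s window (clean data is never discarded
        by this filter) and is typically ~1%."""
        from copingcolony import IBISimParams, simulate_ibi_trace
        from copingcolony.ibi import flatstair_mask
        fracs = []
        for seed in range(10):
            trace, _, _ = simulate_ibi_trace(IBISimParams(
                noise_sd=20, duration=1500, seed=1000 + seed))
            runs = detect_flat_stair_runs(trace, CleaningConfig())
            mask = flatstair_mask(trace.n_beats, runs)
            fracs += [mask[w.beat_indices].mean()
                      for w in segment_windows(trace)]
        assert max(fracs) <= 0.05
        assert np.median(fracs) < 0.02


class TestSegmentation:
    def test_window_counts(self):
        t1000 = IBITrace.from_ibis([1000.0] * 1000)  # 1000 s
        assert len(segment_windows(t1000)) == 3
        t299 = IBITrace.from_ibis([1000.0] * 299)
        assert segment_windows(t299) == []

    def test_boundary_beat_goes_to_next_window(self):
        # beat ending exactly at 300.0 s belongs to window 1
        trace = IBITrace.from_ibis([1000.0] * 601)
        wins = segment_windows(trace)
        w0, w1 = wins[0], wins[1]
        assert 298 in w0.beat_indices          # ends at 299.0 s
        assert 299 in w1.beat_indices          # ends at exactly 300.0 s
        assert len(w0.beat_indices) == 299     # ends 1..299 s

    def test_gap_splits_segments(self):
        ibis = [1000.0] * 400
        trace = IBITrace.from_ibis(ibis)
        # introduce a 100 s recording gap after beat 200
        trace.end_time_s = trace.end_time_s.copy()
        trace.end_time_s[200:] += 100.0
        wins = segment_windows(trace)
        # each 200 s segment yields zero complete 300 s windows
        assert wins == []

    def test_windows_disjoint(self, small_trace):
        trace, _, _ = small_trace
        wins = segment_windows(trace)
        all_idx = np.concatenate([w.beat_indices for w in wins])
        assert len(all_idx) == len(set(all_idx.tolist()))


class TestAnnotateFilter:
    def _one_window(self, log, ibis=None):
        trace = IBITrace.from_ibis(pattern_trace(400) if ibis is None else ibis)
        trace.corrected_mask = np.zeros(trace.n_beats, dtype=bool)
        cfg = CleaningConfig()
        wins = segment_windows(trace)
        runs = detect_flat_stair_runs(trace, cfg)
        annotate_and_filter(wins, log, runs, cfg, trace)
        return wins[0]

    def test_fully_resting_retained(self, rest_log):
        w = self._one_window(rest_log(400))
        assert w.retained and w.drop_reason == ""

    def test_94_percent_resting_dropped(self, rest_log):
        w = self._one_window(rest_log(400, [(10.0, 28.5, "Alert")]))
        assert w.resting_fraction < 0.95
        assert not w.retained and w.drop_reason == DROP_LOW_RESTING

    def test_any_locomotion_disqualifies(self, rest_log):
        from copingcolony.ibi import DROP_DISQUALIFYING
        w = self._one_window(rest_log(400, [(10.0, 22.0, "Locomotion")]))
        assert w.resting_fraction >= 0.95
        assert not w.retained and w.drop_reason == DROP_DISQUALIFYING

    def test_empty_log_drops_with_reason(self):
        w = self._one_window(pd.DataFrame(columns=["start_s", "end_s", "state"]))
        assert not w.retained and w.drop_reason == DROP_NO_BEHAVIOUR

    def test_filter_monotone_in_thresholds(self, small_trace):
        """Raising the resting threshold or tightening the flat/stair
        cap never retains more windows."""
        trace, log, _ = small_trace
        def n_retained(rest_min, fs_max):
            cfg = CleaningConfig(resting_min_fraction=rest_min,
                                 flatstair_max_fraction=fs_max)
            _, wins = process_trace(trace, log, cfg)
            return sum(w.retained for w in wins)
        base = n_retained(0.95, 0.05)
        assert n_retained(0.99, 0.05) <= base
        assert n_retained(0.95, 0.01) <= base
        assert n_retained(0.80, 0.20) >= base
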