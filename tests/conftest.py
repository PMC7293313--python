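import numpy as np
import pandas as pd
import pytest

from copingcolony import (ColonySimParams, IBISimParams, simulate_colony,
                          simulate_ibi_trace)
from copingcolony import hrv as _hrv
from copingcolony import metrics as _metrics


@pytest.fixture(scope="session")
def small_trace():
    """A short clean white-noise trace (1000 s, ~1100 beats)."""
    params = IBISimParams(duration=1000.0, seed=11)
    trace, log, truth = simulate_ibi_trace(params)
    return trace, log, truth


@pytest.fixture(scope="session")
def colony():
    """One default colony realisation (≈95 mother-year rows)."""
    return simulate_colony(ColonySimParams(seed=42))


@pytest.fixture(scope="session")
def analysis_table(colony):
    """Merged modelling table for the default colony."""
    captures, hrv_table, _ = colony
    perf = _metrics.performance_table(captures)
    ind = _hrv.individual_hrv_table(hrv_table)
    return _metrics.build_analysis_table(perf, ind)


def pattern_trace(n_beats: int, base=(800.0, 820.0, 790.0, 810.0)):
    """A deterministic flat/stair-free IBI sequence for constructed
    tests (no equal neighbours, alternating difference signs)."""
    reps = int(np.ceil(n_beats / len(base)))
    return np.tile(np.asarray(base), reps)[:n_beats]


@pytest.fixture
def rest_log():
    def make(duration_s, exceptions=()):
        """Behaviour log: Resting over [0, duration] except the given
        (start, end, state) intervals."""
        rows = []
        t = 0.0
        for start, end, state in sorted(exceptions):
            if start > t:
                rows.append((t, start, "Resting"))
            rows.append((start, end, state))
            t = end
        if t < duration_s:
            rows.append((t, duration_s, "Resting"))
        return pd.DataFrame(rows, columns=["start_s", "end_s", "state"])
    return make
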