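import numpy as np
import pandas as pd
import pytest

from timerrider import EarlyComponent, LaterUnit, SimulationConfig, TrialSet


@pytest.fixture
def unit() -> LaterUnit:
    """Reference unit: unit threshold interval, mean rate 5 /s, SD 1 /s
    (median latency 200 ms, promptness N(5, 1))."""
    return LaterUnit(s0=0.0, s_t=1.0, rate_mean=5.0, rate_sd=1.0)


@pytest.fixture
def pure_cfg(unit) -> SimulationConfig:
    """Pure recinormal design: early and express pathways disabled."""
    return SimulationConfig(
        unit=unit, early=EarlyComponent(weight=0.0), p_express=0.0, n_trials=500
    )


def make_trialset(latencies_ms, condition="a", n_censored=0) -> TrialSet:
    """Build a TrialSet directly from latencies (plus optional censored rows)."""
    lat = np.asarray(latencies_ms, dtype=float)
    n = len(lat) + n_censored
    frame = pd.DataFrame(
        {
            "trial_index": np.arange(n, dtype=int),
            "condition": condition,
            "subpopulation": ["main"] * len(lat) + ["censored"] * n_censored,
            "latency_ms": np.concatenate([lat, np.full(n_censored, np.nan)]),
        }
    )
    return TrialSet(frame)
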