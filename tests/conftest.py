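import numpy as np
import pandas as pd
import pytest

from soarflight.synthetic import (
    SimConfig,
    make_corridor_mask,
    make_weather_grid,
    simulate_flight,
)


@pytest.fixture(scope="session")
def mixed_fleet():
    """A small duty-cycled fleet with all five modes and default noise."""
    cfg = SimConfig(seed=7, n_birds=4, n_bursts_per_bird=15, burst_s=120)
    return simulate_flight(cfg)


@pytest.fixture(scope="session")
def corridor_mask():
    return make_corridor_mask(lat=43.0, coast_east_lon=15.2, sea_width_km=195.0)


@pytest.fixture()
def uniform_grid():
    """24 h grid over the corridor with u=5 m/s eastward wind, dT=1.1 C."""
    times = pd.date_range("2020-10-03", periods=24, freq="h")
    return make_weather_grid(times, np.arange(41.0, 45.26, 0.25), np.arange(11.0, 17.26, 0.25))


def truth_by_burst(labeled):
    return labeled.truth.groupby("burst_id").first()


def segment_truth(segments, labeled):
    """(true behavior, true pattern, segment) triples via the burst id."""
    tb = truth_by_burst(labeled)
    out = []
    for seg in segments:
        burst = seg.fixes["burst_id"].iloc[0]
        out.append((tb.loc[burst, "behavior"], tb.loc[burst, "pattern"], seg))
    return out
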