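import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import birchphen as bp
from birchphen.synthetic import snap_thresholds

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def grid():
    return bp.GridSpec(50.0, 60.0, 10.0, 20.0, resolution=0.5)


@pytest.fixture(scope="session")
def clean_scenario():
    """All noise terms off: the deterministic synthetic world."""
    return bp.SimulationScenario(
        noise_sd=0.0,
        obs_noise_sigma=0.0,
        lrt_spike_prob=0.0,
        missing_frac=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def dates():
    return pd.date_range("2006-03-01", "2006-06-30", freq="D")


@pytest.fixture(scope="session")
def clean_temps(clean_scenario, grid, dates):
    return bp.gen_temperature(clean_scenario, grid, dates)


@pytest.fixture(scope="session")
def truth_map(clean_temps, grid):
    """Heat-sum-realisable ground-truth threshold map."""
    return snap_thresholds(clean_temps, bp.gen_truth_threshold(grid))


@pytest.fixture(scope="session")
def stations(grid):
    return bp.gen_station_locations(grid, 30, seed=11)


@pytest.fixture(scope="session")
def clean_records(clean_temps, truth_map, stations):
    return bp.gen_leaf_unfolding(clean_temps, truth_map, stations)


@pytest.fixture(scope="session")
def clean_pollen(clean_temps, truth_map, clean_scenario, stations):
    return bp.gen_pollen_series(clean_temps, truth_map, clean_scenario, stations)


def make_series(conc, observed=None, start="2006-03-01", station_id="S", lat=55.0, lon=15.0):
    """Small StationSeries helper for hand-built examples."""
    conc = np.asarray(conc, dtype=float)
    if observed is None:
        observed = np.ones(len(conc), dtype=bool)
    dates = pd.date_range(start, periods=len(conc), freq="D")
    return bp.StationSeries(station_id, lat, lon, dates, conc, np.asarray(observed, bool))
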