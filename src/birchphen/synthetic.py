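"""Synthetic meteorology, phenology and pollen observations with known truth.

The real study drew its inputs from NWP temperature archives, a continental
pollen-count network and a phenological database; none of those are needed
here.  Instead this module generates the same kinds of inputs from a known
ground truth, so that every downstream stage (threshold fitting, season
definition, QC, verification) can be exercised as a parameter-recovery
problem.

The generated world is deliberately simple:

* temperature is a linear spring warming trend with a meridional gradient,
  an optional constant bias and optional white noise;
* the true flowering threshold is a linear function of latitude;
* leaf-unfolding dates are the exact heat-sum crossing days plus rounded
  Gaussian date noise;
* pollen is zero before the local flowering start, then a raised-cosine
  pulse; pre-season days may carry long-range-transport (LRT) spikes;
  multiplicative lognormal noise and an i.i.d. missing-day mask are applied
  on top.

Each noise source draws from its own seeded sub-stream, so switching one
off leaves all others bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence, Tuple

import json
import numpy as np
import pandas as pd

from .grids import THRESHOLD_FLOOR, GriddedTemperature, GridSpec, ThresholdMap
from .phenology import HeatSumParams, daily_mean, first_crossing
from .stations import PhenologyRecord, StationSeries

__all__ = [
    "SimulationScenario",
    "gen_temperature",
    "gen_truth_threshold",
    "gen_leaf_unfolding",
    "gen_pollen_series",
    "gen_station_locations",
    "pulse_weights",
    "pulse_integral",
]

# Named sub-stream keys; each generator/noise source owns one so that
# toggling a single noise term never perturbs the others.
_STREAMS = {"temp_noise": 0, "date_noise": 1, "spikes": 2, "obs_noise": 3, "missing": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class SimulationScenario:
    """All knobs of the synthetic world.

    Temperature: ``base_temp`` (degC) at ``ref_lat`` on 1 March, warming at
    ``warming_rate`` degC/day, decreasing northwards by ``lat_gradient``
    degC per degree latitude; a constant ``bias`` and zero-mean Gaussian
    ``noise_sd`` sit on top.  Pollen: a raised-cosine pulse of
    ``season_length`` days peaking at ``peak_conc`` grains m^-3 starts at the
    local heat-sum crossing; before it, each day carries an LRT spike of
    ``lrt_spike_conc`` with probability ``lrt_spike_prob``.  Observation:
    multiplicative lognormal noise with log-sd ``obs_noise_sigma`` and an
    i.i.d. Bernoulli missing mask at ``missing_frac`` (plus an optional
    March-only surcharge ``march_extra_missing_frac`` that exercises the
    QC homogeneity rule).
    """

    base_temp: float = 5.0
    warming_rate: float = 0.15
    lat_gradient: float = -0.5
    ref_lat: float = 55.0
    bias: float = 0.0
    noise_sd: float = 2.0
    truth_threshold: Optional[ThresholdMap] = None
    season_length: int = 30
    peak_conc: float = 2000.0
    lrt_spike_prob: float = 0.1
    lrt_spike_conc: float = 30.0
    obs_noise_sigma: float = 0.3
    missing_frac: float = 0.05
    march_extra_missing_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("base_temp", "warming_rate", "lat_gradient", "bias"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for name in ("lrt_spike_prob", "missing_frac", "march_extra_missing_frac"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.season_length < 1:
            raise ValueError("season_length must be at least 1 day")
        if self.noise_sd < 0 or self.obs_noise_sigma < 0:
            raise ValueError("noise scales must be non-negative")

    def with_(self, **kwargs) -> "SimulationScenario":
        return replace(self, **kwargs)

    def to_config(self, path) -> None:
        """Write the scenario as a flat key/value JSON file."""
        d = asdict(self)
        d.pop("truth_threshold")
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)

    @classmethod
    def from_config(cls, path) -> "SimulationScenario":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def gen_temperature(
    scenario: SimulationScenario,
    grid: GridSpec,
    dates,
) -> GriddedTemperature:
    """Linear-trend temperature field on the grid over ``dates``.

    ``value(t, lat) = base_temp + warming_rate * days_since_1_March
    + lat_gradient * (lat - ref_lat) + bias + noise``.  ``dates`` must span
    at least 1 March - 31 May of one year (daily or 3-hourly index).
    """
    dates = pd.DatetimeIndex(dates)
    if len(dates) == 0:
        raise ValueError("empty date range")
    year = dates[0].year
    mar1 = pd.Timestamp(year, 3, 1)
    may31 = pd.Timestamp(year, 5, 31)
    if dates[0] > mar1 or dates[-1] < may31:
        raise ValueError("date range must cover at least 1 March - 31 May")
    elapsed = (dates - mar1) / pd.Timedelta(days=1)  # fractional days
    t_term = scenario.base_temp + scenario.warming_rate * elapsed.to_numpy()
    lat_term = scenario.lat_gradient * (grid.lats - scenario.ref_lat)
    vals = (
        t_term[:, None, None]
        + lat_term[None, :, None]
        + np.zeros((1, 1, grid.n_lon))
        + scenario.bias
    )
    if scenario.noise_sd > 0:
        rng = _rng(scenario.seed, "temp_noise")
        vals = vals + rng.normal(0.0, scenario.noise_sd, size=vals.shape)
    return GriddedTemperature.from_array(grid, dates, vals)


def gen_truth_threshold(
    grid: GridSpec,
    base: float = 100.0,
    lat_gradient: float = 2.0,
    ref_lat: float = 45.0,
    floor: float = THRESHOLD_FLOOR,
) -> ThresholdMap:
    """Ground-truth threshold map, linear in latitude and floored positive.

    ``threshold(lat) = base + lat_gradient * (lat - ref_lat)``, clipped
    below at ``floor`` degree-days.
    """
    if not base > 0:
        raise ValueError("base threshold must be positive")
    col = base + lat_gradient * (grid.lats - ref_lat)
    vals = np.broadcast_to(col[:, None], (grid.n_lat, grid.n_lon)).copy()
    return ThresholdMap(grid=grid, values=np.maximum(vals, floor), method="TRUTH")


def snap_thresholds(
    temps: GriddedTemperature,
    tmap: ThresholdMap,
    params: HeatSumParams = HeatSumParams(),
) -> ThresholdMap:
    """Replace each threshold by the heat sum realised on its crossing day.

    With daily accumulation a threshold is only identifiable up to the heat
    sum actually attained on the day it is first reached: any value in the
    interval between two consecutive daily sums yields the same flowering
    date.  Snapping the ground-truth map onto this lattice (same crossing
    day, exactly attainable value) makes exact parameter recovery
    well-defined; cells whose threshold is never reached become undefined.
    """
    from .phenology import daily_mean as _dm

    daily = _dm(temps)
    idx = pd.DatetimeIndex(daily.times).normalize()
    start = params.start_for_year(idx[0].year)
    sel = idx >= start
    excess = np.maximum(daily.data.values[sel] - params.cutoff, 0.0)
    cum = np.cumsum(excess, axis=0)
    reached = cum >= tmap.values[None, :, :]
    any_hit = reached.any(axis=0) & np.isfinite(tmap.values)
    first = np.argmax(reached, axis=0)
    out = np.full(tmap.values.shape, np.nan)
    ii, jj = np.nonzero(any_hit)
    out[ii, jj] = cum[first[ii, jj], ii, jj]
    return ThresholdMap(grid=tmap.grid, values=out, method=tmap.method)


def gen_station_locations(
    grid: GridSpec, n: int, seed: int, on_cell_centres: bool = True
) -> list[Tuple[str, float, float]]:
    """``n`` station locations inside the grid, ids ``S000``...

    With ``on_cell_centres`` (default) stations sit exactly on distinct
    randomly chosen cell centres, which makes station/cell round trips
    exact; otherwise positions are uniform in the bounding box.
    """
    rng = np.random.default_rng(seed)
    if on_cell_centres:
        n_cells = grid.n_lat * grid.n_lon
        if n > n_cells:
            raise ValueError("more stations than grid cells")
        flat = rng.choice(n_cells, size=n, replace=False)
        ii, jj = np.unravel_index(flat, (grid.n_lat, grid.n_lon))
        return [
            (f"S{k:03d}", float(grid.lats[i]), float(grid.lons[j]))
            for k, (i, j) in enumerate(zip(ii, jj))
        ]
    lats = rng.uniform(grid.lat_min, grid.lat_max, n)
    lons = rng.uniform(grid.lon_min, grid.lon_max, n)
    return [(f"S{k:03d}", float(a), float(o)) for k, (a, o) in enumerate(zip(lats, lons))]


def gen_leaf_unfolding(
    temps: GriddedTemperature,
    truth: ThresholdMap,
    stations: Sequence[Tuple[str, float, float]],
    date_noise_sd: float = 0.0,
    seed: int = 0,
    params: HeatSumParams = HeatSumParams(),
) -> list[PhenologyRecord]:
    """Leaf-unfolding records: heat-sum crossing day plus rounded date noise.

    Stations whose cell never reaches the local threshold are flagged
    missing.  Noisy dates are clamped at the accumulation start so a record
    can never pre-date the window it is fitted against.
    """
    daily = daily_mean(temps)
    rng = _rng(seed, "date_noise")
    records: list[PhenologyRecord] = []
    for sid, lat, lon in stations:
        cell = daily.station_series(lat, lon)
        thr = truth.at_station(lat, lon)
        crossing = first_crossing(cell, params, thr) if np.isfinite(thr) else None
        if crossing is None:
            records.append(PhenologyRecord(sid, lat, lon, None))
            continue
        date = crossing
        if date_noise_sd > 0:
            shift = int(np.rint(rng.normal(0.0, date_noise_sd)))
            date = date + pd.Timedelta(days=shift)
        start = params.start_for_year(crossing.year)
        date = max(date, start)
        date = min(date, pd.Timestamp(daily.times[-1]).normalize())
        records.append(PhenologyRecord(sid, lat, lon, date))
    return records


def pulse_weights(season_length: int) -> np.ndarray:
    """Raised-cosine (Hann) daily weights; exact sum ``season_length / 2``."""
    j = np.arange(season_length)
    return np.sin(np.pi * (j + 0.5) / season_length) ** 2


def pulse_integral(scenario: SimulationScenario) -> float:
    """Closed-form seasonal sum of the noise-free pulse (grains m^-3 day).

    For any length L >= 2 the Hann weights sum to exactly L/2; the
    degenerate single-day pulse has weight 1.
    """
    L = scenario.season_length
    return scenario.peak_conc * (1.0 if L == 1 else L / 2.0)


def gen_pollen_series(
    temps: GriddedTemperature,
    truth: ThresholdMap,
    scenario: SimulationScenario,
    stations: Sequence[Tuple[str, float, float]],
    params: HeatSumParams = HeatSumParams(),
) -> list[StationSeries]:
    """Daily pollen series per station over the daily-mean temperature window.

    The noise-free signal is zero before the local heat-sum crossing, then a
    raised-cosine pulse of ``season_length`` days scaled to ``peak_conc``.
    Strictly pre-season days carry LRT spikes with probability
    ``lrt_spike_prob``; the observed value is signal times lognormal noise;
    days go missing independently with probability ``missing_frac`` (plus
    the March surcharge when configured).
    """
    daily = daily_mean(temps)
    dates = pd.DatetimeIndex(daily.times).normalize()
    n_days = len(dates)
    spike_rng = _rng(scenario.seed, "spikes")
    noise_rng = _rng(scenario.seed, "obs_noise")
    miss_rng = _rng(scenario.seed, "missing")
    weights = pulse_weights(scenario.season_length)

    out: list[StationSeries] = []
    for sid, lat, lon in stations:
        cell = daily.station_series(lat, lon)
        thr = truth.at_station(lat, lon)
        crossing = first_crossing(cell, params, thr) if np.isfinite(thr) else None

        signal = np.zeros(n_days)
        if crossing is not None:
            k0 = int(dates.get_indexer([crossing])[0])
            k1 = min(k0 + scenario.season_length, n_days)
            signal[k0:k1] = scenario.peak_conc * weights[: k1 - k0]
            pre_season = np.arange(n_days) < k0
        else:
            pre_season = np.ones(n_days, dtype=bool)

        if scenario.lrt_spike_prob > 0:
            spikes = spike_rng.random(n_days) < scenario.lrt_spike_prob
            signal[pre_season & spikes] += scenario.lrt_spike_conc

        conc = signal.copy()
        if scenario.obs_noise_sigma > 0:
            conc = conc * np.exp(
                noise_rng.normal(0.0, scenario.obs_noise_sigma, size=n_days)
            )

        p_miss = np.full(n_days, scenario.missing_frac)
        if scenario.march_extra_missing_frac > 0:
            in_march = dates.month == 3
            p_miss[in_march] = np.minimum(
                1.0, p_miss[in_march] + scenario.march_extra_missing_frac
            )
        missing = miss_rng.random(n_days) < p_miss
        conc = conc.copy()
        conc[missing] = np.nan
        out.append(
            StationSeries(sid, lat, lon, dates, conc, observed=~missing)
        )
    return out
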