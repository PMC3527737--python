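"""Degree-day phenology: heat-sum accumulation and threshold-map fitting.

The developmental clock for birch flowering is the temperature sum

    S(d) = sum_{t = start}^{d} max(Tbar_t - T_c, 0)

with daily-mean temperature ``Tbar`` (degC), accumulation start 1 March and
cut-off ``T_c = 3.5`` degC.  Flowering at a location starts on the first day
``S(d)`` reaches that location's threshold (degree-days).  Threshold maps
are fitted from observations in two ways: from leaf-unfolding dates (LU),
by evaluating the heat sum accumulated up to the reported date, and from
pollen counts (OBS), by first locating the season start with a cumulative
2.5 % criterion and evaluating the heat sum there.  Station values are
spread onto the grid by inverse-distance weighting, and the two maps are
combined regionally (LU in the north, OBS elsewhere where available).

Note a structural consequence of the heat-sum form: a constant temperature
bias ``b`` applied to days already above the cut-off shifts the accumulated
sum by exactly ``b`` degree-days per day, so a 0.5 degC bias sustained over
a 2-3 month accumulation period amounts to 30-50 degree-days - comparable
to the thresholds themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grids import THRESHOLD_FLOOR, GriddedTemperature, GridSpec, RegionMask, ThresholdMap
from .season import cumulative_fraction_date
from .stations import PhenologyRecord, StationSeries

__all__ = [
    "HeatSumParams",
    "daily_mean",
    "heat_sum",
    "heat_sum_series",
    "first_crossing",
    "fit_threshold_lu",
    "fit_threshold_obs",
    "interpolate_thresholds",
    "combine_maps",
    "predict_start_map",
    "predict_station_starts",
]


@dataclass(frozen=True)
class HeatSumParams:
    """Accumulation constants: start date (month, day) and cut-off (degC)."""

    start_month: int = 3
    start_day: int = 1
    cutoff: float = 3.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")
        if (self.start_month, self.start_day) >= (5, 31):
            raise ValueError("accumulation must start before 31 May")

    def start_for_year(self, year: int) -> pd.Timestamp:
        return pd.Timestamp(year, self.start_month, self.start_day)


def daily_mean(temps: GriddedTemperature) -> GriddedTemperature:
    """Reduce a sub-daily temperature field to daily means.

    Requires a uniform sub-daily step dividing 24 h; daily input is
    returned unchanged.
    """
    if temps.is_daily:
        return temps
    step_s = temps.step.total_seconds()
    if step_s > 86400 or 86400 % int(step_s) != 0:
        raise ValueError("time step must be daily or a divisor of 24 h")
    daily = temps.data.resample(time="1D").mean()
    return GriddedTemperature(grid=temps.grid, data=daily)


def _daily_series(series: pd.Series) -> pd.Series:
    """Collapse a station temperature series to daily means if needed."""
    idx = pd.DatetimeIndex(series.index)
    if len(idx) > 1 and (idx[1] - idx[0]) < pd.Timedelta(days=1):
        return series.groupby(idx.normalize()).mean()
    return series


def heat_sum_series(
    daily_temps: pd.Series, params: HeatSumParams = HeatSumParams()
) -> pd.Series:
    """Cumulative heat sum (degree-days) from the accumulation start date.

    Indexed by day; entry ``d`` is the sum over [start, d] of the positive
    part of the daily-mean excess over the cut-off.
    """
    daily = _daily_series(daily_temps)
    idx = pd.DatetimeIndex(daily.index)
    start = params.start_for_year(idx[0].year)
    if start < idx[0]:
        raise ValueError(
            f"series begins {idx[0].date()}, after accumulation start {start.date()}"
        )
    daily = daily[idx >= start]
    if daily.empty:
        raise ValueError("series does not cover the accumulation window")
    excess = np.maximum(daily.to_numpy(dtype=float) - params.cutoff, 0.0)
    return pd.Series(np.cumsum(excess), index=daily.index)


def heat_sum(
    daily_temps: pd.Series,
    params: HeatSumParams = HeatSumParams(),
    until=None,
) -> float:
    """Heat sum accumulated from the start date up to and including ``until``."""
    cum = heat_sum_series(daily_temps, params)
    if until is None:
        return float(cum.iloc[-1])
    until = pd.Timestamp(until).normalize()
    if until < cum.index[0] or until > cum.index[-1]:
        raise ValueError("requested date outside the accumulation window")
    return float(cum.loc[until])


def first_crossing(
    daily_temps: pd.Series,
    params: HeatSumParams = HeatSumParams(),
    threshold: float = 100.0,
) -> Optional[pd.Timestamp]:
    """Earliest day whose cumulative heat sum reaches ``threshold``.

    Reaching the threshold exactly counts as crossing; ``None`` when the
    threshold is never reached within the series.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    cum = heat_sum_series(daily_temps, params)
    hit = np.nonzero(cum.to_numpy() >= threshold)[0]
    if hit.size == 0:
        return None
    return cum.index[hit[0]]


def fit_threshold_lu(
    temps: GriddedTemperature,
    records: Sequence[PhenologyRecord],
    params: HeatSumParams = HeatSumParams(),
) -> pd.DataFrame:
    """Fit per-station thresholds from leaf-unfolding dates (LU method).

    The threshold at a station is the heat sum accumulated at its grid cell
    up to the reported leaf-unfolding date.  Records with a missing date are
    skipped; a date before the accumulation start signals a corrupt record
    and raises.

    Returns a frame with columns ``station_id, lat, lon, threshold``.
    """
    daily = daily_mean(temps)
    rows = []
    for rec in records:
        if rec.missing:
            continue
        lu = pd.Timestamp(rec.leaf_unfolding_date).normalize()
        start = params.start_for_year(lu.year)
        if lu < start:
            raise ValueError(
                f"station {rec.station_id}: leaf-unfolding date {lu.date()} "
                f"precedes accumulation start {start.date()}"
            )
        cell = daily.station_series(rec.lat, rec.lon)
        rows.append(
            {
                "station_id": rec.station_id,
                "lat": rec.lat,
                "lon": rec.lon,
                "threshold": heat_sum(cell, params, until=lu),
            }
        )
    return pd.DataFrame(rows, columns=["station_id", "lat", "lon", "threshold"])


def fit_threshold_obs(
    temps: GriddedTemperature,
    pollen: Sequence[StationSeries],
    params: HeatSumParams = HeatSumParams(),
    q: float = 0.025,
    window: Optional[Tuple] = None,
) -> pd.DataFrame:
    """Fit per-station thresholds from pollen counts (OBS method).

    Season start comes from the cumulative-``q`` criterion (default 2.5 %);
    the threshold is the heat sum at that date.  Stations whose series
    admits no season (all-zero) are skipped.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    daily = daily_mean(temps)
    rows = []
    for st in pollen:
        try:
            start_date = cumulative_fraction_date(st, q, window)
        except ValueError:
            continue
        cell = daily.station_series(st.lat, st.lon)
        rows.append(
            {
                "station_id": st.station_id,
                "lat": st.lat,
                "lon": st.lon,
                "threshold": heat_sum(cell, params, until=start_date),
            }
        )
    return pd.DataFrame(rows, columns=["station_id", "lat", "lon", "threshold"])


def interpolate_thresholds(
    station_values: pd.DataFrame,
    grid: GridSpec,
    method: str = "LU",
    power: float = 2.0,
    radius_deg: float = 5.0,
    floor: float = THRESHOLD_FLOOR,
) -> ThresholdMap:
    """Spread station thresholds onto the grid by inverse-distance weighting.

    Distances are Euclidean in degrees; only stations within ``radius_deg``
    of a cell centre contribute, with weight ``d**-power``.  Cells with no
    station in radius stay undefined (NaN).  A cell whose centre coincides
    with a station reproduces that station's value exactly.
    """
    df = station_values.dropna(subset=["threshold"])
    if df.empty:
        raise ValueError("no stations with a fitted threshold")
    slat = df["lat"].to_numpy(float)
    slon = df["lon"].to_numpy(float)
    sval = np.maximum(df["threshold"].to_numpy(float), floor)

    glat = grid.lats[:, None, None]  # (n_lat, 1, 1)
    glon = grid.lons[None, :, None]  # (1, n_lon, 1)
    d2 = (glat - slat[None, None, :]) ** 2 + (glon - slon[None, None, :]) ** 2
    d = np.sqrt(d2)
    in_radius = d <= radius_deg

    out = np.full((grid.n_lat, grid.n_lon), np.nan)
    # exact hits: distance-zero convention
    exact = d < 1e-9
    with np.errstate(divide="ignore"):
        w = np.where(in_radius & ~exact, d ** (-power), 0.0)
    wsum = w.sum(axis=2)
    has_w = wsum > 0
    num = (w * sval[None, None, :]).sum(axis=2)
    out[has_w] = num[has_w] / wsum[has_w]
    hit_any = exact.any(axis=2)
    if hit_any.any():
        first_hit = np.argmax(exact, axis=2)
        out[hit_any] = sval[first_hit[hit_any]]
    return ThresholdMap(grid=grid, values=out, method=method)


def combine_maps(
    lu: ThresholdMap, obs: ThresholdMap, mask: RegionMask
) -> ThresholdMap:
    """Regional combination: LU in the north, OBS elsewhere where defined.

    Southern cells where the OBS map is undefined fall back to LU.
    """
    if lu.grid != obs.grid or lu.grid != mask.grid:
        raise ValueError("threshold maps and region mask must share the grid")
    north = mask.is_north
    out = np.where(north, lu.values, np.where(obs.defined, obs.values, lu.values))
    return ThresholdMap(grid=lu.grid, values=out, method="COMB")


def predict_start_map(
    temps: GriddedTemperature,
    thresholds: ThresholdMap,
    params: HeatSumParams = HeatSumParams(),
) -> np.ndarray:
    """First flowering day per grid cell (datetime64; NaT where undefined).

    Applies the first-crossing rule cell-wise with the cell's threshold;
    cells with an undefined threshold, or whose heat sum never reaches it,
    come back NaT.
    """
    if temps.grid != thresholds.grid:
        raise ValueError("temperature and threshold grids differ")
    daily = daily_mean(temps)
    idx = pd.DatetimeIndex(daily.data.time.values)
    start = params.start_for_year(idx[0].year)
    sel = idx >= start
    vals = daily.data.values[sel]  # (n_days, n_lat, n_lon)
    days = idx[sel]
    excess = np.maximum(vals - params.cutoff, 0.0)
    cum = np.cumsum(excess, axis=0)
    thr = thresholds.values[None, :, :]
    reached = cum >= thr
    any_hit = reached.any(axis=0) & thresholds.defined
    first = np.argmax(reached, axis=0)
    out = np.full(thresholds.values.shape, np.datetime64("NaT"), dtype="datetime64[ns]")
    out[any_hit] = days.values[first[any_hit]]
    return out


def predict_station_starts(
    temps: GriddedTemperature,
    thresholds: ThresholdMap,
    stations: Sequence[Tuple[str, float, float]],
    params: HeatSumParams = HeatSumParams(),
) -> dict[str, Optional[pd.Timestamp]]:
    """First flowering day at each station's grid cell (None if not reached)."""
    start_map = predict_start_map(temps, thresholds, params)
    out: dict[str, Optional[pd.Timestamp]] = {}
    for sid, lat, lon in stations:
        i, j = temps.grid.nearest_cell(lat, lon)
        val = start_map[i, j]
        out[sid] = None if np.isnat(val) else pd.Timestamp(val)
    return out
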