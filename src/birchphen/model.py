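"""Model/results interface for fitting flowering-threshold maps.

:class:`FloweringModel` bundles the data a threshold fit needs — a gridded
temperature driver plus station observations (leaf-unfolding dates and/or
pollen series) — and ``fit()`` returns a :class:`FloweringResults` carrying
the fitted threshold map, the per-station thresholds behind it, prediction
methods and a date-recovery diagnostic, in the spirit of the model/results
split used by statistical modelling packages.

    >>> model = FloweringModel(temps, leaf_unfolding=records)
    >>> res = model.fit(method="lu")
    >>> res.threshold_map          # gridded degree-day thresholds
    >>> res.predict_station_starts()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .grids import GriddedTemperature, RegionMask, ThresholdMap
from .phenology import (
    HeatSumParams,
    combine_maps,
    daily_mean,
    fit_threshold_lu,
    fit_threshold_obs,
    interpolate_thresholds,
    predict_start_map,
    predict_station_starts,
)
from .season import DateStats, cumulative_fraction_date, date_stats
from .stations import PhenologyRecord, StationSeries

__all__ = ["FloweringModel", "FloweringResults"]


class FloweringModel:
    """Degree-day flowering model to be fitted against station observations.

    Parameters
    ----------
    temperatures
        Gridded temperature driver (3-hourly or daily; reduced to daily
        means internally).
    leaf_unfolding
        Station leaf-unfolding records; required for the LU and COMB fits.
    pollen
        Station pollen series; required for the OBS and COMB fits.
    params
        Heat-sum accumulation constants (1 March start, 3.5 degC cut-off).
    season_q
        Cumulative fraction declaring the season start in the OBS fit
        (default 2.5 %).
    region_mask
        North/south combination mask for the COMB fit; defaults to a
        latitude split at ``north_boundary_lat``.
    idw_power, idw_radius_deg
        Inverse-distance interpolation settings for gridding station
        thresholds.
    """

    def __init__(
        self,
        temperatures: GriddedTemperature,
        leaf_unfolding: Optional[Sequence[PhenologyRecord]] = None,
        pollen: Optional[Sequence[StationSeries]] = None,
        params: HeatSumParams = HeatSumParams(),
        season_q: float = 0.025,
        region_mask: Optional[RegionMask] = None,
        north_boundary_lat: float = 60.0,
        idw_power: float = 2.0,
        idw_radius_deg: float = 5.0,
    ) -> None:
        self.temperatures = daily_mean(temperatures)
        self.leaf_unfolding = list(leaf_unfolding) if leaf_unfolding else None
        self.pollen = list(pollen) if pollen else None
        self.params = params
        self.season_q = season_q
        self.region_mask = region_mask or RegionMask.latitude_band(
            temperatures.grid, north_boundary_lat
        )
        self.idw_power = idw_power
        self.idw_radius_deg = idw_radius_deg

    @classmethod
    def from_files(
        cls,
        temperature_nc,
        leaf_unfolding_csv=None,
        pollen_csv=None,
        **kwargs,
    ) -> "FloweringModel":
        """Build the model from the on-disk formats (NetCDF + CSV)."""
        from . import io

        temps = io.read_temperature(temperature_nc)
        records = (
            io.read_phenology_records(leaf_unfolding_csv)
            if leaf_unfolding_csv
            else None
        )
        pollen = io.read_station_series(pollen_csv) if pollen_csv else None
        return cls(temps, leaf_unfolding=records, pollen=pollen, **kwargs)

    # -- fitting -----------------------------------------------------------

    def _station_thresholds(self, method: str) -> pd.DataFrame:
        if method == "lu":
            if not self.leaf_unfolding:
                raise ValueError("LU fit requires leaf-unfolding records")
            return fit_threshold_lu(self.temperatures, self.leaf_unfolding, self.params)
        if method == "obs":
            if not self.pollen:
                raise ValueError("OBS fit requires pollen series")
            return fit_threshold_obs(
                self.temperatures, self.pollen, self.params, q=self.season_q
            )
        raise ValueError(f"unknown fitting method '{method}'")

    def _gridded(self, station_thresholds: pd.DataFrame, tag: str) -> ThresholdMap:
        return interpolate_thresholds(
            station_thresholds,
            self.temperatures.grid,
            method=tag,
            power=self.idw_power,
            radius_deg=self.idw_radius_deg,
        )

    def fit(self, method: str = "comb") -> "FloweringResults":
        """Fit a threshold map with method ``"lu"``, ``"obs"`` or ``"comb"``."""
        method = method.lower()
        if method in ("lu", "obs"):
            st = self._station_thresholds(method)
            if st.empty:
                raise ValueError(f"no station thresholds could be fitted ({method})")
            tmap = self._gridded(st, method.upper())
            return FloweringResults(self, tmap, st, method.upper())
        if method == "comb":
            lu_st = self._station_thresholds("lu")
            obs_st = self._station_thresholds("obs")
            lu_map = self._gridded(lu_st, "LU")
            obs_map = self._gridded(obs_st, "OBS")
            tmap = combine_maps(lu_map, obs_map, self.region_mask)
            st = pd.concat(
                [lu_st.assign(source="LU"), obs_st.assign(source="OBS")],
                ignore_index=True,
            )
            return FloweringResults(self, tmap, st, "COMB")
        raise ValueError(f"unknown fitting method '{method}'")

    # -- observed dates used for diagnostics -------------------------------

    def observed_start_dates(self) -> dict[str, pd.Timestamp]:
        """Observed flowering-start proxies at the fitting stations.

        Leaf-unfolding dates where available; otherwise pollen-season start
        dates under the model's cumulative criterion.
        """
        dates: dict[str, pd.Timestamp] = {}
        if self.pollen:
            for st in self.pollen:
                try:
                    dates[st.station_id] = cumulative_fraction_date(st, self.season_q)
                except ValueError:
                    continue
        if self.leaf_unfolding:
            for rec in self.leaf_unfolding:
                if not rec.missing:
                    dates[rec.station_id] = rec.leaf_unfolding_date
        return dates

    def station_locations(self) -> list[Tuple[str, float, float]]:
        locs: dict[str, Tuple[str, float, float]] = {}
        for rec in self.leaf_unfolding or []:
            locs[rec.station_id] = (rec.station_id, rec.lat, rec.lon)
        for st in self.pollen or []:
            locs[st.station_id] = (st.station_id, st.lat, st.lon)
        return list(locs.values())


@dataclass
class FloweringResults:
    """Fitted threshold map plus predictions and diagnostics."""

    model: FloweringModel
    threshold_map: ThresholdMap
    station_thresholds: pd.DataFrame
    method: str
    _date_stats: Optional[DateStats] = field(default=None, repr=False)

    def predict_start_map(
        self, temperatures: Optional[GriddedTemperature] = None
    ) -> np.ndarray:
        """Per-cell first flowering day under the fitted thresholds."""
        temps = temperatures or self.model.temperatures
        return predict_start_map(temps, self.threshold_map, self.model.params)

    def predict_station_starts(
        self,
        stations: Optional[Sequence[Tuple[str, float, float]]] = None,
        temperatures: Optional[GriddedTemperature] = None,
    ) -> dict[str, Optional[pd.Timestamp]]:
        temps = temperatures or self.model.temperatures
        stations = stations or self.model.station_locations()
        return predict_station_starts(temps, self.threshold_map, stations, self.model.params)

    def date_recovery(self) -> DateStats:
        """Bias/RMSE of predicted start dates against the observed proxies."""
        if self._date_stats is None:
            obs = self.model.observed_start_dates()
            pred = self.predict_station_starts()
            self._date_stats = date_stats(obs, pred)
        return self._date_stats

    def summary(self) -> str:
        """Plain-text fit summary."""
        vals = self.threshold_map.values[self.threshold_map.defined]
        lines = [
            "Flowering threshold fit",
            "=" * 47,
            f"{'method':<28}{self.method:>19}",
            f"{'stations fitted':<28}{len(self.station_thresholds):>19}",
            f"{'grid cells defined':<28}{int(self.threshold_map.defined.sum()):>19}",
            f"{'cut-off temperature (degC)':<28}{self.model.params.cutoff:>19.2f}",
            f"{'threshold mean (dd)':<28}{vals.mean():>19.2f}",
            f"{'threshold sd (dd)':<28}{vals.std(ddof=0):>19.2f}",
            f"{'threshold range (dd)':<28}"
            f"{f'{vals.min():.1f} - {vals.max():.1f}':>19}",
        ]
        try:
            ds = self.date_recovery()
            lines += [
                f"{'start-date bias (days)':<28}{ds.bias:>19.2f}",
                f"{'start-date RMSE (days)':<28}{ds.rmse:>19.2f}",
                f"{'stations compared':<28}{ds.n:>19}",
            ]
        except ValueError:
            lines.append("start-date diagnostic: not available")
        lines.append("=" * 47)
        return "\n".join(lines)

    def plot_threshold_map(self, ax=None):
        """Colour map of the fitted thresholds (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        g = self.threshold_map.grid
        im = ax.pcolormesh(g.lons, g.lats, self.threshold_map.values, shading="nearest")
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        ax.set_title(f"Heat-sum threshold map ({self.method})")
        plt.colorbar(im, ax=ax, label="degree-days")
        return ax
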