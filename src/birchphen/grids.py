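"""Gridded containers for the phenology pipeline.

The temperature driver, the fitted heat-sum threshold maps and the regional
combination mask all live on the same regular latitude/longitude grid.  The
containers here are thin, validated wrappers around :class:`xarray.DataArray`
(for the time-resolved temperature field) and plain NumPy arrays (for static
per-cell fields), so that downstream code can rely on a consistent cell
geometry without re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "GridSpec",
    "GriddedTemperature",
    "ThresholdMap",
    "RegionMask",
]

#: Physical plausibility bounds for near-surface air temperature (degC).
TEMP_MIN, TEMP_MAX = -60.0, 50.0

#: Lower clip for fitted heat-sum thresholds (degree-days).  A threshold of
#: exactly zero would declare flowering on the accumulation start date
#: regardless of temperature, which is never a meaningful fit.
THRESHOLD_FLOOR = 1.0


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid defined by its bounding box and resolution.

    Cell centres sit at ``min + (i + 0.5) * resolution``; the box must hold
    at least a 2 x 2 block of cells.
    """

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 0.25

    def __post_init__(self) -> None:
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ValueError("latitude bounds must satisfy -90 <= min < max <= 90")
        if not self.lon_min < self.lon_max:
            raise ValueError("longitude bounds must satisfy min < max")
        if self.n_lat < 2 or self.n_lon < 2:
            raise ValueError("grid must contain at least 2 x 2 cells")

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def lats(self) -> np.ndarray:
        """Cell-centre latitudes, south to north."""
        return self.lat_min + (np.arange(self.n_lat) + 0.5) * self.resolution

    @property
    def lons(self) -> np.ndarray:
        """Cell-centre longitudes, west to east."""
        return self.lon_min + (np.arange(self.n_lon) + 0.5) * self.resolution

    def contains(self, lat: float, lon: float) -> bool:
        return (self.lat_min <= lat <= self.lat_max) and (
            self.lon_min <= lon <= self.lon_max
        )

    def nearest_cell(self, lat: float, lon: float) -> tuple[int, int]:
        """Indices of the cell whose centre is nearest to a point.

        Raises ``ValueError`` for points outside the bounding box: stations
        are mapped to cells, never extrapolated.
        """
        if not self.contains(lat, lon):
            raise ValueError(f"point ({lat}, {lon}) lies outside the grid")
        i = int(np.argmin(np.abs(self.lats - lat)))
        j = int(np.argmin(np.abs(self.lons - lon)))
        return i, j


def _validate_time_axis(times: pd.DatetimeIndex) -> pd.Timedelta:
    if len(times) < 2:
        raise ValueError("need at least two timesteps")
    deltas = np.diff(times.values)
    if not (deltas > np.timedelta64(0, "s")).all():
        raise ValueError("time axis must be strictly increasing")
    if len(set(deltas.tolist())) != 1:
        raise ValueError("time axis must be equally spaced")
    return pd.Timedelta(deltas[0])


@dataclass
class GriddedTemperature:
    """Near-surface temperature (degC) on a regular grid over a date range.

    ``data`` has dims ``(time, lat, lon)``; the time axis is strictly
    increasing and equally spaced (3-hourly or daily in practice).
    """

    grid: GridSpec
    data: xr.DataArray

    def __post_init__(self) -> None:
        if tuple(self.data.dims) != ("time", "lat", "lon"):
            raise ValueError("data must have dims (time, lat, lon)")
        if self.data.shape[1:] != (self.grid.n_lat, self.grid.n_lon):
            raise ValueError("data shape does not match grid")
        times = pd.DatetimeIndex(self.data.time.values)
        self.step = _validate_time_axis(times)
        vals = self.data.values
        if not np.isfinite(vals).all():
            raise ValueError("temperature field contains non-finite values")
        if vals.min() < TEMP_MIN or vals.max() > TEMP_MAX:
            raise ValueError(
                f"temperatures outside plausible range [{TEMP_MIN}, {TEMP_MAX}] degC"
            )

    @classmethod
    def from_array(
        cls,
        grid: GridSpec,
        times: Sequence,
        values: np.ndarray,
    ) -> "GriddedTemperature":
        da = xr.DataArray(
            np.asarray(values, dtype=float),
            dims=("time", "lat", "lon"),
            coords={
                "time": pd.DatetimeIndex(times),
                "lat": grid.lats,
                "lon": grid.lons,
            },
            name="t2m",
            attrs={"units": "degC", "long_name": "near-surface air temperature"},
        )
        return cls(grid=grid, data=da)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.time.values)

    @property
    def is_daily(self) -> bool:
        return self.step == pd.Timedelta(days=1)

    def cell_series(self, i: int, j: int) -> pd.Series:
        """Temperature time series at cell (i, j)."""
        return pd.Series(self.data.values[:, i, j], index=self.times)

    def station_series(self, lat: float, lon: float) -> pd.Series:
        """Temperature series at the grid cell nearest to a station."""
        i, j = self.grid.nearest_cell(lat, lon)
        return self.cell_series(i, j)


@dataclass
class ThresholdMap:
    """Gridded heat-sum thresholds (degree-days) with a provenance tag.

    ``values`` is ``(n_lat, n_lon)`` with NaN marking cells where no
    threshold could be fitted.  ``method`` records how the map was built:
    ``LU`` (leaf-unfolding dates), ``OBS`` (pollen-count season starts),
    ``COMB`` (regional combination) or ``TRUTH`` (synthetic ground truth).
    """

    grid: GridSpec
    values: np.ndarray
    method: str

    VALID_METHODS = ("LU", "OBS", "COMB", "TRUTH")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_lat, self.grid.n_lon):
            raise ValueError("threshold array shape does not match grid")
        if self.method not in self.VALID_METHODS:
            raise ValueError(f"method must be one of {self.VALID_METHODS}")
        defined = self.values[np.isfinite(self.values)]
        if defined.size and defined.min() <= 0:
            raise ValueError("defined thresholds must be strictly positive")

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of cells carrying a fitted threshold."""
        return np.isfinite(self.values)

    def at_station(self, lat: float, lon: float) -> float:
        i, j = self.grid.nearest_cell(lat, lon)
        return float(self.values[i, j])


@dataclass
class RegionMask:
    """Per-cell region labels plus the subset of labels treated as 'north'.

    Used to combine threshold maps: northern cells take the leaf-unfolding
    fit, the rest take the pollen-count fit where available.
    """

    grid: GridSpec
    labels: np.ndarray
    north_labels: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.grid.n_lat, self.grid.n_lon):
            raise ValueError("label array shape does not match grid")
        if any(lbl is None for lbl in self.labels.ravel()):
            raise ValueError("every cell must carry a label")
        self.north_labels = frozenset(self.north_labels)

    @property
    def is_north(self) -> np.ndarray:
        return np.isin(self.labels, list(self.north_labels))

    @classmethod
    def latitude_band(cls, grid: GridSpec, boundary_lat: float) -> "RegionMask":
        """Two-band mask: cells at/above ``boundary_lat`` are 'north'."""
        north = grid.lats[:, None] >= boundary_lat
        labels = np.where(north, "north", "central-south")
        labels = np.broadcast_to(labels, (grid.n_lat, grid.n_lon)).copy()
        return cls(grid=grid, labels=labels, north_labels=frozenset({"north"}))
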