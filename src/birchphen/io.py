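"""File formats: CF-style NetCDF for gridded fields, CSV for station data.

Gridded temperature is stored as variable ``t2m`` (units ``degC``) with
``time/lat/lon`` dimensions; threshold maps as ``heat_sum_threshold``
(units ``degree_days``) with the fitting method in a global attribute.
Station series use a long CSV with one row per station-day and an explicit
``observed`` flag; leaf-unfolding records one row per station with an empty
field for a missing date.  Dates are ISO-8601 throughout.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .grids import GriddedTemperature, GridSpec, ThresholdMap
from .stations import PhenologyRecord, StationSeries, records_to_frame, series_to_frame

__all__ = [
    "write_temperature",
    "read_temperature",
    "write_threshold_map",
    "read_threshold_map",
    "write_station_series",
    "read_station_series",
    "write_phenology_records",
    "read_phenology_records",
]

_ENGINE = "scipy"  # NetCDF3 backend; no external netCDF library required


def _grid_from_coords(lats: np.ndarray, lons: np.ndarray) -> GridSpec:
    res = float(lats[1] - lats[0])
    return GridSpec(
        lat_min=float(lats[0] - res / 2),
        lat_max=float(lats[-1] + res / 2),
        lon_min=float(lons[0] - res / 2),
        lon_max=float(lons[-1] + res / 2),
        resolution=res,
    )


def write_temperature(temps: GriddedTemperature, path) -> None:
    ds = temps.data.to_dataset(name="t2m")
    ds.t2m.attrs.update(units="degC", standard_name="air_temperature")
    ds.lat.attrs.update(units="degrees_north", standard_name="latitude")
    ds.lon.attrs.update(units="degrees_east", standard_name="longitude")
    ds.attrs["Conventions"] = "CF-1.8"
    ds.to_netcdf(path, engine=_ENGINE)


def read_temperature(path) -> GriddedTemperature:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        da = ds["t2m"].load()
    grid = _grid_from_coords(da.lat.values, da.lon.values)
    return GriddedTemperature.from_array(grid, pd.DatetimeIndex(da.time.values), da.values)


def write_threshold_map(tmap: ThresholdMap, path) -> None:
    ds = xr.Dataset(
        {
            "heat_sum_threshold": (
                ("lat", "lon"),
                tmap.values,
                {"units": "degree_days", "long_name": "heat sum threshold"},
            )
        },
        coords={"lat": tmap.grid.lats, "lon": tmap.grid.lons},
        attrs={"Conventions": "CF-1.8", "method": tmap.method},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def read_threshold_map(path) -> ThresholdMap:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        da = ds["heat_sum_threshold"].load()
        method = str(ds.attrs.get("method", "TRUTH"))
    grid = _grid_from_coords(da.lat.values, da.lon.values)
    return ThresholdMap(grid=grid, values=da.values, method=method)


def write_station_series(series: Sequence[StationSeries], path) -> None:
    df = series_to_frame(series)
    df["date"] = pd.DatetimeIndex(df["date"]).strftime("%Y-%m-%d")
    df["conc"] = np.where(df["observed"], df["conc"], "")
    df.to_csv(path, index=False)


def read_station_series(path) -> list[StationSeries]:
    df = pd.read_csv(path, parse_dates=["date"])
    out = []
    for sid, g in df.groupby("station_id", sort=True):
        g = g.sort_values("date")
        observed = g["observed"].astype(bool).to_numpy()
        conc = pd.to_numeric(g["conc"], errors="coerce").to_numpy(dtype=float)
        out.append(
            StationSeries(
                station_id=str(sid),
                lat=float(g["lat"].iloc[0]),
                lon=float(g["lon"].iloc[0]),
                dates=pd.DatetimeIndex(g["date"]),
                conc=conc,
                observed=observed,
            )
        )
    return out


def write_phenology_records(records: Sequence[PhenologyRecord], path) -> None:
    df = records_to_frame(records)
    df["lu_date"] = [
        "" if pd.isna(d) else pd.Timestamp(d).strftime("%Y-%m-%d") for d in df["lu_date"]
    ]
    df.to_csv(path, index=False)


def read_phenology_records(path) -> list[PhenologyRecord]:
    df = pd.read_csv(path, dtype={"station_id": str})
    out = []
    for _, row in df.iterrows():
        raw = row["lu_date"]
        date = None if pd.isna(raw) or str(raw) == "" else pd.Timestamp(raw)
        out.append(
            PhenologyRecord(
                station_id=str(row["station_id"]),
                lat=float(row["lat"]),
                lon=float(row["lon"]),
                leaf_unfolding_date=date,
            )
        )
    return out
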