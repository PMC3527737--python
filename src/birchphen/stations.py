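"""Station-level observation containers.

A pollen monitoring station reports one daily concentration (grains m^-3);
days without a count are recorded through an explicit boolean mask rather
than by dropping rows, so every series is gap-free on the calendar axis.
Leaf-unfolding records carry a single phenological event date per station.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["StationSeries", "PhenologyRecord"]


@dataclass
class StationSeries:
    """One station's daily pollen concentration series with a missing mask.

    ``conc`` holds grains m^-3 per calendar day; entries on unobserved days
    are carried as NaN and excluded from all statistics via ``observed``.
    """

    station_id: str
    lat: float
    lon: float
    dates: pd.DatetimeIndex
    conc: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.conc = np.asarray(self.conc, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        n = len(self.dates)
        if len(self.conc) != n or len(self.observed) != n:
            raise ValueError("dates, conc and observed must share length")
        if n == 0:
            raise ValueError("series must cover at least one day")
        deltas = np.diff(self.dates.values)
        if n > 1 and not (deltas == np.timedelta64(1, "D")).all():
            raise ValueError(
                "dates must be consecutive calendar days (missing days are "
                "mask entries, not absent rows)"
            )
        obs_vals = self.conc[self.observed]
        if obs_vals.size and (np.isnan(obs_vals).any() or (obs_vals < 0).any()):
            raise ValueError("observed concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def n_missing(self) -> int:
        return int(len(self) - self.observed.sum())

    def to_series(self, missing_as_zero: bool = False) -> pd.Series:
        """Concentration series; unobserved days are NaN (or zero)."""
        vals = np.where(self.observed, self.conc, 0.0 if missing_as_zero else np.nan)
        return pd.Series(vals, index=self.dates, name=self.station_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_id": self.station_id,
                "lat": self.lat,
                "lon": self.lon,
                "date": self.dates,
                "conc": self.conc,
                "observed": self.observed,
            }
        )

    def window(self, start, end) -> "StationSeries":
        """Sub-series over [start, end] (inclusive calendar window)."""
        sel = (self.dates >= pd.Timestamp(start)) & (self.dates <= pd.Timestamp(end))
        if not sel.any():
            raise ValueError("window does not overlap the series")
        return StationSeries(
            self.station_id,
            self.lat,
            self.lon,
            self.dates[sel],
            self.conc[sel],
            self.observed[sel],
        )


@dataclass(frozen=True)
class PhenologyRecord:
    """Leaf-unfolding date for one station; ``None`` when not observed."""

    station_id: str
    lat: float
    lon: float
    leaf_unfolding_date: Optional[pd.Timestamp]

    @property
    def missing(self) -> bool:
        return self.leaf_unfolding_date is None


def series_to_frame(series: Sequence[StationSeries]) -> pd.DataFrame:
    """Long-format frame for a set of station series."""
    return pd.concat([s.to_frame() for s in series], ignore_index=True)


def records_to_frame(records: Sequence[PhenologyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "station_id": [r.station_id for r in records],
            "lat": [r.lat for r in records],
            "lon": [r.lon for r in records],
            "lu_date": [r.leaf_unfolding_date for r in records],
        }
    )
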