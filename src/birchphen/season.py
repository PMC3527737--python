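"""Pollen-season definition by cumulative-percentage criteria.

The flowering season is declared started on the earliest day on which the
cumulative pollen count reaches a given fraction (2.5 % or 5 %) of the
seasonal sum, and ended when it reaches 95 %.  Because the criteria are
fractions of the total, season dates are invariant under rescaling of the
whole series.  Start/end date comparisons between observation and model use
the convention bias = mean(observed - predicted), so a positive bias means
the prediction is, on average, too early.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .stations import StationSeries

__all__ = [
    "SeasonCriteria",
    "SeasonDates",
    "DateStats",
    "cumulative_fraction_date",
    "season_dates",
    "date_stats",
]

#: Default analysis window (month, day): birch seasonal totals in Europe are
#: dominated by March-June.
DEFAULT_WINDOW = ((3, 1), (6, 30))


@dataclass(frozen=True)
class SeasonCriteria:
    """Cumulative fractions declaring season start and end."""

    start_fraction: float = 0.025
    end_fraction: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.start_fraction < self.end_fraction < 1.0):
            raise ValueError("need 0 < start_fraction < end_fraction < 1")


@dataclass(frozen=True)
class SeasonDates:
    """Season start/end plus the seasonal sum over the analysis window."""

    start: pd.Timestamp
    end: pd.Timestamp
    total: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("season start must not follow season end")
        if not self.total > 0:
            raise ValueError("seasonal total must be positive")


@dataclass(frozen=True)
class DateStats:
    """Bias and RMSE of predicted dates against observed dates (days).

    ``bias = mean(observed - predicted)``: positive means predictions run
    too early, negative too late.
    """

    bias: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one station pair")
        if self.rmse < abs(self.bias) - 1e-9:
            raise ValueError("rmse cannot be smaller than |bias|")


def _window_bounds(
    dates: pd.DatetimeIndex, window: Optional[Tuple] = None
) -> tuple[pd.Timestamp, pd.Timestamp]:
    if window is None:
        year = dates[0].year
        (m0, d0), (m1, d1) = DEFAULT_WINDOW
        lo, hi = pd.Timestamp(year, m0, d0), pd.Timestamp(year, m1, d1)
    else:
        lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    lo = max(lo, dates[0])
    hi = min(hi, dates[-1])
    if lo > hi:
        raise ValueError("analysis window does not overlap the series")
    return lo, hi


def cumulative_fraction_date(
    series: StationSeries, q: float, window: Optional[Tuple] = None
) -> pd.Timestamp:
    """Earliest day on which the cumulative count reaches ``q`` of the total.

    Unobserved days contribute zero (no gap-filling).  Raises ``ValueError``
    when the window total is zero or the whole window is unmasked.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    lo, hi = _window_bounds(series.dates, window)
    sub = series.window(lo, hi)
    vals = np.where(sub.observed, sub.conc, 0.0)
    total = vals.sum()
    if total <= 0:
        raise ValueError(
            f"station {series.station_id}: no positive pollen count in window"
        )
    cum = np.cumsum(vals)
    idx = int(np.searchsorted(cum, q * total))  # first cum >= q*total
    return sub.dates[idx]


def season_dates(
    series: StationSeries,
    criteria: SeasonCriteria = SeasonCriteria(),
    window: Optional[Tuple] = None,
    warn_censored_end: bool = True,
) -> SeasonDates:
    """Season start and end dates under cumulative-percentage criteria."""
    lo, hi = _window_bounds(series.dates, window)
    start = cumulative_fraction_date(series, criteria.start_fraction, (lo, hi))
    end = cumulative_fraction_date(series, criteria.end_fraction, (lo, hi))
    if warn_censored_end and end == hi:
        warnings.warn(
            f"station {series.station_id}: 95% date falls on the window edge; "
            "the true season end may be censored",
            stacklevel=2,
        )
    sub = series.window(lo, hi)
    total = float(np.where(sub.observed, sub.conc, 0.0).sum())
    return SeasonDates(start=start, end=end, total=total)


def date_stats(
    obs_dates: Mapping[str, pd.Timestamp],
    pred_dates: Mapping[str, pd.Timestamp],
) -> DateStats:
    """Bias and RMSE over stations present, with a defined date, in both sets."""
    common = [
        k
        for k in obs_dates
        if k in pred_dates
        and obs_dates[k] is not None
        and pred_dates[k] is not None
        and not pd.isna(obs_dates[k])
        and not pd.isna(pred_dates[k])
    ]
    if not common:
        raise ValueError("no station pairs with defined dates on both sides")
    resid = np.array(
        [
            (pd.Timestamp(obs_dates[k]) - pd.Timestamp(pred_dates[k])).days
            for k in common
        ],
        dtype=float,
    )
    return DateStats(
        bias=float(resid.mean()),
        rmse=float(np.sqrt((resid**2).mean())),
        n=len(common),
    )
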