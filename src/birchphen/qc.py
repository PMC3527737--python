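"""Station completeness quality control.

A station enters the evaluation only if its reporting record is complete
enough that season dates and exceedance statistics are meaningful.  Four
rules are applied:

* **A — April/May completeness:** at least 45 observed days during April
  and May (roughly three-quarters of the 61-day period).
* **B — homogeneity:** April reporting must be at least as complete as
  March reporting (guards against stations that start reporting only once
  the season is obviously under way).  The comparison is between monthly
  completeness fractions - observed days over calendar days of the month
  inside the window - so that a station reporting every single day is not
  penalised merely because March is one day longer than April.
* **C — active-season coverage:** for *every* model run supplied, the
  station must have observations on at least 80 % of the days on which that
  run predicts non-zero pollen.
* **Relaxation of C:** because different model setups disagree about which
  days carry pollen, rule C is waived if for *any single* run the station
  missed at most 1 predicted non-zero day.

A station passes iff A and B hold and (C or its relaxation) holds.  Failing
stations report every violated rule, not just the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stations import StationSeries

__all__ = ["QCConfig", "QCResult", "QCNetworkSummary", "qc_station", "qc_network"]

RULE_APRIL_MAY = "A_april_may_days"
RULE_HOMOGENEITY = "B_march_april_homogeneity"
RULE_ACTIVE_SEASON = "C_active_season_coverage"


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the four completeness rules.

    ``completeness_fraction`` documents the ~75 % gloss on the 45/61-day
    rule; the operative count is ``min_apr_may_days``.
    """

    min_apr_may_days: int = 45
    completeness_fraction: float = 0.75
    active_season_coverage: float = 0.80
    relaxation_max_missed: int = 1

    def __post_init__(self) -> None:
        if self.min_apr_may_days < 1:
            raise ValueError("min_apr_may_days must be at least 1")
        if not 0.0 < self.active_season_coverage <= 1.0:
            raise ValueError("active_season_coverage must lie in (0, 1]")
        if self.relaxation_max_missed < 0:
            raise ValueError("relaxation_max_missed must be non-negative")


@dataclass(frozen=True)
class QCResult:
    station_id: str
    passed: bool
    reasons: tuple
    apr_may_days: int
    march_days: int
    april_days: int
    run_coverage: Mapping[str, float] = field(default_factory=dict)
    run_missed_days: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to an empty reason list")


@dataclass(frozen=True)
class QCNetworkSummary:
    results: tuple
    n_total: int
    n_kept: int
    rule_fail_counts: Mapping[str, int]

    @property
    def retention(self) -> float:
        return self.n_kept / self.n_total

    @property
    def kept_ids(self) -> list[str]:
        return [r.station_id for r in self.results if r.passed]


def qc_station(
    series: StationSeries,
    model_nonzero_masks: Mapping[str, np.ndarray],
    cfg: QCConfig = QCConfig(),
) -> QCResult:
    """Apply the four completeness rules to one station.

    ``model_nonzero_masks`` maps run name to a boolean per-day mask, aligned
    with ``series.dates``, marking days with predicted non-zero pollen at
    the station's cell.
    """
    for run, mask in model_nonzero_masks.items():
        if len(mask) != len(series):
            raise ValueError(
                f"run '{run}' mask length {len(mask)} does not match the "
                f"{len(series)}-day station window"
            )
    months = series.dates.month
    obs = series.observed
    apr_may = int(obs[(months == 4) | (months == 5)].sum())
    march = int(obs[months == 3].sum())
    april = int(obs[months == 4].sum())
    n_march = int((months == 3).sum())
    n_april = int((months == 4).sum())

    reasons = []
    if apr_may < cfg.min_apr_may_days:
        reasons.append(RULE_APRIL_MAY)
    march_frac = march / n_march if n_march else 0.0
    april_frac = april / n_april if n_april else 1.0
    if april_frac < march_frac:
        reasons.append(RULE_HOMOGENEITY)

    coverage: dict[str, float] = {}
    missed: dict[str, int] = {}
    for run, mask in model_nonzero_masks.items():
        mask = np.asarray(mask, dtype=bool)
        n_active = int(mask.sum())
        n_covered = int((mask & obs).sum())
        coverage[run] = n_covered / n_active if n_active else 1.0
        missed[run] = n_active - n_covered
    if model_nonzero_masks:
        rule_c = all(c >= cfg.active_season_coverage for c in coverage.values())
        relaxed = any(m <= cfg.relaxation_max_missed for m in missed.values())
        if not (rule_c or relaxed):
            reasons.append(RULE_ACTIVE_SEASON)

    return QCResult(
        station_id=series.station_id,
        passed=not reasons,
        reasons=tuple(reasons),
        apr_may_days=apr_may,
        march_days=march,
        april_days=april,
        run_coverage=coverage,
        run_missed_days=missed,
    )


def qc_network(
    stations: Sequence[StationSeries],
    masks_by_station: Mapping[str, Mapping[str, np.ndarray]],
    cfg: QCConfig = QCConfig(),
) -> QCNetworkSummary:
    """QC every station; report retention and per-rule failure counts."""
    if not stations:
        raise ValueError("empty station network")
    results = tuple(
        qc_station(s, masks_by_station.get(s.station_id, {}), cfg) for s in stations
    )
    fail_counts = {RULE_APRIL_MAY: 0, RULE_HOMOGENEITY: 0, RULE_ACTIVE_SEASON: 0}
    for r in results:
        for reason in r.reasons:
            fail_counts[reason] += 1
    return QCNetworkSummary(
        results=results,
        n_total=len(results),
        n_kept=sum(r.passed for r in results),
        rule_fail_counts=fail_counts,
    )


def qc_report_frame(summary: QCNetworkSummary) -> pd.DataFrame:
    """Flat report: one row per station with pass flag and reasons."""
    return pd.DataFrame(
        {
            "station_id": [r.station_id for r in summary.results],
            "passed": [r.passed for r in summary.results],
            "reasons": [";".join(r.reasons) for r in summary.results],
        }
    )
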