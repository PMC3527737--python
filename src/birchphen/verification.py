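"""Categorical verification of pollen-concentration forecasts.

Daily concentrations are classified on a five-level scheme (zero < 1,
low 1-10, moderate 10-100, high 100-1000, very high >= 1000 grains m^-3).
Exceedance skill uses a single allergenic threshold of 50 grains m^-3 -
the centre of the moderate class - and the four-cell contingency table of
model-low/high against observed-low/high.  From the table:

    MA   = (N_ll + N_hh) / N_total            fraction correct
    HR   = N_hh / (N_hl + N_hh)               fraction of correct "high" predictions
    FAR  = N_hl / (N_hl + N_hh)               fraction of wrong "high" predictions
    POFD = N_hl / (N_hl + N_ll)               observed-low days predicted "high"
    OR   = HR / POFD                          likelihood-style odds ratio

where ``N_xy`` counts model-class x / observed-class y days.  Note that HR
here shares its denominator with FAR (so HR + FAR = 1 whenever the model
predicts any "high" day); the conventional probability of detection, which
divides by the observed-high count instead, is provided separately as
``pod_standard``.  OR divides HR by POFD - a likelihood ratio, not the
cross-product odds ratio.

Seasonal renormalisation rescales all model series by one common factor so
the network-mean modelled cumulative count up to a cut-off date (31 May)
matches the observed one, compensating for unmodelled year-to-year pollen
production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationClass",
    "VerificationConfig",
    "ContingencyTable",
    "SkillScores",
    "RenormalisationResult",
    "classify",
    "classify_array",
    "class_histogram",
    "contingency",
    "skill_scores",
    "confusion3",
    "setup_agreement",
    "renormalise",
]


class ConcentrationClass(str, Enum):
    """Five-level concentration scheme; boundary values are assigned upward."""

    ZERO = "zero"  # < 1
    LOW = "low"  # [1, 10)
    MODERATE = "moderate"  # [10, 100)
    HIGH = "high"  # [100, 1000)
    VERY_HIGH = "very_high"  # >= 1000


_CLASS_BOUNDS = np.array([1.0, 10.0, 100.0, 1000.0])
_CLASS_ORDER = list(ConcentrationClass)

#: Coarse 3-level grouping used in confusion matrices: zero-or-low (0-10),
#: moderate (10-100), high-or-very-high (>= 100).
COARSE_LABELS = ("zero_low", "moderate", "high")


@dataclass(frozen=True)
class VerificationConfig:
    """Exceedance threshold (grains m^-3) and renormalisation cut-off date."""

    exceedance_threshold: float = 50.0
    renorm_cutoff: tuple = (5, 31)  # (month, day): 31 May

    def __post_init__(self) -> None:
        if not self.exceedance_threshold > 0:
            raise ValueError("exceedance threshold must be positive")


def classify(conc: float) -> ConcentrationClass:
    """Map a daily concentration to its five-level class."""
    if not np.isfinite(conc) or conc < 0:
        raise ValueError("concentration must be finite and non-negative")
    return _CLASS_ORDER[int(np.searchsorted(_CLASS_BOUNDS, conc, side="right"))]


def classify_array(conc: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify`; returns integer class codes 0..4."""
    conc = np.asarray(conc, dtype=float)
    if np.isnan(conc).any() or (conc < 0).any():
        raise ValueError("concentrations must be finite and non-negative")
    return np.searchsorted(_CLASS_BOUNDS, conc, side="right")


def _coarse_codes(conc: np.ndarray) -> np.ndarray:
    """3-level codes: 0 zero/low (<10), 1 moderate, 2 high/very-high (>=100)."""
    fine = classify_array(conc)
    return np.clip(fine - 1, 0, 2)


def class_histogram(values: Sequence[float]) -> dict[str, float]:
    """Fraction of cases per five-level class; NaN (missing) values excluded."""
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no non-missing values to histogram")
    codes = classify_array(vals)
    counts = np.bincount(codes, minlength=5)
    return {c.value: counts[k] / vals.size for k, c in enumerate(_CLASS_ORDER)}


@dataclass(frozen=True)
class ContingencyTable:
    """Counts for the 50 grains m^-3 exceedance dichotomy.

    ``n_ll``: model low, observed low; ``n_lh``: model low, observed high;
    ``n_hl``: model high, observed low; ``n_hh``: model high, observed high.
    """

    n_ll: int
    n_lh: int
    n_hl: int
    n_hh: int

    def __post_init__(self) -> None:
        for name in ("n_ll", "n_lh", "n_hl", "n_hh"):
            if getattr(self, name) < 0:
                raise ValueError("contingency counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_ll + self.n_lh + self.n_hl + self.n_hh

    # marginals, in the observed/model low/high notation
    @property
    def n_obs_low(self) -> int:
        return self.n_ll + self.n_hl

    @property
    def n_obs_high(self) -> int:
        return self.n_lh + self.n_hh

    @property
    def n_model_low(self) -> int:
        return self.n_ll + self.n_lh

    @property
    def n_model_high(self) -> int:
        return self.n_hl + self.n_hh

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(
            self.n_ll + other.n_ll,
            self.n_lh + other.n_lh,
            self.n_hl + other.n_hl,
            self.n_hh + other.n_hh,
        )


@dataclass(frozen=True)
class SkillScores:
    """Skill scores from an exceedance contingency table.

    Scores whose denominator is empty are ``None`` (flagged, never raised),
    except ``odds_ratio`` which is ``math.inf`` when POFD = 0 with a
    positive hit rate.  ``pod_standard`` is the conventional probability of
    detection (observed-high denominator), provided alongside the primary
    model-high-denominator hit rate.
    """

    ma: Optional[float]
    hr: Optional[float]
    far: Optional[float]
    pofd: Optional[float]
    odds_ratio: Optional[float]
    pod_standard: Optional[float]
    table: ContingencyTable

    def to_dict(self) -> dict:
        return {
            "ma": self.ma,
            "hr": self.hr,
            "far": self.far,
            "pofd": self.pofd,
            "odds_ratio": self.odds_ratio,
            "pod_standard": self.pod_standard,
            "n_total": self.table.n_total,
        }


def contingency(
    obs: Sequence[float],
    model: Sequence[float],
    cfg: VerificationConfig = VerificationConfig(),
) -> ContingencyTable:
    """Exceedance contingency table from paired daily values.

    ``high`` means concentration >= threshold.  Pairs where either side is
    NaN (no observation / no prediction) are skipped.
    """
    obs = np.asarray(obs, dtype=float)
    model = np.asarray(model, dtype=float)
    if obs.shape != model.shape:
        raise ValueError("obs and model series must be aligned")
    ok = ~(np.isnan(obs) | np.isnan(model))
    if not ok.any():
        raise ValueError("no valid obs/model pairs")
    o_high = obs[ok] >= cfg.exceedance_threshold
    m_high = model[ok] >= cfg.exceedance_threshold
    return ContingencyTable(
        n_ll=int((~m_high & ~o_high).sum()),
        n_lh=int((~m_high & o_high).sum()),
        n_hl=int((m_high & ~o_high).sum()),
        n_hh=int((m_high & o_high).sum()),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def skill_scores(t: ContingencyTable) -> SkillScores:
    """Evaluate MA, HR, FAR, POFD and OR on a contingency table."""
    if t.n_total == 0:
        raise ValueError("empty contingency table")
    ma = (t.n_ll + t.n_hh) / t.n_total
    hr = _ratio(t.n_hh, t.n_model_high)
    far = _ratio(t.n_hl, t.n_model_high)
    pofd = _ratio(t.n_hl, t.n_hl + t.n_ll)
    if hr is None or pofd is None:
        odds = None
    elif pofd == 0:
        odds = math.inf if hr > 0 else None
    else:
        odds = hr / pofd
    pod = _ratio(t.n_hh, t.n_obs_high)
    return SkillScores(
        ma=ma, hr=hr, far=far, pofd=pofd, odds_ratio=odds, pod_standard=pod, table=t
    )


def confusion3(
    obs: Sequence[float], model: Sequence[float]
) -> pd.DataFrame:
    """Row-normalised confusion matrix: model 3-class vs observed 3-class+no-data.

    Rows are the model's coarse classes; columns are ``no_data`` (observation
    missing) followed by the observed coarse classes.  Each non-empty row
    sums to 1.  Model values must be defined for every day.
    """
    obs = np.asarray(obs, dtype=float)
    model = np.asarray(model, dtype=float)
    if obs.shape != model.shape or obs.size == 0:
        raise ValueError("obs and model must be aligned and non-empty")
    m_codes = _coarse_codes(model)
    counts = np.zeros((3, 4))
    missing = np.isnan(obs)
    for r in range(3):
        in_row = m_codes == r
        counts[r, 0] = (in_row & missing).sum()
        if (in_row & ~missing).any():
            o_codes = _coarse_codes(obs[in_row & ~missing])
            counts[r, 1:] = np.bincount(o_codes, minlength=3)
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        frac = np.where(sums > 0, counts / sums, np.nan)
    return pd.DataFrame(
        frac,
        index=pd.Index(COARSE_LABELS, name="model"),
        columns=["no_data", *COARSE_LABELS],
    )


def setup_agreement(
    pred_a: Sequence[float], pred_b: Sequence[float]
) -> pd.DataFrame:
    """Row-normalised 3x3 agreement matrix between two model setups.

    Rows index setup A's coarse class, columns setup B's.  Days undefined
    in either setup are dropped.
    """
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("the two prediction series must be aligned and non-empty")
    ok = ~(np.isnan(a) | np.isnan(b))
    if not ok.any():
        raise ValueError("no days defined in both setups")
    ca, cb = _coarse_codes(a[ok]), _coarse_codes(b[ok])
    counts = np.zeros((3, 3))
    np.add.at(counts, (ca, cb), 1.0)
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        frac = np.where(sums > 0, counts / sums, np.nan)
    return pd.DataFrame(
        frac,
        index=pd.Index(COARSE_LABELS, name="setup_a"),
        columns=pd.Index(COARSE_LABELS, name="setup_b"),
    )


@dataclass(frozen=True)
class RenormalisationResult:
    """Common scaling factor and the rescaled model series set."""

    factor: float
    scaled_model: Mapping[str, pd.Series]


def _cumulative_to_cutoff(
    series: pd.Series, cutoff: tuple
) -> float:
    idx = pd.DatetimeIndex(series.index)
    cut = pd.Timestamp(idx[0].year, *cutoff)
    vals = series[idx <= cut].to_numpy(dtype=float)
    return float(np.nansum(vals))


def renormalise(
    model: Mapping[str, pd.Series],
    obs: Mapping[str, pd.Series],
    cfg: VerificationConfig = VerificationConfig(),
) -> RenormalisationResult:
    """Scale all model series so mean cumulative counts match by the cut-off.

    ``factor = mean_station(observed cumulative to 31 May) /
    mean_station(modelled cumulative to 31 May)``, computed over the common
    stations; every model concentration is multiplied by it.  Unobserved
    (NaN) days contribute nothing to the cumulative sums.
    """
    common = sorted(set(model) & set(obs))
    if not common:
        raise ValueError("no overlapping stations between model and observations")
    obs_mean = float(
        np.mean([_cumulative_to_cutoff(obs[k], cfg.renorm_cutoff) for k in common])
    )
    model_mean = float(
        np.mean([_cumulative_to_cutoff(model[k], cfg.renorm_cutoff) for k in common])
    )
    if model_mean <= 0:
        raise ValueError("modelled cumulative count is zero; cannot renormalise")
    if obs_mean <= 0:
        raise ValueError("observed cumulative count is zero; cannot renormalise")
    factor = obs_mean / model_mean
    scaled = {k: s * factor for k, s in model.items()}
    return RenormalisationResult(factor=factor, scaled_model=scaled)
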