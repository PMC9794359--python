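"""Agreement between two snoring-rate series.

Quantifies how well two raters of the same recordings agree — detector vs
ground truth, or two detector parameterizations standing in for two human
examiners — with the Pearson product-moment correlation (two-sided p from
the t distribution with n-2 degrees of freedom) plus error summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import AlignmentError, ConfigError

__all__ = ["RateSeries", "DetectionReport", "pearson_r", "spearman_r",
           "evaluate_detection"]


@dataclass(frozen=True)
class RateSeries:
    """Snoring rates (percent) keyed by recording identifier."""

    ids: tuple
    rates: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        rates = np.asarray(self.rates, dtype=np.float64)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "rates", rates)
        if len(ids) != rates.size:
            raise ConfigError("ids and rates must have equal length")
        if len(set(ids)) != len(ids):
            raise ConfigError("recording ids must be unique")
        if rates.size and (rates.min() < 0 or rates.max() > 100):
            raise ConfigError("rates must lie in [0, 100] percent")


def _aligned(a: RateSeries, b: RateSeries) -> tuple[np.ndarray, np.ndarray]:
    if set(a.ids) != set(b.ids):
        raise AlignmentError("the two series cover different recording ids")
    lookup = dict(zip(b.ids, b.rates))
    return a.rates, np.array([lookup[i] for i in a.ids])


def _check_correlatable(x: np.ndarray, y: np.ndarray) -> None:
    if x.size < 3:
        raise ConfigError("correlation needs at least 3 recordings")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConfigError("correlation is undefined for a constant series")


def pearson_r(a: RateSeries, b: RateSeries) -> tuple[float, float]:
    """Pearson correlation between two aligned rate series.

    Returns ``(r, p)`` with a two-sided p-value.  Raises
    :class:`AlignmentError` for mismatched ids and :class:`ConfigError`
    for n < 3 or a constant series.
    """
    x, y = _aligned(a, b)
    _check_correlatable(x, y)
    result = stats.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def spearman_r(a: RateSeries, b: RateSeries) -> tuple[float, float]:
    """Spearman rank correlation, for when ranks are more trustworthy."""
    x, y = _aligned(a, b)
    _check_correlatable(x, y)
    result = stats.spearmanr(x, y)
    return float(result.statistic), float(result.pvalue)


@dataclass(frozen=True)
class DetectionReport:
    """Recovery report: correlation, error summaries, per-recording residuals."""

    pearson_r: float
    p_value: float
    mae: float
    bias: float
    residuals: dict

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "mae_pct_points": self.mae,
            "bias_pct_points": self.bias,
            "residuals": dict(self.residuals),
        }


def evaluate_detection(detected: RateSeries, truth: RateSeries) -> DetectionReport:
    """Compare detected snoring rates against ground truth.

    Residuals are detected minus truth, in percentage points; `mae` is
    their mean absolute value and `bias` their mean.
    """
    det, tru = _aligned(detected, truth)
    _check_correlatable(det, tru)
    r, p = pearson_r(detected, truth)
    residuals = det - tru
    return DetectionReport(
        pearson_r=r,
        p_value=p,
        mae=float(np.mean(np.abs(residuals))),
        bias=float(np.mean(residuals)),
        residuals={i: float(res) for i, res in zip(detected.ids, residuals)},
    )
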