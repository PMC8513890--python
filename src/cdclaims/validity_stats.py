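"""Diagnostic-validity statistics for a 2x2 algorithm-vs-chart table.

Estimates sensitivity, specificity, PPV and NPV, each as a binomial
proportion on its own denominator with an exact (Clopper-Pearson) confidence
interval from beta-distribution quantiles.  The exact interval is the right
family here because validation tables routinely hit the boundary (no false
negatives, or a perfect cohort with x = n), where Wald/Wilson intervals
misbehave.

Also provides the survey-style extrapolation of a sampled 2x2 back to the
source cohort, the estimated true-case count implied by a PPV, and the
normal-approximation sample size for estimating a proportion to a target
confidence-interval half-width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

__all__ = [
    "Contingency2x2",
    "MetricEstimate",
    "ValidityResult",
    "SampleSizeSpec",
    "clopper_pearson",
    "diagnostic_metrics",
    "extrapolate_2x2",
    "estimate_true_count",
    "required_n_for_proportion",
]

_EPS = 1e-9  # guards floor/ceil against float representation error


@dataclass(frozen=True)
class Contingency2x2:
    """Algorithm-vs-gold-standard contingency table.

    tp: criterion-positive & disease-positive, fp: criterion-positive &
    disease-negative, tn: criterion-negative & disease-negative, fn:
    criterion-negative & disease-positive.  ``weighted`` marks a table whose
    counts have been extrapolated with sampling weights.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    weighted: bool = False

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion x/n with its exact confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    x: int
    n: int


@dataclass(frozen=True)
class ValidityResult:
    """Sensitivity/specificity/PPV/NPV; a metric with zero denominator is None."""

    sensitivity: Optional[MetricEstimate]
    specificity: Optional[MetricEstimate]
    ppv: Optional[MetricEstimate]
    npv: Optional[MetricEstimate]
    level: float = 0.95


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for x successes in n trials.

    Lower bound is the alpha/2 quantile of Beta(x, n-x+1) (0 when x=0); upper
    bound the 1-alpha/2 quantile of Beta(x+1, n-x) (1 when x=n).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n]; got x={x}, n={n}")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def _metric(x: int, n: int, level: float) -> Optional[MetricEstimate]:
    if n == 0:
        return None
    lo, hi = clopper_pearson(x, n, level)
    return MetricEstimate(estimate=x / n, ci_low=lo, ci_high=hi, x=x, n=n)


def diagnostic_metrics(table: Contingency2x2, level: float = 0.95) -> ValidityResult:
    """All four validity metrics with exact CIs from a 2x2 table.

    A metric whose denominator is zero (e.g. NPV when TN+FN=0) is reported as
    None — undefined, not 0 or 1.
    """
    if table.n == 0:
        raise ValueError("cannot compute metrics on an all-zero 2x2 table")
    return ValidityResult(
        sensitivity=_metric(table.tp, table.tp + table.fn, level),
        specificity=_metric(table.tn, table.tn + table.fp, level),
        ppv=_metric(table.tp, table.tp + table.fp, level),
        npv=_metric(table.tn, table.tn + table.fn, level),
        level=level,
    )


def extrapolate_2x2(
    table: Contingency2x2, pos_weight: float, neg_weight: float
) -> Contingency2x2:
    """Scale a sampled 2x2 to the source cohort with arm-level weights.

    The positive-arm counts (TP, FP) are multiplied by ``pos_weight``
    (population positives / sampled positives) and the negative-arm counts
    (TN, FN) by ``neg_weight``, each floored to an integer patient count.
    """
    for name, w in (("pos_weight", pos_weight), ("neg_weight", neg_weight)):
        if w < 0:
            raise ValueError(f"{name} must be non-negative, got {w}")
    return Contingency2x2(
        tp=math.floor(table.tp * pos_weight + _EPS),
        fp=math.floor(table.fp * pos_weight + _EPS),
        tn=math.floor(table.tn * neg_weight + _EPS),
        fn=math.floor(table.fn * neg_weight + _EPS),
        weighted=True,
    )


def estimate_true_count(n_extracted: int, ppv: float) -> int:
    """Estimated number of true cases among ``n_extracted`` algorithm positives.

    Floor of n_extracted * ppv (a count of whole patients).
    """
    if not 0 <= ppv <= 1:
        raise ValueError(f"ppv must be in [0, 1], got {ppv}")
    if n_extracted < 0:
        raise ValueError(f"n_extracted must be non-negative, got {n_extracted}")
    return math.floor(n_extracted * ppv + _EPS)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Planning inputs for estimating a proportion to a CI half-width.

    halfwidth: target half-width of the confidence interval (e.g. 0.1);
    level: confidence level; planning_p: assumed proportion (0.5 is the
    conservative worst case); prevalence: optional population disease
    proportion, carried for context when planning negative-arm sizes.
    """

    halfwidth: float
    level: float = 0.95
    planning_p: float = 0.5
    prevalence: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.halfwidth < 1:
            raise ValueError(f"halfwidth must be in (0, 1), got {self.halfwidth}")
        if not 0 < self.level < 1:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if not 0 < self.planning_p < 1:
            raise ValueError(
                f"planning_p must be strictly inside (0, 1), got {self.planning_p}"
            )


def required_n_for_proportion(spec: SampleSizeSpec) -> int:
    """Smallest n with z^2 p(1-p)/n <= halfwidth^2 (normal approximation)."""
    z = stats.norm.ppf(1 - (1 - spec.level) / 2)
    n = z * z * spec.planning_p * (1 - spec.planning_p) / spec.halfwidth**2
    return math.ceil(n - _EPS)
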