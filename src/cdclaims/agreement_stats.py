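"""Chance-corrected agreement between two rating passes.

Implements the three coefficients conventionally reported for chart-review
reliability: Cohen's kappa, weighted kappa on ordered categories, and Gwet's
AC1.  Kappa corrects observed agreement by the margin-product chance model,
which collapses ("kappa paradox") when one category dominates; AC1 replaces
the chance model with one based on the propensity of random rating and stays
interpretable under skewed prevalence.

All coefficients operate on a q x q cross-tabulation of the two passes; the
same operations serve inter-rater (reviewer 1 vs reviewer 2) and intra-rater
(same reviewer, two passes) reliability.

Confidence intervals are asymptotic: kappa and weighted kappa use the
Fleiss-Cohen-Everitt large-sample variance; AC1 uses Gwet's variance
estimator.  Reported CI bounds are truncated to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_CATEGORIES",
    "AgreementTable",
    "CoefficientEstimate",
    "AgreementResult",
    "UndefinedCoefficientError",
    "cross_tabulate",
    "cohen_kappa",
    "weighted_kappa",
    "gwet_ac1",
    "agreement_weights",
    "agreement_summary",
]

#: Clinical ordering used for weighted kappa: a confirmed-vs-suspected
#: disagreement is closer than confirmed-vs-negative.
DEFAULT_CATEGORIES = ("confirmed", "suspected", "negative")


class UndefinedCoefficientError(ValueError):
    """Chance agreement equals 1; the coefficient is undefined."""


@dataclass(frozen=True)
class AgreementTable:
    """q x q cross-tabulation: rows = pass 1 categories, columns = pass 2."""

    counts: np.ndarray
    categories: tuple = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        q = len(self.categories)
        if counts.shape != (q, q):
            raise ValueError(
                f"counts must be {q}x{q} for categories {self.categories}, "
                f"got shape {counts.shape}"
            )
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("agreement table must contain at least one pair")

    @property
    def n(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class CoefficientEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    level: float = 0.95


@dataclass(frozen=True)
class AgreementResult:
    """The three coefficients for one pair of rating passes."""

    kappa: CoefficientEstimate
    weighted_kappa: CoefficientEstimate
    ac1: CoefficientEstimate
    weighting: str = "linear"


def cross_tabulate(
    ratings1: Sequence, ratings2: Sequence, categories: Iterable = DEFAULT_CATEGORIES
) -> AgreementTable:
    """Cross-tabulate two equal-length rating vectors over ordered categories."""
    categories = tuple(categories)
    if len(ratings1) != len(ratings2):
        raise ValueError(
            f"rating vectors differ in length: {len(ratings1)} vs {len(ratings2)}"
        )
    if len(ratings1) == 0:
        raise ValueError("cannot cross-tabulate empty rating vectors")
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)))
    for r1, r2 in zip(ratings1, ratings2):
        if r1 not in index or r2 not in index:
            bad = r1 if r1 not in index else r2
            raise ValueError(f"unknown category {bad!r}; expected one of {categories}")
        counts[index[r1], index[r2]] += 1
    return AgreementTable(counts=counts, categories=categories)


def agreement_weights(q: int, scheme: str = "linear") -> np.ndarray:
    """Agreement-weight matrix: 1 on the diagonal, decaying off it.

    linear: w_ij = 1 - |i-j|/(q-1); quadratic: w_ij = 1 - (i-j)^2/(q-1)^2.
    For q = 2 both schemes reduce to the identity (weighted = unweighted kappa).
    """
    if scheme not in {"linear", "quadratic"}:
        raise ValueError(f"scheme must be 'linear' or 'quadratic', got {scheme!r}")
    if q < 2:
        raise ValueError("need at least two categories")
    i, j = np.indices((q, q))
    d = np.abs(i - j) / (q - 1)
    return 1.0 - (d if scheme == "linear" else d**2)


def _ci(estimate: float, se: float, level: float) -> tuple[float, float]:
    z = stats.norm.ppf(1 - (1 - level) / 2)
    return max(-1.0, estimate - z * se), min(1.0, estimate + z * se)


def _weighted_kappa_core(
    table: AgreementTable, w: np.ndarray, level: float
) -> CoefficientEstimate:
    n = table.n
    p = table.counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(row, col)).sum())
    if pe >= 1.0 - 1e-12:
        raise UndefinedCoefficientError(
            "chance agreement is 1 (all mass in a single category); kappa undefined"
        )
    kappa = (po - pe) / (1 - pe)
    # Fleiss–Cohen–Everitt large-sample variance
    wbar_row = w @ col        # \bar w_{i.}
    wbar_col = row @ w        # \bar w_{.j}
    term = w * (1 - pe) - (wbar_row[:, None] + wbar_col[None, :]) * (1 - po)
    var = ((p * term**2).sum() - (po * pe - 2 * pe + po) ** 2) / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    lo, hi = _ci(kappa, se, level)
    return CoefficientEstimate(estimate=kappa, se=se, ci_low=lo, ci_high=hi, level=level)


def cohen_kappa(table: AgreementTable, level: float = 0.95) -> CoefficientEstimate:
    """Unweighted Cohen's kappa: (p_o - p_e)/(1 - p_e), margin-product chance."""
    q = len(table.categories)
    return _weighted_kappa_core(table, np.eye(q), level)


def weighted_kappa(
    table: AgreementTable, scheme: str = "linear", level: float = 0.95
) -> CoefficientEstimate:
    """Weighted kappa on ordered categories (linear or quadratic weights)."""
    w = agreement_weights(len(table.categories), scheme)
    return _weighted_kappa_core(table, w, level)


def gwet_ac1(table: AgreementTable, level: float = 0.95) -> CoefficientEstimate:
    """Gwet's AC1 with Gwet's asymptotic variance.

    Chance agreement p_g = (1/(q-1)) * sum_k pi_k (1 - pi_k), where pi_k is
    the mean of the two margins; AC1 = (p_o - p_g)/(1 - p_g).
    """
    n = table.n
    q = len(table.categories)
    p = table.counts / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pi = (row + col) / 2
    pg = float((pi * (1 - pi)).sum() / (q - 1))
    if pg >= 1.0 - 1e-12:
        raise UndefinedCoefficientError("chance agreement is 1; AC1 undefined")
    ac1 = (po - pg) / (1 - pg)

    if n < 2:
        se = 0.0
    else:
        # Gwet's linearized per-item variance, aggregated over cells (k, l):
        # each item in cell (k, l) has agreement a = [k == l] and item-level
        # chance p_g|i = ((1-pi_k) + (1-pi_l)) / (2(q-1)).
        i, j = np.indices((q, q))
        a = (i == j).astype(float)
        pg_item = ((1 - pi[i]) + (1 - pi[j])) / (2 * (q - 1))
        gamma_item = (a - pg) / (1 - pg)
        gamma_star = gamma_item - 2 * (1 - ac1) * (pg_item - pg) / (1 - pg)
        var = float((p * (gamma_star - ac1) ** 2).sum() * n / (n * (n - 1)))
        se = float(np.sqrt(max(var, 0.0)))
    lo, hi = _ci(ac1, se, level)
    return CoefficientEstimate(estimate=ac1, se=se, ci_low=lo, ci_high=hi, level=level)


def agreement_summary(
    table: AgreementTable, scheme: str = "linear", level: float = 0.95
) -> AgreementResult:
    """All three coefficients for one pair of rating passes."""
    return AgreementResult(
        kappa=cohen_kappa(table, level),
        weighted_kappa=weighted_kappa(table, scheme, level),
        ac1=gwet_ac1(table, level),
        weighting=scheme,
    )
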