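"""Study-design stages of a claims-algorithm validation study.

Implements the design used to validate claims case-finding rules against
chart review: age-stratified random sampling of criterion-positive and
criterion-negative patients (with Horvitz-Thompson weights, population
stratum count / sampled stratum count), consensus adjudication of two
independent reviews with a decisive third reviewer, the percentage breakdown
of final review categories by diagnosis source, and assembly of the 2x2
algorithm-vs-chart contingency tables under both case definitions
(confirmed-only and confirmed-or-suspected).

Arm definition: when validating criterion X, the positive pool is the set of
patients meeting X and the negative pool is its complement among the roster.
In particular, when validating the prescription-augmented criterion B,
patients who meet the diagnosis-only criterion A but not B are placed in the
negative pool.  This choice is not dictated by the study design being
emulated (which only reports the diagnosis-only complement) and is logged
here deliberately.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import agreement_stats, validity_stats
from .agreement_stats import AgreementResult, cross_tabulate
from .claims_model import ObservationWindow
from .extraction import CohortCounts, classify_patients, cohort_counts
from .synthetic_data import (
    REVIEW_CATEGORIES,
    SimConfig,
    generate,
    simulate_review,
)
from .validity_stats import Contingency2x2, ValidityResult, diagnostic_metrics

__all__ = [
    "ARM_POSITIVE",
    "ARM_NEGATIVE",
    "CaseDefinition",
    "SampledCase",
    "InsufficientPoolError",
    "AdjudicationNeededError",
    "age_stratum",
    "stratified_sample",
    "adjudicate",
    "resolve_reviews",
    "summarize_review",
    "build_2x2",
    "CriterionValidation",
    "StudyResult",
    "run_study",
]

log = logging.getLogger(__name__)

ARM_POSITIVE = "criterion_positive"
ARM_NEGATIVE = "criterion_negative"


class CaseDefinition(str, enum.Enum):
    """Which chart categories count as disease-positive."""

    CONFIRMED_ONLY = "confirmed_only"
    CONFIRMED_OR_SUSPECTED = "confirmed_or_suspected"

    @property
    def positive_categories(self) -> frozenset:
        if self is CaseDefinition.CONFIRMED_ONLY:
            return frozenset({"confirmed"})
        return frozenset({"confirmed", "suspected"})


@dataclass(frozen=True)
class SampledCase:
    """One sampled patient with arm, age stratum, and sampling weight."""

    patient_id: str
    arm: str
    stratum: str
    weight: float


class InsufficientPoolError(ValueError):
    """A sampling pool is smaller than the requested sample size."""


class AdjudicationNeededError(ValueError):
    """Two reviewers disagree and no third review is available."""


def age_stratum(birth_year, reference_year: int, band_width_years: int = 10):
    """Age-band label (e.g. "40-49") at the reference year; vectorized."""
    age = np.asarray(reference_year) - np.asarray(birth_year)
    if (age < 0).any():
        raise ValueError("birth year after the reference year (negative age)")
    lo = (age // band_width_years) * band_width_years
    labels = np.char.add(
        np.char.add(lo.astype(str), "-"), (lo + band_width_years - 1).astype(str)
    )
    return labels if labels.ndim else labels.item()


def _allocate(sizes: pd.Series, n: int) -> pd.Series:
    """Proportional allocation with largest-remainder rounding, capped at
    stratum sizes (excess redistributed by remainder order)."""
    total = int(sizes.sum())
    quota = n * sizes / total
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    # deterministic order: largest remainder first, stratum label as tie-break
    order = sorted(sizes.index, key=lambda s: (-remainder[s], s))
    i = 0
    while alloc.sum() < n:
        s = order[i % len(order)]
        if alloc[s] < sizes[s]:
            alloc[s] += 1
        i += 1
    return alloc


def stratified_sample(
    inclusion: pd.DataFrame,
    roster: pd.DataFrame,
    criterion: str = "A",
    n_pos: int = 100,
    n_neg: int = 200,
    band_width_years: int = 10,
    seed: Optional[int] = None,
    reference_year: Optional[int] = None,
    window: Optional[ObservationWindow] = None,
) -> pd.DataFrame:
    """Age-stratified random sample of both arms, without replacement.

    Within each arm, allocation across age bands is proportional to stratum
    sizes (largest-remainder rounding) and every sampled case carries the
    Horvitz-Thompson weight N_stratum / n_stratum.  Deterministic given
    ``seed``.  Raises :class:`InsufficientPoolError` when a pool is smaller
    than the requested sample — never a silent take-all.
    """
    crit_col = f"in_{criterion.lower()}"
    if crit_col not in inclusion.columns:
        raise ValueError(f"unknown criterion {criterion!r}")
    if reference_year is None:
        reference_year = window.start.year if window is not None else 2015
    merged = roster.merge(
        inclusion[["patient_id", crit_col]], on="patient_id", how="left"
    )
    merged[crit_col] = merged[crit_col].fillna(False).astype(bool)
    merged["stratum"] = age_stratum(
        merged["birth_year"].to_numpy(), reference_year, band_width_years
    )

    rng = np.random.default_rng(seed)
    rows = []
    for arm, pool, n_req in (
        (ARM_POSITIVE, merged[merged[crit_col]], n_pos),
        (ARM_NEGATIVE, merged[~merged[crit_col]], n_neg),
    ):
        if len(pool) < n_req:
            raise InsufficientPoolError(
                f"{arm} pool for criterion {criterion} has {len(pool)} patients, "
                f"{n_req} requested"
            )
        sizes = pool.groupby("stratum")["patient_id"].count().sort_index()
        alloc = _allocate(sizes, n_req)
        for stratum in sizes.index:
            k = int(alloc[stratum])
            if k == 0:
                continue
            candidates = np.sort(
                pool.loc[pool["stratum"] == stratum, "patient_id"].to_numpy()
            )
            chosen = rng.choice(candidates, size=k, replace=False)
            weight = float(sizes[stratum]) / k
            rows.extend(
                {"patient_id": pid, "arm": arm, "stratum": stratum, "weight": weight}
                for pid in chosen
            )
    return pd.DataFrame(rows, columns=["patient_id", "arm", "stratum", "weight"])


def adjudicate(r1: str, r2: str, r3: Optional[str] = None) -> str:
    """Consensus rule: agreement stands; otherwise the third review decides."""
    for r in (r1, r2) + ((r3,) if r3 is not None else ()):
        if r not in REVIEW_CATEGORIES:
            raise ValueError(f"unknown review category {r!r}")
    if r1 == r2:
        return r1
    if r3 is None:
        raise AdjudicationNeededError(
            f"reviewers disagree ({r1!r} vs {r2!r}) and no third review is available"
        )
    return r3


def resolve_reviews(
    r1: Sequence[str], r2: Sequence[str], r3: Optional[Sequence[str]] = None
) -> np.ndarray:
    """Vectorized adjudication of aligned rating vectors."""
    r1 = np.asarray(r1, dtype=object)
    r2 = np.asarray(r2, dtype=object)
    agree = r1 == r2
    if bool(agree.all()):
        return r1.copy()
    if r3 is None:
        n_open = int((~agree).sum())
        raise AdjudicationNeededError(
            f"{n_open} case(s) need a third review and none was supplied"
        )
    r3 = np.asarray(r3, dtype=object)
    return np.where(agree, r1, r3)


def summarize_review(
    final_categories: Sequence[str], sources: Optional[Sequence[str]] = None
) -> dict:
    """Percentage breakdown of final review results.

    Confirmed cases are split by diagnosis source (a: confirmed at own
    institution, b: by an outside IBD specialist/gastroenterologist, c/d: by
    a primary-care physician with/without supporting findings); suspected and
    negative are reported as their own buckets.  Percentages sum to 100 up to
    rounding.  A confirmed case without a recorded source is attributed to
    its own institution (bucket a) since the review itself confirmed it.
    """
    cats = list(final_categories)
    if not cats:
        raise ValueError("cannot summarize an empty review")
    if sources is None:
        sources = [None] * len(cats)
    keys = ["a", "b", "c", "d", "suspected", "negative"]
    counts = dict.fromkeys(keys, 0)
    for cat, src in zip(cats, sources):
        if cat == "confirmed":
            key = src if src in ("a", "b", "c", "d") else "a"
        elif cat in ("suspected", "negative"):
            key = cat
        else:
            raise ValueError(f"unknown review category {cat!r}")
        counts[key] += 1
    n = len(cats)
    return {k: 100.0 * v / n for k, v in counts.items()}


def build_2x2(
    sample: pd.DataFrame,
    final_categories: Mapping[str, str],
    case_def: CaseDefinition = CaseDefinition.CONFIRMED_ONLY,
) -> Contingency2x2:
    """Unweighted 2x2 table from a sample and its final review categories.

    Test-positive is the criterion-positive arm; disease-positive is defined
    by ``case_def``.  Every sampled patient must have a final category.
    """
    if len(sample) == 0:
        raise ValueError("cannot build a 2x2 table from an empty sample")
    missing = [p for p in sample["patient_id"] if p not in final_categories]
    if missing:
        raise ValueError(
            f"{len(missing)} sampled case(s) lack a final review category: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    case_def = CaseDefinition(case_def)
    pos_cats = case_def.positive_categories
    tp = fp = tn = fn = 0
    for pid, arm in zip(sample["patient_id"], sample["arm"]):
        diseased = final_categories[pid] in pos_cats
        if arm == ARM_POSITIVE:
            tp += diseased
            fp += not diseased
        else:
            fn += diseased
            tn += not diseased
    return Contingency2x2(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))


# ---------------------------------------------------------------------------
# End-to-end synthetic study


@dataclass(frozen=True)
class CriterionValidation:
    """Validation outputs for one criterion arm pair."""

    criterion: str
    sample: pd.DataFrame
    final_categories: dict
    tables: dict          # CaseDefinition -> Contingency2x2
    metrics: dict         # CaseDefinition -> ValidityResult
    breakdown: dict       # positive-arm review breakdown (percentages)
    agreement: Optional[AgreementResult]

    def ppv(self, case_def: CaseDefinition = CaseDefinition.CONFIRMED_ONLY) -> float:
        return self.metrics[CaseDefinition(case_def)].ppv.estimate


@dataclass(frozen=True)
class StudyResult:
    counts: CohortCounts
    criteria: dict        # criterion letter -> CriterionValidation
    roster: pd.DataFrame = field(repr=False)
    gold: pd.DataFrame = field(repr=False)
    inclusion: pd.DataFrame = field(repr=False)


def run_study(
    config: SimConfig,
    criteria: Sequence[str] = ("A", "B"),
    n_pos: int = 100,
    n_neg: int = 200,
    band_width_years: int = 10,
    dual_review_fraction: float = 0.2,
    seed: Optional[int] = None,
) -> StudyResult:
    """Generate a synthetic hospital database and validate criteria end-to-end.

    Pipeline: generate claims -> classify patients -> age-stratified sampling
    of each criterion's arms -> simulate two independent chart reviews (third
    review drawn from the same confusion model for disagreements) ->
    adjudicate -> 2x2 tables and validity metrics under both case
    definitions.  Inter-rater agreement is computed on a random
    ``dual_review_fraction`` subset of the sampled cases, mirroring designs
    that dual-review only a fraction.

    ``seed`` drives generation, sampling, and review; when None,
    ``config.seed`` is used.
    """
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    gen_seed, sample_seed, review_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    roster, claims, gold = generate(config.with_seed(gen_seed))
    from .claims_model import Codebook  # default codebook matches the generator

    inclusion = classify_patients(
        claims, Codebook.default(), window=config.window, roster=roster
    )
    counts = cohort_counts(inclusion)
    gold_idx = gold.set_index("patient_id")

    results = {}
    rng = np.random.default_rng(review_seed)
    for k, criterion in enumerate(criteria):
        sample = stratified_sample(
            inclusion,
            roster,
            criterion=criterion,
            n_pos=n_pos,
            n_neg=n_neg,
            band_width_years=band_width_years,
            seed=sample_seed + k,
            window=config.window,
        )
        sampled_gold = gold_idx.loc[sample["patient_id"]].reset_index()
        r1, r2, r3 = simulate_review(
            sampled_gold,
            config.reviewer_confusion,
            seed=int(rng.integers(2**31)),
            n_raters=3,
        )
        finals = resolve_reviews(r1, r2, r3)
        final_map = dict(zip(sample["patient_id"], finals))

        tables, metrics = {}, {}
        for case_def in CaseDefinition:
            t = build_2x2(sample, final_map, case_def)
            tables[case_def] = t
            metrics[case_def] = diagnostic_metrics(t)

        pos_mask = (sample["arm"] == ARM_POSITIVE).to_numpy()
        breakdown = summarize_review(
            finals[pos_mask], sampled_gold.loc[pos_mask, "source"].to_numpy()
        )

        n_dual = int(round(dual_review_fraction * len(sample)))
        agreement = None
        if n_dual >= 2:
            dual_idx = rng.choice(len(sample), size=n_dual, replace=False)
            table = cross_tabulate(r1[dual_idx], r2[dual_idx])
            try:
                agreement = agreement_stats.agreement_summary(table)
            except agreement_stats.UndefinedCoefficientError:
                agreement = None  # degenerate single-category subset

        results[criterion] = CriterionValidation(
            criterion=criterion,
            sample=sample,
            final_categories=final_map,
            tables=tables,
            metrics=metrics,
            breakdown=breakdown,
            agreement=agreement,
        )
    return StudyResult(
        counts=counts, criteria=results, roster=roster, gold=gold, inclusion=inclusion
    )
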