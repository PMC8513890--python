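"""Case-identification algorithms over monthly claims (inclusion criteria A/B/C).

A patient-month *meets criterion A* when it carries a confirmed (non-suspected)
diagnosis code matching the target prefixes (Crohn's disease, K50) and no
confirmed diagnosis matching the exclusion prefixes (ulcerative colitis K51,
Behçet's disease M35) in that same month.  Criterion B additionally requires a
CD prescription code in the same month; criterion C accepts a prescription or
a CD surgery code.  Hence, month-wise, B ⊆ C ⊆ A.

Exclusion is month-scoped: a confirmed K51 in March does not veto a clean K50
month in May.  A suspected-flag K51/M35 never vetoes — only confirmed codes
count, in both the target and the exclusion direction.

At the patient level a criterion is met when at least ``min_qualifying_months``
distinct months meet it (default 1; repeat-month thresholds are used by some
claims-validation protocols and are exposed as a knob).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .claims_model import (
    ClaimLine,
    Codebook,
    CodeType,
    ObservationWindow,
    code_matches,
)

__all__ = [
    "CriteriaFlags",
    "InclusionResult",
    "CohortCounts",
    "evaluate_month",
    "month_flags",
    "classify_patients",
    "cohort_counts",
    "CRITERIA",
]

CRITERIA = ("A", "B", "C")


class ContractViolation(ValueError):
    """A claim group mixed patients or months."""


@dataclass(frozen=True)
class CriteriaFlags:
    """One patient-month's verdict under criteria A, B, and C."""

    meets_a: bool
    meets_b: bool
    meets_c: bool

    def __post_init__(self) -> None:
        # nesting is structural: B ⊆ C ⊆ A
        assert not self.meets_b or self.meets_c
        assert not self.meets_c or self.meets_a


@dataclass(frozen=True)
class InclusionResult:
    """Patient-level criterion membership with first qualifying months."""

    patient_id: str
    in_a: bool
    in_b: bool
    in_c: bool
    first_month_a: Optional[pd.Period] = None
    first_month_b: Optional[pd.Period] = None
    first_month_c: Optional[pd.Period] = None


def evaluate_month(lines: Iterable[ClaimLine], codebook: Codebook) -> CriteriaFlags:
    """Evaluate criteria A/B/C on one patient-month's claim lines."""
    lines = list(lines)
    if lines:
        patients = {l.patient_id for l in lines}
        months = {l.month for l in lines}
        if len(patients) > 1 or len(months) > 1:
            raise ContractViolation(
                f"evaluate_month got mixed groups: patients={sorted(patients)}, "
                f"months={sorted(str(m) for m in months)}"
            )
    has_cd = any(
        l.code_type is CodeType.DX
        and not l.suspected
        and code_matches(l.code, codebook.cd_dx_prefixes)
        for l in lines
    )
    has_excl = any(
        l.code_type is CodeType.DX
        and not l.suspected
        and code_matches(l.code, codebook.excl_dx_prefixes)
        for l in lines
    )
    has_rx = any(l.code_type is CodeType.RX and l.code in codebook.cd_rx_codes for l in lines)
    has_pr = any(l.code_type is CodeType.PR and l.code in codebook.cd_pr_codes for l in lines)
    meets_a = has_cd and not has_excl
    meets_b = meets_a and has_rx
    meets_c = meets_a and (has_rx or has_pr)
    return CriteriaFlags(meets_a, meets_b, meets_c)


def month_flags(claims: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    """Vectorized per patient-month criteria flags.

    Returns a frame with columns patient_id, month, meets_a, meets_b, meets_c,
    one row per (patient, month) present in ``claims``.  Agrees line-for-line
    with :func:`evaluate_month` (property-tested).
    """
    if claims.empty:
        empty = pd.DataFrame(
            columns=["patient_id", "month", "meets_a", "meets_b", "meets_c"]
        )
        return empty.astype(
            {"meets_a": bool, "meets_b": bool, "meets_c": bool}
        )
    dx = (claims["code_type"] == CodeType.DX.value) & ~claims["suspected"]
    cd_prefixes = tuple(sorted(codebook.cd_dx_prefixes))
    excl_prefixes = tuple(sorted(codebook.excl_dx_prefixes))
    code = claims["code"]
    flags = pd.DataFrame(
        {
            "patient_id": claims["patient_id"],
            "month": claims["month"],
            "cd": dx & code.str.startswith(cd_prefixes),
            "excl": dx & code.str.startswith(excl_prefixes),
            "rx": (claims["code_type"] == CodeType.RX.value)
            & code.isin(codebook.cd_rx_codes),
            "pr": (claims["code_type"] == CodeType.PR.value)
            & code.isin(codebook.cd_pr_codes),
        }
    )
    g = flags.groupby(["patient_id", "month"], sort=True, observed=True).any()
    meets_a = g["cd"] & ~g["excl"]
    out = pd.DataFrame(
        {
            "meets_a": meets_a,
            "meets_b": meets_a & g["rx"],
            "meets_c": meets_a & (g["rx"] | g["pr"]),
        }
    ).reset_index()
    return out


def classify_patients(
    claims: pd.DataFrame,
    codebook: Codebook,
    window: ObservationWindow | None = None,
    roster: pd.DataFrame | None = None,
    min_qualifying_months: int = 1,
) -> pd.DataFrame:
    """Patient-level criterion membership from a claims table.

    Parameters
    ----------
    claims
        Canonical claims frame (see :mod:`cdclaims.claims_model`).
    window
        If given, claim lines outside the window are ignored.
    roster
        If given, patients present in the roster but absent from the claims
        are included with all-false flags (they form part of the
        criterion-negative pool).
    min_qualifying_months
        Number of distinct qualifying months required for patient-level
        inclusion (default 1).

    Returns a frame with columns patient_id, in_a/b/c (bool) and
    first_month_a/b/c (Period or NaT), one row per patient.
    """
    if min_qualifying_months < 1:
        raise ValueError("min_qualifying_months must be >= 1")
    if window is not None and not claims.empty:
        keep = (claims["month"] >= window.start) & (claims["month"] <= window.end)
        claims = claims[keep]
    flags = month_flags(claims, codebook)

    patients = pd.Index(claims["patient_id"].unique(), name="patient_id")
    if roster is not None:
        patients = patients.union(pd.Index(roster["patient_id"], name="patient_id"))
    out = pd.DataFrame(index=patients.sort_values())
    for crit in ("a", "b", "c"):
        col = f"meets_{crit}"
        qualifying = flags[flags[col]]
        counts = qualifying.groupby("patient_id")["month"].count()
        firsts = qualifying.groupby("patient_id")["month"].min()
        in_crit = counts.reindex(out.index, fill_value=0) >= min_qualifying_months
        out[f"in_{crit}"] = in_crit
        first = firsts.reindex(out.index)
        first[~in_crit] = pd.NaT
        out[f"first_month_{crit}"] = first
    return out.reset_index()


@dataclass(frozen=True)
class CohortCounts:
    """Cohort sizes under each criterion (|B| ≤ |C| ≤ |A| always)."""

    n_total: int
    n_a: int
    n_b: int
    n_c: int


def cohort_counts(results: pd.DataFrame) -> CohortCounts:
    """Count patients meeting each criterion in a classify_patients frame."""
    if results.empty:
        return CohortCounts(0, 0, 0, 0)
    return CohortCounts(
        n_total=int(len(results)),
        n_a=int(results["in_a"].sum()),
        n_b=int(results["in_b"].sum()),
        n_c=int(results["in_c"].sum()),
    )
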