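"""Data model and file formats for monthly health-insurance claims.

Japanese providers bill the insurance payer once per calendar month, so the
month is the atomic time unit throughout this package: a claims table is a
flat list of billing lines, each carrying a patient id, a billing month, a
code system (diagnosis / prescription / procedure), the code itself, and —
for diagnoses only — the "suspected" (rule-out) flag that distinguishes a
confirmed diagnosis from one recorded merely to justify a diagnostic test.

Codes are matched by normalized prefix: ICD-10 dialects differ in dotting
and case, so ``K50.1``, ``k501`` and ``K501`` are the same code, and the
chapter prefix ``K50`` covers every ``K50.x`` subcode.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

__all__ = [
    "ClaimsFormatError",
    "CodeType",
    "ObservationWindow",
    "ClaimLine",
    "Patient",
    "Codebook",
    "normalize_code",
    "code_matches",
    "CLAIMS_COLUMNS",
    "PATIENTS_COLUMNS",
    "read_claims",
    "write_claims",
    "read_patients",
    "write_patients",
    "claims_to_frame",
    "iter_patient_months",
]

log = logging.getLogger(__name__)


class ClaimsFormatError(ValueError):
    """A claims/roster file or a single code violates the expected format."""


class CodeType(str, enum.Enum):
    """Code system of a billing line: diagnosis, prescription, or procedure."""

    DX = "DX"
    RX = "RX"
    PR = "PR"


def normalize_code(raw: str) -> str:
    """Normalize a billing code: strip whitespace, uppercase, drop dots.

    Idempotent; raises :class:`ClaimsFormatError` on empty/blank input.
    """
    if raw is None:
        raise ClaimsFormatError("billing code is missing (None)")
    text = str(raw).strip()
    if not text:
        raise ClaimsFormatError(f"billing code is empty or blank: {raw!r}")
    return text.upper().replace(".", "")


def code_matches(code: str, prefixes: Iterable[str]) -> bool:
    """True iff some prefix is a leading substring of ``code``.

    ``code`` and ``prefixes`` are assumed normalized; a chapter-level prefix
    such as ``K50`` therefore matches ``K500``/``K501``/... but ``K500`` does
    not match the bare ``K50``.
    """
    return any(code.startswith(p) for p in prefixes)


@dataclass(frozen=True)
class ObservationWindow:
    """Inclusive range of billing months defining the study period."""

    start: pd.Period
    end: pd.Period

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Period(self.start, freq="M"))
        object.__setattr__(self, "end", pd.Period(self.end, freq="M"))
        if self.start > self.end:
            raise ValueError(f"window start {self.start} is after end {self.end}")

    @classmethod
    def from_spec(cls, spec: str) -> "ObservationWindow":
        """Parse ``"YYYY-MM:YYYY-MM"`` (as used on the command line)."""
        try:
            start, end = spec.split(":")
        except ValueError as exc:
            raise ClaimsFormatError(
                f"window spec must be 'YYYY-MM:YYYY-MM', got {spec!r}"
            ) from exc
        return cls(pd.Period(start, freq="M"), pd.Period(end, freq="M"))

    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, self.end, freq="M")

    @property
    def n_months(self) -> int:
        return (self.end - self.start).n + 1

    def __contains__(self, month) -> bool:
        m = pd.Period(month, freq="M")
        return self.start <= m <= self.end


@dataclass(frozen=True)
class ClaimLine:
    """One monthly billing line."""

    patient_id: str
    month: pd.Period
    code_type: CodeType
    code: str
    suspected: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "month", pd.Period(self.month, freq="M"))
        object.__setattr__(self, "code_type", CodeType(self.code_type))
        object.__setattr__(self, "code", normalize_code(self.code))
        if self.suspected and self.code_type is not CodeType.DX:
            raise ClaimsFormatError(
                f"suspected flag set on non-diagnosis line "
                f"({self.patient_id}, {self.month}, {self.code_type.value})"
            )


@dataclass(frozen=True)
class Patient:
    """Roster entry: opaque id, birth year, sex (M/F/U)."""

    patient_id: str
    birth_year: int
    sex: str = "U"

    def __post_init__(self) -> None:
        if self.sex not in {"M", "F", "U"}:
            raise ClaimsFormatError(f"sex must be M/F/U, got {self.sex!r}")

    def age_at(self, month) -> int:
        """Age in completed years at the start of ``month`` (year arithmetic)."""
        age = pd.Period(month, freq="M").year - self.birth_year
        if age < 0:
            raise ValueError(
                f"patient {self.patient_id} born {self.birth_year} has "
                f"negative age at {month}"
            )
        return age


def _normalized_frozenset(codes: Iterable[str]) -> frozenset:
    return frozenset(normalize_code(c) for c in codes)


@dataclass(frozen=True)
class Codebook:
    """Code sets defining the case-identification rules.

    ``cd_dx_prefixes`` are the target ICD-10 prefixes (Crohn's disease, K50);
    ``excl_dx_prefixes`` veto a month when present as a confirmed diagnosis
    (ulcerative colitis K51, Behçet's disease M35 — the diseases most often
    carrying a spurious K50); ``cd_rx_codes`` / ``cd_pr_codes`` are the exact
    CD prescription and surgery codes used by the B/C criteria.
    """

    cd_dx_prefixes: frozenset = frozenset({"K50"})
    excl_dx_prefixes: frozenset = frozenset({"K51", "M35"})
    cd_rx_codes: frozenset = frozenset()
    cd_pr_codes: frozenset = frozenset()

    def __post_init__(self) -> None:
        for name in ("cd_dx_prefixes", "excl_dx_prefixes", "cd_rx_codes", "cd_pr_codes"):
            object.__setattr__(self, name, _normalized_frozenset(getattr(self, name)))
        if not self.cd_dx_prefixes:
            raise ClaimsFormatError("cd_dx_prefixes must be non-empty")
        if not self.excl_dx_prefixes:
            raise ClaimsFormatError("excl_dx_prefixes must be non-empty")
        if not self.cd_rx_codes:
            raise ClaimsFormatError("cd_rx_codes must be non-empty")
        # prefix-aware disjointness: "K50" would swallow an exclusion "K50.1"
        overlap = {
            (a, b)
            for a in self.cd_dx_prefixes
            for b in self.excl_dx_prefixes
            if a.startswith(b) or b.startswith(a)
        }
        if overlap:
            raise ClaimsFormatError(
                f"target and exclusion prefixes overlap after normalization: {sorted(overlap)}"
            )

    @classmethod
    def from_mapping(cls, data: Mapping) -> "Codebook":
        return cls(
            cd_dx_prefixes=frozenset(data.get("cd_dx_prefixes", ["K50"])),
            excl_dx_prefixes=frozenset(data.get("excl_dx_prefixes", ["K51", "M35"])),
            cd_rx_codes=frozenset(data.get("cd_rx_codes", [])),
            cd_pr_codes=frozenset(data.get("cd_pr_codes", [])),
        )

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ClaimsFormatError(f"codebook YAML must be a mapping: {path}")
        return cls.from_mapping(data)

    def to_yaml(self, path) -> None:
        data = {
            "cd_dx_prefixes": sorted(self.cd_dx_prefixes),
            "excl_dx_prefixes": sorted(self.excl_dx_prefixes),
            "cd_rx_codes": sorted(self.cd_rx_codes),
            "cd_pr_codes": sorted(self.cd_pr_codes),
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def default(cls) -> "Codebook":
        """Shipped default codebook (placeholder national codes for CD drugs)."""
        ref = resources.files("cdclaims.data").joinpath("default_codebook.yaml")
        with ref.open("r", encoding="utf-8") as fh:
            return cls.from_mapping(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Tabular I/O.  The canonical in-memory container for a claims table is a
# pandas DataFrame with columns CLAIMS_COLUMNS, month as Period[M], suspected
# as bool, codes normalized.

CLAIMS_COLUMNS = ["patient_id", "month", "code_type", "code", "suspected"]
PATIENTS_COLUMNS = ["patient_id", "birth_year", "sex"]

_VALID_CODE_TYPES = {c.value for c in CodeType}


def claims_to_frame(lines: Iterable[ClaimLine]) -> pd.DataFrame:
    """Build a canonical claims DataFrame from ClaimLine records."""
    records = [
        (l.patient_id, l.month, l.code_type.value, l.code, bool(l.suspected))
        for l in lines
    ]
    df = pd.DataFrame(records, columns=CLAIMS_COLUMNS)
    df["month"] = pd.PeriodIndex(df["month"], freq="M")
    return df


def _first_bad(mask: pd.Series) -> int:
    """1-based file line number (header = line 1) of the first True in mask."""
    return int(mask.idxmax()) + 2


def read_claims(path, window: ObservationWindow | None = None) -> pd.DataFrame:
    """Read a claims CSV, validate it, and drop lines outside the window.

    Dropped out-of-window lines are counted and logged.  Malformed rows raise
    :class:`ClaimsFormatError` naming the offending file line.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLAIMS_COLUMNS if c not in df.columns]
    if missing:
        raise ClaimsFormatError(f"{path}: missing columns {missing}")
    df = df[CLAIMS_COLUMNS].copy()

    bad_type = ~df["code_type"].isin(_VALID_CODE_TYPES)
    if bad_type.any():
        i = _first_bad(bad_type)
        raise ClaimsFormatError(
            f"{path}:{i}: unknown code_type {df['code_type'][bad_type].iloc[0]!r}"
        )
    months = pd.to_datetime(df["month"], format="%Y-%m", errors="coerce")
    bad_month = months.isna()
    if bad_month.any():
        i = _first_bad(bad_month)
        raise ClaimsFormatError(
            f"{path}:{i}: month must be YYYY-MM, got {df['month'][bad_month].iloc[0]!r}"
        )
    bad_flag = ~df["suspected"].isin({"0", "1"})
    if bad_flag.any():
        i = _first_bad(bad_flag)
        raise ClaimsFormatError(
            f"{path}:{i}: suspected must be 0 or 1, got {df['suspected'][bad_flag].iloc[0]!r}"
        )
    bad_code = df["code"].str.strip() == ""
    if bad_code.any():
        raise ClaimsFormatError(f"{path}:{_first_bad(bad_code)}: empty code")

    out = pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "month": pd.PeriodIndex(months, freq="M"),
            "code_type": df["code_type"],
            "code": df["code"].str.strip().str.upper().str.replace(".", "", regex=False),
            "suspected": df["suspected"] == "1",
        }
    )
    bad_susp = out["suspected"] & (out["code_type"] != CodeType.DX.value)
    if bad_susp.any():
        raise ClaimsFormatError(
            f"{path}:{_first_bad(bad_susp)}: suspected flag set on non-DX line"
        )
    if window is not None:
        in_window = (out["month"] >= window.start) & (out["month"] <= window.end)
        n_dropped = int((~in_window).sum())
        if n_dropped:
            log.info("read_claims: dropped %d line(s) outside %s..%s",
                     n_dropped, window.start, window.end)
        out = out[in_window].reset_index(drop=True)
    return out


def write_claims(df: pd.DataFrame, path) -> None:
    out = df[CLAIMS_COLUMNS].copy()
    out["month"] = out["month"].astype(str)
    out["suspected"] = out["suspected"].astype(int)
    out.to_csv(path, index=False)


def read_patients(path) -> pd.DataFrame:
    """Read a patient roster CSV (`patient_id,birth_year,sex`)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str})
    missing = [c for c in PATIENTS_COLUMNS if c not in df.columns]
    if missing:
        raise ClaimsFormatError(f"{path}: missing columns {missing}")
    df = df[PATIENTS_COLUMNS].copy()
    df["birth_year"] = df["birth_year"].astype(int)
    if df["patient_id"].duplicated().any():
        dup = df["patient_id"][df["patient_id"].duplicated()].iloc[0]
        raise ClaimsFormatError(f"{path}: duplicate patient_id {dup!r} in roster")
    bad_sex = ~df["sex"].isin({"M", "F", "U"})
    if bad_sex.any():
        raise ClaimsFormatError(
            f"{path}:{_first_bad(bad_sex)}: sex must be M/F/U"
        )
    return df


def write_patients(df: pd.DataFrame, path) -> None:
    df[PATIENTS_COLUMNS].to_csv(path, index=False)


def iter_patient_months(df: pd.DataFrame) -> Iterator[tuple[tuple[str, pd.Period], list[ClaimLine]]]:
    """Yield ((patient_id, month), [ClaimLine...]) groups from a claims frame."""
    for key, group in df.groupby(["patient_id", "month"], sort=True, observed=True):
        lines = [
            ClaimLine(
                patient_id=row.patient_id,
                month=row.month,
                code_type=CodeType(row.code_type),
                code=row.code,
                suspected=bool(row.suspected),
            )
            for row in group.itertuples(index=False)
        ]
        yield (key[0], key[1]), lines
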