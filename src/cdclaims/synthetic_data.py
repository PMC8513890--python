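"""Seeded generator of a hospital-scale claims database with known truth.

The generator emulates the claims feed of a single IBD-specialist hospital:
a roster of patients, each making a handful of billing months over a
multi-year window.  Every patient has a latent true status — Crohn's disease
(CD), one of a small spectrum of CD-mimicking diseases, or neither — and the
claims mechanism follows the diagnostic realities that make claims-based
case-finding imperfect:

* true CD patients receive confirmed K50 diagnosis codes in most billing
  months and a CD prescription code in most of those;
* mimic diseases (infectious enterocolitis, intestinal Behçet's disease,
  drug-induced enterocolitis, intestinal tuberculosis, unspecified stenosis,
  cirrhosis) attract spurious confirmed K50 codes at a lower per-month rate
  and CD prescriptions only rarely;
* Behçet mimics additionally carry their own confirmed M35 code, which can
  land in the same month as the spurious K50 and trigger the exclusion rule;
* non-CD patients occasionally receive *suspected-flagged* K50 codes
  (rule-out billing), which a correct extractor must ignore.

Alongside the claims it emits a gold-standard table (the chart-review truth:
confirmed / suspected / negative, with the source of a confirmed diagnosis)
and can simulate the two-reviewer chart review as independent draws from a
row-stochastic confusion matrix over the gold category.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .claims_model import (
    CLAIMS_COLUMNS,
    Codebook,
    CodeType,
    ObservationWindow,
)

__all__ = [
    "SimConfigError",
    "SimConfig",
    "MIMIC_DX_CODES",
    "DEFAULT_MIMIC_SPECTRUM",
    "REVIEW_CATEGORIES",
    "generate",
    "simulate_review",
    "expected_observed_agreement",
]

REVIEW_CATEGORIES = ("confirmed", "suspected", "negative")
SOURCES = ("a", "b", "c", "d")

#: Relative frequencies of the mimic diseases among false positives,
#: matching the 4/2/1/1/1/1 breakdown seen in single-center chart review.
DEFAULT_MIMIC_SPECTRUM: dict = {
    "infectious_enterocolitis": 0.4,
    "intestinal_behcet": 0.2,
    "drug_induced_enterocolitis": 0.1,
    "intestinal_tuberculosis": 0.1,
    "unspecified_stenosis": 0.1,
    "cirrhosis": 0.1,
}

#: The diagnosis code each mimic disease carries for its *true* condition.
#: Intestinal Behçet's own code (M35.2 → "M352") matches the M35 exclusion
#: prefix, which is what makes the same-month exclusion rule consequential.
MIMIC_DX_CODES: dict = {
    "infectious_enterocolitis": "A09",
    "intestinal_behcet": "M352",
    "drug_induced_enterocolitis": "K521",
    "intestinal_tuberculosis": "A183",
    "unspecified_stenosis": "K566",
    "cirrhosis": "K746",
}

#: Filler diagnoses given to every billing month for background realism.
_FILLER_DX = ("E119", "I109", "J069", "K219", "M545")

_DEFAULT_CONFUSION = (
    (0.98, 0.015, 0.005),
    (0.04, 0.93, 0.03),
    (0.005, 0.015, 0.98),
)


class SimConfigError(ValueError):
    """A SimConfig field is out of its valid range."""


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the synthetic hospital claims database.

    Defaults are calibrated so that, at hospital scale, roughly 85–90% of the
    patients flagged by the diagnosis-code-only criterion truly have CD
    (chart-confirmed PPV ≈ 0.83) and adding the same-month prescription
    requirement raises the PPV substantially — the qualitative structure a
    single-center validation observes.  See docs/methods.md for the
    calibration rationale of every default.
    """

    n_patients: int = 20_000
    prevalence_cd: float = 0.008
    prevalence_mimic: float = 0.0016
    mimic_spectrum: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIMIC_SPECTRUM)
    )
    #: per-visit-month probability of a confirmed K50 code
    p_k50_given_cd: float = 0.90
    p_k50_given_mimic: float = 0.30
    #: probability a Behçet mimic's own M35 code lands in a K50 month
    p_excl_code_given_behcet: float = 0.50
    #: probability a K50-coded month also carries a CD prescription code
    p_rx_given_cd_coded: float = 0.85
    p_rx_given_mimic_coded: float = 0.03
    #: probability of a CD surgery code in a CD patient's K50 month that has
    #: no prescription (keeps the prescription-or-surgery criterion close to
    #: the prescription-only criterion)
    p_pr_given_rx_absent: float = 0.05
    #: mean of the (truncated-at-1) Poisson number of billing months
    mean_visit_months: float = 6.0
    #: per-visit-month probability of a suspected-flagged (rule-out) K50 on
    #: patients without CD.  Unvalidated: no quantitative false-negative /
    #: rule-out structure is reported for real data.
    p_k50_suspected: float = 0.01
    #: chart review splits true CD into confirmed vs suspected
    p_confirmed_given_cd: float = 0.965
    reviewer_confusion: Sequence[Sequence[float]] = _DEFAULT_CONFUSION
    source_distribution: Sequence[float] = (0.74, 0.24, 0.0, 0.02)
    window: ObservationWindow = field(
        default_factory=lambda: ObservationWindow("2015-01", "2019-12")
    )
    seed: int = 0

    def validate(self) -> None:
        errors = []
        if self.n_patients < 1:
            errors.append("n_patients must be >= 1")
        prob_fields = [
            "prevalence_cd",
            "prevalence_mimic",
            "p_k50_given_cd",
            "p_k50_given_mimic",
            "p_excl_code_given_behcet",
            "p_rx_given_cd_coded",
            "p_rx_given_mimic_coded",
            "p_pr_given_rx_absent",
            "p_k50_suspected",
            "p_confirmed_given_cd",
        ]
        for name in prob_fields:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name} must be in [0, 1], got {v}")
        if self.prevalence_cd + self.prevalence_mimic > 1.0:
            errors.append("prevalence_cd + prevalence_mimic must be <= 1")
        masses = np.array(list(self.mimic_spectrum.values()), dtype=float)
        if (masses < 0).any() or not np.isclose(masses.sum(), 1.0):
            errors.append("mimic_spectrum masses must be non-negative and sum to 1")
        unknown = set(self.mimic_spectrum) - set(MIMIC_DX_CODES)
        if unknown:
            errors.append(f"unknown mimic labels: {sorted(unknown)}")
        conf = np.asarray(self.reviewer_confusion, dtype=float)
        if conf.shape != (3, 3) or (conf < 0).any() or not np.allclose(conf.sum(axis=1), 1.0):
            errors.append("reviewer_confusion must be a 3x3 row-stochastic matrix")
        src = np.asarray(self.source_distribution, dtype=float)
        if src.shape != (4,) or (src < 0).any() or not np.isclose(src.sum(), 1.0):
            errors.append("source_distribution must be 4 non-negative probabilities summing to 1")
        if self.mean_visit_months <= 0:
            errors.append("mean_visit_months must be positive")
        if errors:
            raise SimConfigError("; ".join(errors))

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _visit_mask(rng: np.random.Generator, n: int, n_months: int, mean: float) -> np.ndarray:
    """Boolean (n, n_months) mask of billing months; >=1 month per patient."""
    m = np.clip(rng.poisson(mean, size=n), 1, n_months)
    ranks = np.argsort(rng.random((n, n_months)), axis=1).argsort(axis=1)
    return ranks < m[:, None]


def generate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (patient roster, claims table, gold-standard table).

    Deterministic given ``config.seed``.  Every patient appears in the roster
    and the gold table; claims reference only rostered patients.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    months = config.window.months()
    n_months = len(months)
    start_year = config.window.start.year

    ids = np.array([f"P{i:06d}" for i in range(n)])

    # latent truth -----------------------------------------------------------
    u = rng.random(n)
    is_cd = u < config.prevalence_cd
    is_mimic = (~is_cd) & (u < config.prevalence_cd + config.prevalence_mimic)
    mimic_labels = np.array(list(config.mimic_spectrum.keys()))
    mimic_masses = np.array(list(config.mimic_spectrum.values()))
    label_of = np.full(n, "", dtype=object)
    n_mimic = int(is_mimic.sum())
    if n_mimic and mimic_masses.sum() > 0:
        label_of[is_mimic] = rng.choice(mimic_labels, size=n_mimic, p=mimic_masses)
    is_behcet = label_of == "intestinal_behcet"

    # roster -----------------------------------------------------------------
    age = np.clip(np.round(rng.normal(45, 18, size=n)), 0, 95).astype(int)
    birth_year = start_year - age
    p_male = np.where(is_cd, 0.69, 0.5)  # CD skews male in specialist cohorts
    sex = np.where(rng.random(n) < p_male, "M", "F")
    roster = pd.DataFrame({"patient_id": ids, "birth_year": birth_year, "sex": sex})

    # patient-month claim mechanisms ----------------------------------------
    visit = _visit_mask(rng, n, n_months, config.mean_visit_months)
    u_k50 = rng.random((n, n_months))
    p_k50 = np.where(is_cd, config.p_k50_given_cd, 0.0)
    p_k50 = np.where(is_mimic, config.p_k50_given_mimic, p_k50)
    k50 = visit & (u_k50 < p_k50[:, None])

    u_rx = rng.random((n, n_months))
    p_rx = np.where(is_cd, config.p_rx_given_cd_coded, 0.0)
    p_rx = np.where(is_mimic, config.p_rx_given_mimic_coded, p_rx)
    rx = k50 & (u_rx < p_rx[:, None])

    u_pr = rng.random((n, n_months))
    pr = k50 & ~rx & is_cd[:, None] & (u_pr < config.p_pr_given_rx_absent)

    # Behçet mimics: their own confirmed M35 code in every visit month not
    # already chosen to coincide with K50, plus coincidence months by rule.
    u_m35 = rng.random((n, n_months))
    m35_with_k50 = k50 & is_behcet[:, None] & (u_m35 < config.p_excl_code_given_behcet)
    m35_plain = visit & ~k50 & is_behcet[:, None]
    m35 = m35_with_k50 | m35_plain

    # other mimics carry their own disease code in non-K50 visit months
    own_dx = visit & ~k50 & is_mimic[:, None] & ~is_behcet[:, None]

    # rule-out suspected K50 lines on patients without CD
    u_susp = rng.random((n, n_months))
    susp_k50 = visit & ~is_cd[:, None] & ~k50 & (u_susp < config.p_k50_suspected)

    # assemble claim lines ---------------------------------------------------
    rx_pool = np.array(sorted(Codebook.default().cd_rx_codes))
    pr_pool = np.array(sorted(Codebook.default().cd_pr_codes))
    month_values = months.asfreq("M")

    parts = []

    def emit(mask: np.ndarray, code_type: str, codes, suspected: bool = False) -> None:
        pi, mi = np.nonzero(mask)
        if len(pi) == 0:
            return
        if isinstance(codes, str):
            code_col = np.full(len(pi), codes, dtype=object)
        elif callable(codes):
            code_col = codes(pi)
        else:
            code_col = rng.choice(codes, size=len(pi))
        parts.append(
            pd.DataFrame(
                {
                    "patient_id": ids[pi],
                    "month": month_values[mi],
                    "code_type": code_type,
                    "code": code_col,
                    "suspected": suspected,
                }
            )
        )

    emit(k50, CodeType.DX.value, "K500")
    emit(susp_k50, CodeType.DX.value, "K500", suspected=True)
    emit(m35, CodeType.DX.value, "M352")
    emit(own_dx, CodeType.DX.value, lambda pi: np.array(
        [MIMIC_DX_CODES[label_of[p]] for p in pi], dtype=object))
    emit(rx, CodeType.RX.value, rx_pool)
    if len(pr_pool):
        emit(pr, CodeType.PR.value, pr_pool)
    emit(visit, CodeType.DX.value, _FILLER_DX)

    claims = pd.concat(parts, ignore_index=True)
    claims["month"] = pd.PeriodIndex(claims["month"], freq="M")
    claims = claims.sort_values(
        ["patient_id", "month", "code_type", "code", "suspected"]
    ).reset_index(drop=True)[CLAIMS_COLUMNS]

    # gold standard ----------------------------------------------------------
    true_status = np.where(
        is_cd, "CD", np.where(is_mimic, "", "none")
    ).astype(object)
    true_status[is_mimic] = np.array(
        ["mimic:" + l for l in label_of[is_mimic]], dtype=object
    )
    u_cat = rng.random(n)
    chart = np.where(
        is_cd & (u_cat < config.p_confirmed_given_cd),
        "confirmed",
        np.where(is_cd, "suspected", "negative"),
    ).astype(object)
    source = np.full(n, "", dtype=object)
    confirmed = chart == "confirmed"
    n_conf = int(confirmed.sum())
    if n_conf:
        source[confirmed] = rng.choice(
            np.array(SOURCES), size=n_conf, p=np.asarray(config.source_distribution)
        )
    gold = pd.DataFrame(
        {
            "patient_id": ids,
            "true_status": true_status,
            "chart_category": chart,
            "source": source,
        }
    )
    return roster, claims, gold


def simulate_review(
    gold: pd.DataFrame,
    confusion: Sequence[Sequence[float]] | None = None,
    seed: Optional[int] = None,
    n_raters: int = 2,
) -> list[np.ndarray]:
    """Simulate independent chart reviewers over the gold-standard rows.

    Each reviewer's category for a case is drawn from the row of the
    confusion matrix indexed by the case's ``chart_category``; reviewers are
    mutually independent.  Returns ``n_raters`` aligned label arrays (empty
    input yields empty arrays).  Deterministic given ``seed``.
    """
    conf = np.asarray(
        confusion if confusion is not None else _DEFAULT_CONFUSION, dtype=float
    )
    if conf.shape != (3, 3) or (conf < 0).any() or not np.allclose(conf.sum(axis=1), 1.0):
        raise SimConfigError("reviewer confusion must be a 3x3 row-stochastic matrix")
    rng = np.random.default_rng(seed)
    cats = np.array(REVIEW_CATEGORIES)
    idx = pd.Categorical(
        gold["chart_category"], categories=REVIEW_CATEGORIES
    ).codes
    if (idx < 0).any():
        bad = gold["chart_category"].iloc[int(np.argmax(idx < 0))]
        raise ValueError(f"unknown chart_category {bad!r}")
    m = len(gold)
    out = []
    cum = conf.cumsum(axis=1)
    for _ in range(n_raters):
        if m == 0:
            out.append(np.array([], dtype=object))
            continue
        u = rng.random(m)
        choice = (u[:, None] > cum[idx]).sum(axis=1)
        out.append(cats[choice].astype(object))
    return out


def expected_observed_agreement(
    confusion: Sequence[Sequence[float]], category_prevalence: Sequence[float]
) -> float:
    """Closed-form expected raw agreement of two independent reviewers.

    sum_t prev_t * (row_t . row_t): both reviewers draw from row t of the
    confusion matrix, so they agree with probability ||row_t||^2.
    """
    conf = np.asarray(confusion, dtype=float)
    prev = np.asarray(category_prevalence, dtype=float)
    return float(prev @ (conf * conf).sum(axis=1))
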