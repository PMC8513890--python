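"""Sampling, adjudication, review summaries, and 2x2 assembly."""

import numpy as np
import pandas as pd
import pytest

from cdclaims.validation_pipeline import (
    ARM_NEGATIVE,
    ARM_POSITIVE,
    AdjudicationNeededError,
    CaseDefinition,
    InsufficientPoolError,
    adjudicate,
    age_stratum,
    build_2x2,
    resolve_reviews,
    stratified_sample,
    summarize_review,
)


def make_population(n_pos, n_neg, birth_years_pos=None, birth_years_neg=None, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"q{i:05d}" for i in range(n_pos + n_neg)]
    in_a = [True] * n_pos + [False] * n_neg
    by_pos = birth_years_pos if birth_years_pos is not None else rng.integers(
        1940, 2000, n_pos
    )
    by_neg = birth_years_neg if birth_years_neg is not None else rng.integers(
        1940, 2000, n_neg
    )
    roster = pd.DataFrame(
        {
            "patient_id": ids,
            "birth_year": np.concatenate([np.asarray(by_pos), np.asarray(by_neg)]),
            "sex": "U",
        }
    )
    inclusion = pd.DataFrame(
        {"patient_id": ids, "in_a": in_a, "in_b": False, "in_c": False}
    )
    return inclusion, roster


def test_age_stratum_labels():
    assert age_stratum(1980, 2015, 10) == "30-39"
    assert list(age_stratum(np.array([2015, 1970]), 2015, 10)) == ["0-9", "40-49"]
    with pytest.raises(ValueError):
        age_stratum(2020, 2015)


def test_sample_sizes_and_weight_totals():
    """100 of 255 positives sampled; HT weights add back to ~255 per arm."""
    inclusion, roster = make_population(255, 600)
    s = stratified_sample(inclusion, roster, "A", n_pos=100, n_neg=200, seed=42)
    pos = s[s["arm"] == ARM_POSITIVE]
    neg = s[s["arm"] == ARM_NEGATIVE]
    assert len(pos) == 100 and len(neg) == 200
    assert pos["weight"].sum() == pytest.approx(255, abs=1e-9)
    assert neg["weight"].sum() == pytest.approx(600, abs=1e-9)
    assert (s["weight"] >= 1).all()
    assert not s["patient_id"].duplicated().any()


def test_single_stratum_full_take_has_unit_weights():
    inclusion, roster = make_population(
        200, 300, birth_years_pos=[1980] * 200
    )
    s = stratified_sample(inclusion, roster, "A", n_pos=200, n_neg=200, seed=1)
    pos = s[s["arm"] == ARM_POSITIVE]
    assert len(pos) == 200
    assert (pos["weight"] == 1.0).all()
    assert set(pos["patient_id"]) == set(inclusion["patient_id"][:200])


def test_two_strata_proportional_allocation():
    inclusion, roster = make_population(
        200, 300, birth_years_pos=[1980] * 150 + [1960] * 50
    )
    s = stratified_sample(inclusion, roster, "A", n_pos=100, n_neg=100, seed=3)
    pos = s[s["arm"] == ARM_POSITIVE]
    assert (pos["stratum"] == "30-39").sum() == 75
    assert (pos["stratum"] == "50-59").sum() == 25
    assert set(pos.loc[pos["stratum"] == "30-39", "weight"]) == {150 / 75}


def test_insufficient_pool_raises():
    inclusion, roster = make_population(50, 100)
    with pytest.raises(InsufficientPoolError, match="50 patients"):
        stratified_sample(inclusion, roster, "A", n_pos=100, n_neg=50)


def test_sampling_is_seeded_and_without_replacement():
    inclusion, roster = make_population(255, 600)
    s1 = stratified_sample(inclusion, roster, "A", seed=7)
    s2 = stratified_sample(inclusion, roster, "A", seed=7)
    s3 = stratified_sample(inclusion, roster, "A", seed=8)
    pd.testing.assert_frame_equal(s1, s2)
    assert not s1["patient_id"].equals(s3["patient_id"])
    assert not s1["patient_id"].duplicated().any()


def test_inclusion_frequencies_match_allocation():
    """Per-stratum inclusion frequency over 200 seeded draws stays within
    3 standard errors of the allocation fraction."""
    inclusion, roster = make_population(
        120, 60, birth_years_pos=[1985] * 80 + [1955] * 40
    )
    n_draws = 200
    counts = {}
    for seed in range(n_draws):
        s = stratified_sample(inclusion, roster, "A", n_pos=60, n_neg=30, seed=seed)
        for pid in s.loc[s["arm"] == ARM_POSITIVE, "patient_id"]:
            counts[pid] = counts.get(pid, 0) + 1
    # stratum "30-39": 80 patients, 40 sampled -> inclusion prob 0.5
    freq = np.array([counts.get(f"q{i:05d}", 0) / n_draws for i in range(80)])
    se = np.sqrt(0.5 * 0.5 / n_draws)
    assert freq.mean() == pytest.approx(0.5, abs=1e-12)  # 40 of 80 every draw
    assert np.all(np.abs(freq - 0.5) <= 3.5 * se)


def test_adjudication_rules():
    assert adjudicate("confirmed", "confirmed") == "confirmed"
    assert adjudicate("confirmed", "negative", "suspected") == "suspected"
    with pytest.raises(AdjudicationNeededError):
        adjudicate("suspected", "negative")
    with pytest.raises(ValueError):
        adjudicate("confirmed", "definitely")


def test_resolve_reviews_vectorized():
    r1 = ["confirmed", "negative", "suspected"]
    r2 = ["confirmed", "suspected", "suspected"]
    r3 = ["negative", "negative", "confirmed"]
    out = resolve_reviews(r1, r2, r3)
    assert list(out) == ["confirmed", "negative", "suspected"]
    with pytest.raises(AdjudicationNeededError):
        resolve_reviews(r1, r2)
    assert list(resolve_reviews(r1, r1)) == r1


def test_summarize_review_breakdown():
    finals = (
        ["confirmed"] * 62 + ["confirmed"] * 20 + ["confirmed"] * 1
        + ["suspected"] * 7 + ["negative"] * 10
    )
    sources = ["a"] * 62 + ["b"] * 20 + ["d"] * 1 + [None] * 17
    pct = summarize_review(finals, sources)
    assert pct == {
        "a": 62.0, "b": 20.0, "c": 0.0, "d": 1.0, "suspected": 7.0, "negative": 10.0,
    }
    assert sum(pct.values()) == pytest.approx(100.0)
    assert summarize_review(["confirmed"], ["a"]) == {
        "a": 100.0, "b": 0.0, "c": 0.0, "d": 0.0, "suspected": 0.0, "negative": 0.0,
    }
    fifty = summarize_review(["confirmed", "negative"], ["a", None])
    assert fifty["a"] == 50.0 and fifty["negative"] == 50.0
    with pytest.raises(ValueError):
        summarize_review([])


def _sample_frame(n_pos, n_neg):
    rows = [
        {"patient_id": f"s{i:04d}", "arm": ARM_POSITIVE if i < n_pos else ARM_NEGATIVE,
         "stratum": "30-39", "weight": 1.0}
        for i in range(n_pos + n_neg)
    ]
    return pd.DataFrame(rows)


def test_build_2x2_under_both_case_definitions():
    sample = _sample_frame(100, 200)
    finals = {}
    for i in range(100):
        finals[f"s{i:04d}"] = (
            "confirmed" if i < 83 else "suspected" if i < 90 else "negative"
        )
    for i in range(100, 300):
        finals[f"s{i:04d}"] = "negative"
    t1 = build_2x2(sample, finals, CaseDefinition.CONFIRMED_ONLY)
    assert (t1.tp, t1.fp, t1.tn, t1.fn) == (83, 17, 200, 0)
    t2 = build_2x2(sample, finals, CaseDefinition.CONFIRMED_OR_SUSPECTED)
    assert (t2.tp, t2.fp, t2.tn, t2.fn) == (90, 10, 200, 0)
    # arm totals conserved; widening the case definition can only move TP up
    assert t1.tp + t1.fp == t2.tp + t2.fp == 100
    assert t1.tn + t1.fn == t2.tn + t2.fn == 200
    assert t2.tp >= t1.tp


def test_build_2x2_counts_false_negatives():
    sample = _sample_frame(2, 3)
    finals = {"s0000": "confirmed", "s0001": "negative",
              "s0002": "confirmed", "s0003": "negative", "s0004": "suspected"}
    t = build_2x2(sample, finals, CaseDefinition.CONFIRMED_ONLY)
    assert (t.tp, t.fp, t.tn, t.fn) == (1, 1, 2, 1)


def test_build_2x2_errors():
    sample = _sample_frame(1, 1)
    with pytest.raises(ValueError, match="lack a final review"):
        build_2x2(sample, {"s0000": "confirmed"})
    with pytest.raises(ValueError, match="empty sample"):
        build_2x2(sample.iloc[:0], {})
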