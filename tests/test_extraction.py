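"""Inclusion criteria A/B/C: month-level logic, patient-level classification,
nesting invariants, and brute-force oracle equivalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cdclaims.claims_model import ClaimLine, Codebook, CodeType, ObservationWindow
from cdclaims.extraction import (
    ContractViolation,
    classify_patients,
    cohort_counts,
    evaluate_month,
    month_flags,
)

from conftest import make_claims

RX = "RX-MESALAZINE"
PR = "PR-INTESTINAL-RESECTION"


def brute_force_month(lines, codebook) -> tuple[bool, bool, bool]:
    """Independent oracle: literal re-reading of the criteria definitions.

    A: some confirmed target diagnosis line AND no confirmed exclusion line;
    B: A and some CD prescription line; C: A and some CD prescription or
    surgery line.  Evaluated by direct enumeration over the lines.
    """
    confirmed_dx = [l for l in lines if l.code_type is CodeType.DX and not l.suspected]
    target = [
        l for l in confirmed_dx
        if any(l.code.startswith(p) for p in codebook.cd_dx_prefixes)
    ]
    vetoed = [
        l for l in confirmed_dx
        if any(l.code.startswith(p) for p in codebook.excl_dx_prefixes)
    ]
    rx = [l for l in lines if l.code_type is CodeType.RX and l.code in codebook.cd_rx_codes]
    pr = [l for l in lines if l.code_type is CodeType.PR and l.code in codebook.cd_pr_codes]
    a = bool(target) and not vetoed
    return a, a and bool(rx), a and (bool(rx) or bool(pr))


def lines_for(month_rows, pid="p1", month="2016-03"):
    return [
        ClaimLine(pid, month, ct, code, suspected=susp)
        for ct, code, susp in month_rows
    ]


@pytest.mark.parametrize(
    "rows,expected",
    [
        # confirmed K50 alone -> A only
        ([("DX", "K500", False)], (True, False, False)),
        # same-month confirmed ulcerative colitis vetoes the month
        ([("DX", "K500", False), ("DX", "K519", False)], (False, False, False)),
        # K50 plus CD prescription -> A and B (and C)
        ([("DX", "K500", False), ("RX", RX, False)], (True, True, True)),
        # suspected-flag K50 is not a confirmed diagnosis
        ([("DX", "K500", True)], (False, False, False)),
        # K50 plus surgery code -> A and C but not B
        ([("DX", "K500", False), ("PR", PR, False)], (True, False, True)),
    ],
)
def test_evaluate_month_criteria(codebook, rows, expected):
    flags = evaluate_month(lines_for(rows), codebook)
    assert (flags.meets_a, flags.meets_b, flags.meets_c) == expected


def test_suspected_exclusion_code_does_not_veto(codebook):
    flags = evaluate_month(
        lines_for([("DX", "K500", False), ("DX", "K51", True)]), codebook
    )
    assert flags.meets_a


def test_evaluate_month_rejects_mixed_groups(codebook):
    lines = [ClaimLine("p1", "2016-03", "DX", "K500"),
             ClaimLine("p2", "2016-03", "DX", "K500")]
    with pytest.raises(ContractViolation):
        evaluate_month(lines, codebook)


# --- randomized line groups ------------------------------------------------

_LINE = st.tuples(
    st.sampled_from(["DX", "RX", "PR"]),
    st.sampled_from(["K500", "K50", "K519", "K51", "M352", "E119", RX, PR, "RX-OTHER"]),
    st.booleans(),
).map(lambda t: (t[0], t[1], t[2] if t[0] == "DX" else False))

_GROUP = st.lists(_LINE, min_size=0, max_size=8)


@given(_GROUP)
@settings(max_examples=300)
def test_evaluate_month_matches_brute_force_oracle(codebook, rows):
    lines = lines_for(rows)
    flags = evaluate_month(lines, codebook)
    assert (flags.meets_a, flags.meets_b, flags.meets_c) == brute_force_month(
        lines, codebook
    )


@given(_GROUP)
@settings(max_examples=200)
def test_month_nesting_and_permutation_invariance(codebook, rows):
    lines = lines_for(rows)
    flags = evaluate_month(lines, codebook)
    assert (not flags.meets_b) or flags.meets_c
    assert (not flags.meets_c) or flags.meets_a
    reordered = evaluate_month(list(reversed(lines)), codebook)
    assert reordered == flags


# --- patient-level classification ------------------------------------------


def test_same_month_requirement(codebook, window):
    claims = make_claims(
        [
            ("p1", "2016-03", "DX", "K500", False),
            ("p1", "2016-04", "RX", RX, False),
        ]
    )
    res = classify_patients(claims, codebook, window=window).set_index("patient_id")
    assert bool(res.loc["p1", "in_a"]) and not bool(res.loc["p1", "in_b"])


def test_first_qualifying_months(codebook, window):
    claims = make_claims(
        [
            ("p1", "2015-02", "DX", "K500", False),
            ("p1", "2015-07", "DX", "K500", False),
            ("p1", "2015-07", "RX", RX, False),
        ]
    )
    res = classify_patients(claims, codebook, window=window).set_index("patient_id")
    assert res.loc["p1", "first_month_a"] == pd.Period("2015-02", "M")
    assert res.loc["p1", "first_month_b"] == pd.Period("2015-07", "M")


def test_patient_without_target_code_is_negative(codebook, window):
    claims = make_claims([("p1", "2016-03", "DX", "E119", False)])
    res = classify_patients(claims, codebook, window=window).set_index("patient_id")
    assert not res.loc["p1", ["in_a", "in_b", "in_c"]].any()
    assert pd.isna(res.loc["p1", "first_month_a"])


def test_roster_patients_without_claims_included(codebook, window):
    claims = make_claims([("p1", "2016-03", "DX", "K500", False)])
    roster = pd.DataFrame(
        {"patient_id": ["p1", "p2"], "birth_year": [1980, 1970], "sex": ["M", "F"]}
    )
    res = classify_patients(claims, codebook, window=window, roster=roster)
    assert set(res["patient_id"]) == {"p1", "p2"}
    assert not res.set_index("patient_id").loc["p2", "in_a"]


def test_min_qualifying_months_knob(codebook, window):
    claims = make_claims(
        [
            ("p1", "2016-03", "DX", "K500", False),
            ("p2", "2016-03", "DX", "K500", False),
            ("p2", "2016-05", "DX", "K500", False),
        ]
    )
    res = classify_patients(
        claims, codebook, window=window, min_qualifying_months=2
    ).set_index("patient_id")
    assert not res.loc["p1", "in_a"] and res.loc["p2", "in_a"]


def test_cohort_counts_enumeration(codebook, window):
    claims = make_claims(
        [
            ("p1", "2016-03", "DX", "K500", False),
            ("p2", "2016-03", "DX", "K500", False),
            ("p2", "2016-03", "RX", RX, False),
            ("p3", "2016-03", "DX", "K500", True),
        ]
    )
    counts = cohort_counts(classify_patients(claims, codebook, window=window))
    assert (counts.n_a, counts.n_b, counts.n_c) == (2, 1, 1)
    assert counts.n_total == 3
    empty = cohort_counts(classify_patients(make_claims([]), codebook))
    assert (empty.n_total, empty.n_a, empty.n_b, empty.n_c) == (0, 0, 0, 0)


def _random_claims(rng, n_patients=400, n_lines=4000):
    codes = np.array(["K500", "K50", "K519", "K51", "M352", "E119", RX, PR, "RX-OTHER"])
    types = np.where(
        np.char.startswith(codes.astype(str), "RX"), "RX",
        np.where(np.char.startswith(codes.astype(str), "PR"), "PR", "DX"),
    )
    pick = rng.integers(0, len(codes), size=n_lines)
    months = pd.PeriodIndex(
        [f"2016-{m:02d}" for m in rng.integers(1, 13, size=n_lines)], freq="M"
    )
    df = pd.DataFrame(
        {
            "patient_id": np.char.add("p", rng.integers(0, n_patients, n_lines).astype(str)),
            "month": months,
            "code_type": types[pick],
            "code": codes[pick],
            "suspected": (types[pick] == "DX") & (rng.random(n_lines) < 0.3),
        }
    )
    return df


def test_vectorized_flags_agree_with_line_level_evaluator(codebook, rng):
    """month_flags (vectorized path) must agree with evaluate_month everywhere."""
    claims = _random_claims(rng)
    flags = month_flags(claims, codebook).set_index(["patient_id", "month"])
    for (pid, month), group in claims.groupby(["patient_id", "month"]):
        lines = [
            ClaimLine(pid, month, r.code_type, r.code, bool(r.suspected))
            for r in group.itertuples()
        ]
        f = evaluate_month(lines, codebook)
        row = flags.loc[(pid, month)]
        assert (row["meets_a"], row["meets_b"], row["meets_c"]) == (
            f.meets_a, f.meets_b, f.meets_c,
        )


def test_patient_level_nesting_over_randomized_claims(codebook, rng):
    res = classify_patients(_random_claims(rng, n_patients=300), codebook)
    assert (~res["in_b"] | res["in_c"]).all()
    assert (~res["in_c"] | res["in_a"]).all()
    counts = cohort_counts(res)
    assert counts.n_b <= counts.n_c <= counts.n_a
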