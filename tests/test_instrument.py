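"""ASSIST scoring, dichotomisation and grouping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from assistnet.instrument import (
    FREQUENCY_LEVELS,
    RECENCY_LEVELS,
    SUBSTANCES,
    AssistValidationError,
    assign_group,
    classify_polysubstance,
    dichotomize_items,
    load_weight_table,
    score_involvement,
    substance_items,
)


def test_weight_table_structure():
    table = load_weight_table()
    assert set(table) == set(SUBSTANCES)
    assert "q5" not in table["tobacco"]
    assert table["cannabis"]["q5"]["daily_or_almost_daily"] == 8
    assert table["alcohol"]["q6"]["yes_not_past_3_months"] == 3


@pytest.mark.parametrize(
    "sub,levels,expected",
    [
        ("cannabis", {}, 0.0),  # all never
        (
            "cannabis",
            {
                "q2": "daily_or_almost_daily", "q3": "daily_or_almost_daily",
                "q4": "daily_or_almost_daily", "q5": "daily_or_almost_daily",
                "q6": "yes_past_3_months", "q7": "yes_past_3_months",
            },
            39.0,  # 6+6+7+8+6+6
        ),
        (
            "tobacco",
            {
                "q2": "daily_or_almost_daily", "q3": "daily_or_almost_daily",
                "q4": "daily_or_almost_daily",
                "q6": "yes_past_3_months", "q7": "yes_past_3_months",
            },
            31.0,  # Q5 not administered
        ),
        ("alcohol", {"q2": "monthly", "q3": "once_or_twice"}, 6.0),
    ],
)
def test_involvement_score_examples(cohort_builder, sub, levels, expected):
    df = cohort_builder([{f"{sub}_{k}": v for k, v in levels.items()}])
    scores = score_involvement(df)
    assert scores.loc[0, f"{sub}_score"] == expected
    assert scores.loc[0, f"{sub}_logscore"] == pytest.approx(np.log1p(expected))
    assert (scores.loc[0, f"{sub}_logscore"] == 0) == (expected == 0)


def test_missing_item_gives_missing_score(cohort_builder):
    df = cohort_builder([{"cannabis_q4": None}])
    scores = score_involvement(df)
    assert np.isnan(scores.loc[0, "cannabis_score"])
    assert np.isnan(scores.loc[0, "cannabis_logscore"])


def test_unknown_level_raises(cohort_builder):
    df = cohort_builder([{"opioids_q2": "sometimes"}])
    with pytest.raises(AssistValidationError, match="opioids_q2"):
        score_involvement(df)
    with pytest.raises(AssistValidationError, match="opioids_q2"):
        dichotomize_items(df)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.integers(0, 4), st.integers(0, 4), st.integers(0, 4),
            st.integers(0, 4), st.integers(0, 2), st.integers(0, 2),
        ),
        min_size=1, max_size=1,
    ),
    item_idx=st.integers(0, 5),
)
def test_score_monotone_in_item_levels(data, item_idx):
    """Raising any single item's ordinal level never decreases the score."""
    from tests.conftest import make_cohort

    items = substance_items("cannabis")
    (vals,) = data
    caps = (4, 4, 4, 4, 2, 2)

    def level_string(item, v):
        return RECENCY_LEVELS[v] if item in ("q6", "q7") else FREQUENCY_LEVELS[v]

    row = {f"cannabis_{it}": level_string(it, v) for it, v in zip(items, vals)}
    base = score_involvement(make_cohort([row])).loc[0, "cannabis_score"]
    it = items[item_idx]
    v = vals[item_idx]
    if v < caps[item_idx]:
        row2 = dict(row)
        row2[f"cannabis_{it}"] = level_string(it, v + 1)
        bumped = score_involvement(make_cohort([row2])).loc[0, "cannabis_score"]
        assert bumped >= base


def test_dichotomisation_semantics(cohort_builder):
    df = cohort_builder(
        [
            {"cannabis_q2": "once_or_twice"},
            {f"cannabis_{it}": None for it in substance_items("cannabis")},
            {"alcohol_q6": "yes_not_past_3_months"},
            {"alcohol_q6": "yes_past_3_months"},
            {"tobacco_q3": "weekly"},  # harm without use
        ]
    )
    ind = dichotomize_items(df)
    assert ind.loc[0, "cannabis_used"] == True  # noqa: E712
    assert all(pd.isna(ind.loc[1, f"cannabis_{n}"]) for n in
               ("used", "urge", "problems", "failed_expectations", "concerns"))
    # only the past-3-month level counts for Q6/Q7
    assert ind.loc[2, "alcohol_concerns"] == False  # noqa: E712
    assert ind.loc[3, "alcohol_concerns"] == True  # noqa: E712
    assert ind.loc[3, "any_concerns"] == True  # noqa: E712
    # QC: harm with no use is flagged, not erased
    assert ind.loc[4, "tobacco_urge"] == True  # noqa: E712
    assert ind.loc[4, "tobacco_harm_without_use"]


def test_any_aggregates_match_per_substance_flags(cohort_builder):
    df = cohort_builder(
        [{"cannabis_q3": "monthly", "cannabis_q2": "monthly"}, {}]
    )
    ind = dichotomize_items(df)
    per_sub = [c for c in ind.columns if c.endswith("_urge") and c != "any_urge"]
    expected = ind[per_sub].fillna(False).any(axis=1)
    assert (ind["any_urge"].fillna(False) == expected).all()


@pytest.mark.parametrize(
    "rows,include,expected",
    [
        ([{"tobacco_q2": "weekly", "alcohol_q2": "weekly"}], True, "polydrug"),
        ([{"tobacco_q2": "weekly", "alcohol_q2": "weekly"}], False, "none"),
        ([{"cannabis_q2": "monthly"}], False, "one_only"),
        ([{}], True, "none"),
        ([{}], False, "none"),
    ],
)
def test_polysubstance_classification(cohort_builder, rows, include, expected):
    ind = dichotomize_items(cohort_builder(rows))
    assert classify_polysubstance(ind, include)[0] == expected


def test_polysubstance_include_count_dominates_exclude(cohort_builder, rng):
    rows = []
    for _ in range(60):
        row = {}
        for sub in SUBSTANCES:
            if rng.random() < 0.3:
                row[f"{sub}_q2"] = "weekly"
        rows.append(row)
    ind = dichotomize_items(cohort_builder(rows))
    order = {lev: i for i, lev in enumerate(["none", "one_only", "polydrug"])}
    incl = classify_polysubstance(ind, True).astype(object).map(order)
    excl = classify_polysubstance(ind, False).astype(object).map(order)
    assert (incl >= excl).all()


@pytest.mark.parametrize(
    "row,expected",
    [
        ({"ats_q2": "monthly", "cannabis_q2": "weekly", "tobacco_q2": "daily_or_almost_daily"}, "ats"),
        ({"cannabis_q2": "weekly", "tobacco_q2": "weekly"}, "cannabis_no_ats"),
        ({"sedatives_q2": "once_or_twice"}, "alcohol_tobacco_other"),
        ({}, "none"),
    ],
)
def test_group_assignment(cohort_builder, row, expected):
    ind = dichotomize_items(cohort_builder([row]))
    assert assign_group(ind)[0] == expected


def test_group_missing_when_undecidable(cohort_builder):
    # ATS answer missing and nothing overrides it
    ind = dichotomize_items(cohort_builder([{"ats_q2": None, "cannabis_q2": "weekly"}]))
    assert pd.isna(assign_group(ind)[0])
    # but observed ATS use decides regardless of other missingness
    ind = dichotomize_items(cohort_builder([{"ats_q2": "weekly", "cannabis_q2": None}]))
    assert assign_group(ind)[0] == "ats"


def test_groups_partition_cohort(cohort_builder, rng):
    rows = []
    for _ in range(200):
        row = {}
        for sub in SUBSTANCES:
            u = rng.random()
            if u < 0.25:
                row[f"{sub}_q2"] = "weekly"
            elif u < 0.30:
                row[f"{sub}_q2"] = None
        rows.append(row)
    ind = dichotomize_items(cohort_builder(rows))
    groups = assign_group(ind)
    counts = groups.value_counts(dropna=False)
    non_missing = groups.notna().sum()
    assert counts.reindex(["ats", "cannabis_no_ats", "alcohol_tobacco_other", "none"]).fillna(0).sum() == non_missing
    # by construction: cannabis group always uses cannabis, non-ats groups never use ATS
    can = ind.loc[groups == "cannabis_no_ats", "cannabis_used"]
    assert bool(can.all()) and len(can)
    not_ats = ind.loc[groups.notna() & (groups != "ats"), "ats_used"]
    assert not not_ats.fillna(False).any()
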