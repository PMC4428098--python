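"""The five HDL-C definitions: boundary behaviour of the adult filter,
median/tie conventions, the pre/post partition, and cohort-level properties
on randomly generated subjects."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from emr_pheno_sens import (
    LabMeasurement,
    MedicationMention,
    all_hdl,
    build_phenotype_table,
    filter_adult_labs,
    first_last_hdl,
    pre_post_hdl,
)
from emr_pheno_sens._dates import eighteenth_birthday

BIRTH = date(1970, 1, 15)


def lab(when: date, value: float, sid: str = "S1") -> LabMeasurement:
    return LabMeasurement(sid, when, value)


class TestAdultFilter:
    def test_lab_on_18th_birthday_is_retained(self):
        labs = [lab(eighteenth_birthday(BIRTH), 50.0)]
        assert filter_adult_labs(labs, BIRTH) == labs

    def test_lab_one_day_before_18th_birthday_is_dropped(self):
        labs = [lab(eighteenth_birthday(BIRTH) - timedelta(days=1), 50.0)]
        assert filter_adult_labs(labs, BIRTH) == []

    def test_empty_input_is_identity(self):
        assert filter_adult_labs([], BIRTH) == []

    def test_lab_before_birth_raises(self):
        with pytest.raises(ValueError, match="precedes birth"):
            filter_adult_labs([lab(BIRTH - timedelta(days=1), 50.0)], BIRTH)

    def test_leap_day_birth_threshold_rolls_to_march_first(self):
        birth = date(1992, 2, 29)
        assert eighteenth_birthday(birth) == date(2010, 3, 1)
        kept = filter_adult_labs([lab(date(2010, 2, 28), 41.0)], birth)
        assert kept == []


class TestMedians:
    def test_odd_count_median(self):
        labs = [lab(date(2000 + i, 1, 1), v) for i, v in enumerate([40, 50, 72])]
        assert all_hdl(labs) == 50

    def test_even_count_median_averages_middle_pair(self):
        labs = [lab(date(2000, 1, 1), 40.0), lab(date(2001, 1, 1), 60.0)]
        assert all_hdl(labs) == 50

    def test_empty_set_is_none(self):
        assert all_hdl([]) is None


class TestFirstLast:
    def test_two_dated_points(self):
        labs = [lab(date(2001, 1, 1), 44.0), lab(date(2005, 6, 1), 58.0)]
        assert first_last_hdl(labs) == (44.0, 58.0)

    def test_singleton(self):
        assert first_last_hdl([lab(date(2003, 1, 1), 51.0)]) == (51.0, 51.0)

    def test_same_date_tie_uses_min_for_first_max_for_last(self):
        labs = [lab(date(2002, 2, 2), 45.0), lab(date(2002, 2, 2), 47.0)]
        assert first_last_hdl(labs) == (45.0, 47.0)

    def test_empty(self):
        assert first_last_hdl([]) == (None, None)


class TestPrePost:
    def test_partition_around_start_date(self):
        labs = [lab(date(2000, 1, 1), 50.0), lab(date(2002, 1, 1), 44.0)]
        assert pre_post_hdl(labs, date(2001, 1, 1)) == (50.0, 44.0)

    def test_no_medication_evidence_all_labs_are_premedication(self):
        labs = [lab(date(2000, 1, 1), 50.0), lab(date(2002, 1, 1), 44.0)]
        assert pre_post_hdl(labs, None) == (47.0, None)

    def test_same_day_lab_counts_as_post(self):
        start = date(2001, 5, 5)
        pre, post = pre_post_hdl([lab(start, 61.0)], start)
        assert (pre, post) == (None, 61.0)


def _mention(sid, when, term="Lipitor", generic="atorvastatin", cls="statin"):
    return MedicationMention(sid, when, term, generic, cls)


def three_subject_fixture():
    """Hand-computed toy cohort.

    A: birth 1970-01-15, medicated from 2002-01-01 (first of two mentions);
       one minor-age lab dropped; adult labs 44, 50 | 62 (on med start), 58
       -> all 54, first 44, last 58, pre 47, post 60.
    B: birth 1981-03-10, never medicated; two labs on the 18th birthday
       (retained; tie) plus one later -> all 46, first 40, last 55,
       pre = all, post none.
    C: birth 1990-06-01, single lab at age 16 -> everything missing.
    """
    demo = pd.DataFrame(
        {
            "subject_id": ["A", "B", "C"],
            "sex": ["female", "male", "male"],
            "birth_date": ["1970-01-15", "1981-03-10", "1990-06-01"],
        }
    )
    labs = pd.DataFrame(
        [
            ("A", "1987-06-01", 60.0),  # age 17: dropped by the adult filter
            ("A", "2000-01-01", 44.0),
            ("A", "2001-05-01", 50.0),
            ("A", "2002-01-01", 62.0),  # same day as first mention -> post
            ("A", "2003-02-01", 58.0),
            ("B", "1999-03-10", 40.0),  # 18th birthday, tie ...
            ("B", "1999-03-10", 46.0),  # ... with this one
            ("B", "2005-12-31", 55.0),
            ("C", "2007-01-01", 50.0),  # age 16: dropped
        ],
        columns=["subject_id", "date", "value"],
    )
    mentions = [_mention("A", date(2002, 1, 1)), _mention("A", date(2004, 1, 1), "Zocor",
                                                          "simvastatin", "statin")]
    expected = pd.DataFrame(
        {
            "subject_id": ["A", "B", "C"],
            "all_hdl": [54.0, 46.0, None],
            "first_hdl": [44.0, 40.0, None],
            "last_hdl": [58.0, 55.0, None],
            "premed_hdl": [47.0, 46.0, None],
            "postmed_hdl": [60.0, None, None],
            "n_labs_all": [4, 3, 0],
            "n_labs_pre": [2, 3, 0],
            "n_labs_post": [2, 0, 0],
        }
    )
    return demo, labs, mentions, expected


def test_three_subject_hand_computed_table():
    demo, labs, mentions, expected = three_subject_fixture()
    got = build_phenotype_table(demo, labs, mentions)
    value_cols = ["all_hdl", "first_hdl", "last_hdl", "premed_hdl", "postmed_hdl"]
    expected[value_cols] = expected[value_cols].astype(float)
    pd.testing.assert_frame_equal(got, expected, check_dtype=False)


def test_unknown_mention_subject_raises():
    demo, labs, _, _ = three_subject_fixture()
    with pytest.raises(ValueError, match="unknown subject_id"):
        build_phenotype_table(demo, labs, [_mention("ZZ", date(2000, 1, 1))])


def test_single_eligible_lab_collapses_definitions():
    demo = pd.DataFrame(
        {"subject_id": ["X"], "sex": ["male"], "birth_date": ["1950-01-01"]}
    )
    labs = pd.DataFrame([("X", "2000-05-05", 48.0)], columns=["subject_id", "date", "value"])
    row = build_phenotype_table(demo, labs, []).iloc[0]
    assert row["all_hdl"] == row["first_hdl"] == row["last_hdl"] == 48.0


# ---------------------------------------------------------------------------
# randomized cohort properties


def random_subjects(rng, n=500):
    """Random per-subject lab histories plus an optional medication date."""
    subjects = []
    for i in range(n):
        n_labs = int(rng.integers(0, 8))
        labs = [
            lab(
                date(1995, 1, 1) + timedelta(days=int(rng.integers(0, 6000))),
                float(rng.uniform(20, 110)),
                sid=f"P{i}",
            )
            for _ in range(n_labs)
        ]
        med = (
            date(1995, 1, 1) + timedelta(days=int(rng.integers(0, 6000)))
            if rng.random() < 0.5
            else None
        )
        subjects.append((labs, med))
    return subjects


def test_pre_post_partition_is_exact(rng):
    for labs, med in random_subjects(rng):
        if med is None:
            continue
        pre = [l for l in labs if l.lab_date < med]
        post = [l for l in labs if l.lab_date >= med]
        assert len(pre) + len(post) == len(labs)
        assert pre_post_hdl(labs, med) == (all_hdl(pre), all_hdl(post))


def test_outputs_bounded_by_eligible_values(rng):
    for labs, med in random_subjects(rng):
        if not labs:
            continue
        lo, hi = min(l.value for l in labs), max(l.value for l in labs)
        first, last = first_last_hdl(labs)
        for v in (all_hdl(labs), first, last, *pre_post_hdl(labs, med)):
            if v is not None:
                assert lo <= v <= hi


def test_permutation_invariance(rng):
    for labs, med in random_subjects(rng, n=200):
        shuffled = list(labs)
        rng.shuffle(shuffled)
        assert all_hdl(shuffled) == all_hdl(labs)
        assert first_last_hdl(shuffled) == first_last_hdl(labs)
        assert pre_post_hdl(shuffled, med) == pre_post_hdl(labs, med)


def test_premed_equals_all_without_medication(rng):
    for labs, _ in random_subjects(rng, n=200):
        pre, post = pre_post_hdl(labs, None)
        assert pre == all_hdl(labs)
        assert post is None


def test_translation_equivariance(rng):
    c = 7.25
    for labs, med in random_subjects(rng, n=200):
        shifted = [lab(l.lab_date, l.value + c, sid=l.subject_id) for l in labs]
        pairs = [
            (all_hdl(labs), all_hdl(shifted)),
            *zip(first_last_hdl(labs), first_last_hdl(shifted)),
            *zip(pre_post_hdl(labs, med), pre_post_hdl(shifted, med)),
        ]
        for before, after in pairs:
            if before is None:
                assert after is None
            else:
                assert after == pytest.approx(before + c, abs=1e-9)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    values=st.lists(
        st.floats(min_value=10, max_value=200, allow_nan=False), min_size=1, max_size=9
    ),
    shift=st.floats(min_value=-5, max_value=60),
    cut=st.integers(min_value=0, max_value=3000),
)
def test_summaries_bounded_and_translation_equivariant(values, shift, cut):
    labs = [
        lab(date(1995, 1, 1) + timedelta(days=37 * i), v, sid="H")
        for i, v in enumerate(values)
    ]
    med = date(1995, 1, 1) + timedelta(days=cut)
    lo, hi = min(values), max(values)
    outputs = (all_hdl(labs), *first_last_hdl(labs), *pre_post_hdl(labs, med))
    for v in outputs:
        if v is not None:
            assert lo - 1e-9 <= v <= hi + 1e-9
    shifted = [lab(l.lab_date, l.value + shift, sid="H") for l in labs]
    for a, b in zip(
        outputs, (all_hdl(shifted), *first_last_hdl(shifted), *pre_post_hdl(shifted, med))
    ):
        if a is not None:
            assert b == pytest.approx(a + shift, abs=1e-8)


def test_no_mentions_cohort_premed_equals_all():
    demo = pd.DataFrame(
        {
            "subject_id": [f"N{i}" for i in range(20)],
            "sex": ["male"] * 20,
            "birth_date": ["1950-01-01"] * 20,
        }
    )
    rng = np.random.default_rng(42)
    labs = pd.DataFrame(
        [
            (f"N{i}", (date(2000, 1, 1) + timedelta(int(rng.integers(0, 3000)))).isoformat(),
             float(rng.uniform(30, 90)))
            for i in range(20)
            for _ in range(int(rng.integers(1, 5)))
        ],
        columns=["subject_id", "date", "value"],
    )
    table = build_phenotype_table(demo, labs, [])
    assert table["premed_hdl"].equals(table["all_hdl"])
    assert table["postmed_hdl"].isna().all()
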