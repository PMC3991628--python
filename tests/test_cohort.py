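"""Cohort container, CSV round trip, splitting and blinding contracts."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from panelmmc.cohort import (
    Cohort,
    CohortValidationError,
    BlindedCohortError,
    Subject,
    apply_concentration_floor,
    blind,
    draw_date_block,
    months_to_diagnosis,
    MTD_1_12,
    MTD_12_35,
    read_cohort,
    split_halves,
    unblind,
    write_cohort,
)


def test_csv_round_trip_is_identity(default_cohort, tmp_path):
    cohort, _ = default_cohort
    path = tmp_path / "cohort.csv"
    write_cohort(cohort, path)
    back = read_cohort(path)
    assert back.marker_registry == cohort.marker_registry
    assert len(back) == len(cohort)
    for s in cohort.subjects:
        t = back[s.subject_id]
        assert t.status == s.status
        assert t.age_years == s.age_years
        assert t.draw_date == s.draw_date
        assert t.days_to_dx == s.days_to_dx
        assert t.duplicate_of == s.duplicate_of
        for m in cohort.marker_registry:
            assert t.concentrations[m] == pytest.approx(
                s.concentrations[m], rel=0, abs=0
            )


def test_read_cohort_reports_missing_column(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame({"subject_id": ["a"], "status": ["case"]}).to_csv(
        path, index=False
    )
    with pytest.raises(CohortValidationError, match="missing required columns"):
        read_cohort(path)


def test_case_without_days_to_dx_is_reported_with_row(tmp_path):
    frame = pd.DataFrame(
        {
            "subject_id": ["a", "b"],
            "status": ["case", "control"],
            "age": [60, 61],
            "sex": ["male", "male"],
            "race": ["white", "white"],
            "draw_date": ["1999-01-01", "1999-01-02"],
            "days_to_dx": [None, None],
            "survival_cat": ["NA", "NA"],
            "duplicate_of": [None, None],
            "M1": [1.0, 2.0],
        }
    )
    path = tmp_path / "bad.csv"
    frame.to_csv(path, index=False)
    with pytest.raises(CohortValidationError, match="lacks days_to_dx") as exc:
        read_cohort(path)
    assert 1 in exc.value.rows


def test_concentration_floor_replaces_nonpositive_values():
    markers = ["M1"]
    subs = [
        Subject("a", "control", 60, "male", "white", date(1999, 1, 1),
                concentrations={"M1": 0.0}),
        Subject("b", "control", 60, "male", "white", date(1999, 1, 1),
                concentrations={"M1": 4.0}),
        Subject("c", "control", 60, "male", "white", date(1999, 1, 1),
                concentrations={"M1": 8.0}),
    ]
    cohort = Cohort(subs, markers)
    lods = apply_concentration_floor(cohort)
    assert lods["M1"] == 4.0  # smallest positive observed
    assert cohort["a"].concentrations["M1"] == 2.0  # LOD/2
    assert cohort["b"].concentrations["M1"] == 4.0  # untouched


def test_mtd_conversion_and_strata():
    assert months_to_diagnosis(364) == 11
    assert months_to_diagnosis(365) == 11  # floor(365/30.44)
    assert months_to_diagnosis(1064) == 34
    assert MTD_1_12.contains(364) and not MTD_1_12.contains(365)
    assert MTD_12_35.contains(365) and not MTD_12_35.contains(1065)
    # the two strata partition the complete day range
    for d in (0, 100, 364, 365, 800, 1064):
        assert MTD_1_12.contains(d) != MTD_12_35.contains(d)


def test_draw_date_blocks_are_two_month_calendar_blocks():
    assert draw_date_block(date(1999, 1, 5)) == draw_date_block(date(1999, 2, 25))
    assert draw_date_block(date(1999, 2, 28)) != draw_date_block(date(1999, 3, 1))
    assert draw_date_block(date(1999, 12, 1)) != draw_date_block(date(2000, 1, 1))


class TestSplitHalves:
    def test_partition_and_match_group_integrity(self, default_cohort):
        cohort, _ = default_cohort
        a, b = split_halves(cohort, seed=3)
        ids_a = {s.subject_id for s in a.subjects}
        ids_b = {s.subject_id for s in b.subjects}
        assert ids_a.isdisjoint(ids_b)
        assert ids_a | ids_b == {s.subject_id for s in cohort.subjects}
        # no control separated from its case
        for half in (a, b):
            half_ids = {s.subject_id for s in half.subjects}
            for case_id, ctrls in half.match_groups.items():
                assert case_id in half_ids
                assert all(c in half_ids for c in ctrls)

    def test_case_counts_differ_by_at_most_one(self, default_cohort):
        cohort, _ = default_cohort
        a, b = split_halves(cohort, seed=3)
        assert abs(len(a.cases()) - len(b.cases())) <= 1
        assert len(a.cases()) + len(b.cases()) == 135

    def test_configurable_fraction(self, default_cohort):
        # the original study split 56/79; any fraction is allowed
        cohort, _ = default_cohort
        a, b = split_halves(cohort, seed=3, fraction=56 / 135)
        assert len(a.cases()) == 56
        assert len(b.cases()) == 79

    def test_deterministic_given_seed(self, default_cohort):
        cohort, _ = default_cohort
        a1, _ = split_halves(cohort, seed=11)
        a2, _ = split_halves(cohort, seed=11)
        assert [s.subject_id for s in a1.subjects] == [
            s.subject_id for s in a2.subjects
        ]

    def test_empty_cohort_errors(self):
        with pytest.raises(CohortValidationError):
            split_halves(Cohort([], ["M1"]), seed=0)


class TestBlinding:
    def test_blind_unblind_round_trip(self, default_cohort):
        cohort, _ = default_cohort
        blinded, key = blind(cohort)
        restored = unblind(blinded, key)
        for s in cohort.subjects:
            t = restored[s.subject_id]
            assert t.status == s.status
            assert t.days_to_dx == s.days_to_dx
            assert t.survival_cat == s.survival_cat

    def test_blinded_cohort_exposes_no_labels(self, default_cohort):
        cohort, _ = default_cohort
        blinded, _ = blind(cohort)
        assert all(s.status == "blinded" for s in blinded.subjects)
        assert all(s.days_to_dx is None for s in blinded.subjects)
        with pytest.raises(BlindedCohortError):
            blinded.cases()

    def test_key_conserves_case_count(self, default_cohort):
        cohort, _ = default_cohort
        n_cases_rows = sum(1 for s in cohort.subjects if s.status == "case")
        _, key = blind(cohort)
        assert key.n_cases == n_cases_rows

    def test_key_csv_round_trip(self, default_cohort, tmp_path):
        from panelmmc.cohort import KeyTable

        cohort, _ = default_cohort
        _, key = blind(cohort)
        path = tmp_path / "key.csv"
        key.write_csv(path)
        back = KeyTable.read_csv(path)
        assert back.status == key.status
        assert back.days_to_dx == key.days_to_dx
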