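"""CPET record model, maximal-effort filtering and stratified summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vo2ref.records import (
    AGE_BANDS,
    CpetRecord,
    EffortCriteria,
    Sex,
    age_band_label,
    apply_exclusions,
    compute_bmi,
    exclusion_reason,
    is_maximal_effort,
    predicted_hrmax,
    read_cohort_csv,
    sex_difference_percent,
    summarize_cohort,
    write_cohort_csv,
)


def make_record(**kw):
    defaults = dict(
        id="r1", sex=Sex.MALE, age=30.0, height=180.0, weight=75.0,
        vo2max_rel=45.0, hrmax=185.0, rer=1.1,
    )
    defaults.update(kw)
    return CpetRecord(**defaults)


class TestBmiAndTanaka:
    @pytest.mark.parametrize(
        "weight,height,expected",
        [(100.0, 100.0, 100.0), (80.9, 183.0, 24.157)],
    )
    def test_bmi(self, weight, height, expected):
        assert compute_bmi(weight, height) == pytest.approx(expected, abs=1e-3)

    def test_bmi_of_stratum_means_matches_tabulated_value(self):
        # mean-of-ratios vs ratio-of-means: agreement only to ~0.1 expected
        assert compute_bmi(80.9, 183.0) == pytest.approx(24.2, abs=0.1)

    def test_bmi_rejects_nonpositive_and_names_field(self):
        with pytest.raises(ValueError, match="weight"):
            compute_bmi(0, 180)
        with pytest.raises(ValueError, match="height"):
            compute_bmi(70, -1)

    @pytest.mark.parametrize("age,expected", [(0, 208.0), (40, 180.0), (62.52, 164.236)])
    def test_tanaka_prediction(self, age, expected):
        assert predicted_hrmax(age) == pytest.approx(expected)

    def test_oldest_band_mean_hr_exceeds_85pct_threshold(self):
        # 85% of the prediction at age 62.52 sits well below the observed
        # stratum mean of 162 bpm, so typical subjects pass the screen
        assert 0.85 * predicted_hrmax(62.52) == pytest.approx(139.6, abs=0.01)
        assert 162 > 0.85 * predicted_hrmax(62.52)


class TestMaximalEffort:
    def test_rer_just_below_threshold_fails(self):
        assert not is_maximal_effort(make_record(age=30, rer=0.99, hrmax=200))

    def test_thresholds_are_inclusive(self):
        # 0.85 × (208 − 21) = 158.95 exactly
        rec = make_record(age=30, rer=1.0, hrmax=158.95)
        assert is_maximal_effort(rec)

    def test_child_passes_with_high_hr(self):
        rec = make_record(age=8.83, rer=1.12, hrmax=187)
        assert 0.85 * predicted_hrmax(8.83) == pytest.approx(171.55, abs=0.01)
        assert is_maximal_effort(rec)

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_record(age=-1)
        with pytest.raises(ValueError):
            make_record(vo2max_rel=0)


class TestExclusions:
    def test_empty_input(self):
        assert apply_exclusions([]) == ([], [])

    def test_all_passing_cohort_excludes_nothing(self):
        recs = [make_record(id=f"r{i}", age=20 + i) for i in range(5)]
        included, excluded = apply_exclusions(recs)
        assert excluded == [] and included == recs

    def test_reason_priority_order(self):
        # a record failing every rule reports the first (athlete) only
        rec = make_record(athlete=True, smoker=True, weight=120, rer=0.9, hrmax=100)
        assert exclusion_reason(rec) == "athlete"
        rec = make_record(smoker=True, weight=120, rer=0.9, hrmax=100)
        assert exclusion_reason(rec) == "smoker"
        rec = make_record(weight=120, rer=0.9, hrmax=100)
        assert exclusion_reason(rec) == "bmi"
        rec = make_record(rer=0.9, hrmax=100)
        assert exclusion_reason(rec) == "rer"
        rec = make_record(hrmax=100)
        assert exclusion_reason(rec) == "hr"

    def test_bmi_rule_is_strict(self):
        # BMI exactly 30 is kept; above 30 is excluded
        at_limit = make_record(weight=30 * 1.8**2, height=180.0)
        assert exclusion_reason(at_limit) is None
        above = make_record(weight=30 * 1.8**2 + 0.1, height=180.0)
        assert exclusion_reason(above) == "bmi"

    def test_filtering_is_idempotent(self, contaminated_cohort):
        _, cohort = contaminated_cohort
        included, _ = apply_exclusions(cohort)
        again, excluded = apply_exclusions(included)
        assert excluded == [] and again == included

    def test_contamination_rate_recovered(self, contaminated_cohort):
        spec, cohort = contaminated_cohort
        _, excluded = apply_exclusions(cohort)
        p = spec.submaximal_fraction
        frac = len(excluded) / len(cohort)
        assert abs(frac - p) <= 3 * math.sqrt(p * (1 - p) / len(cohort))


class TestAgeBands:
    @given(st.floats(min_value=5.0, max_value=99.0, allow_nan=False))
    @settings(derandomize=True, max_examples=200)
    def test_every_age_lands_in_exactly_one_left_closed_band(self, age):
        label = age_band_label(age)
        hits = [lab for lo, hi, lab in AGE_BANDS if lo <= age < hi]
        assert hits == [label]

    def test_printed_labels_use_floor_semantics(self):
        assert age_band_label(9.9) == "5-9"
        assert age_band_label(10.0) == "10-14"
        assert age_band_label(60.0) == ">=60"


class TestSummaries:
    def test_single_record_omits_sd(self):
        [summary] = summarize_cohort([make_record(age=25.0)])
        assert summary.n == 1
        assert summary.means["age"] == 25.0
        assert "age" not in summary.sds

    def test_two_record_closed_form(self):
        recs = [make_record(id="a", vo2max_rel=40.0), make_record(id="b", vo2max_rel=50.0)]
        [summary] = summarize_cohort(recs)
        assert summary.means["vo2max_rel"] == pytest.approx(45.0)
        assert summary.sds["vo2max_rel"] == pytest.approx(math.sqrt(50.0), abs=1e-9)

    def test_synthetic_stratum_mean_tracks_generating_median(self, contaminated_cohort):
        spec, cohort = contaminated_cohort
        males_20s = [
            r for r in cohort if r.sex is Sex.MALE and age_band_label(r.age) == "20-29"
        ]
        vo2 = np.array([r.vo2max_rel for r in males_20s])
        expected = np.mean(spec.m_curve_male(np.array([r.age for r in males_20s])))
        se = vo2.std(ddof=1) / math.sqrt(len(vo2))
        assert abs(vo2.mean() - expected) < 2 * se


class TestSexDifference:
    def test_overall_difference_rounds_to_18_percent(self):
        assert round(sex_difference_percent(45.39, 37.23), 1) == 18.0

    def test_youngest_band_difference_rounds_to_9_6_percent(self):
        assert round(sex_difference_percent(45.86, 41.48), 1) == 9.6

    def test_equal_means_give_zero(self):
        assert sex_difference_percent(40.0, 40.0) == 0.0

    def test_nonpositive_male_mean_rejected(self):
        with pytest.raises(ValueError):
            sex_difference_percent(0.0, 40.0)


class TestCsvRoundTrip:
    def test_write_read_round_trip(self, tmp_path, clean_cohort):
        _, cohort = clean_cohort
        path = tmp_path / "cohort.csv"
        write_cohort_csv(cohort[:50], path)
        back, errors = read_cohort_csv(path)
        assert errors == []
        assert back == cohort[:50]

    def test_malformed_rows_collected_not_fatal(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "id,sex,age,height,weight,vo2max_rel,hrmax,rer\n"
            "ok,male,30,180,75,45,185,1.1\n"
            "bad,male,-5,180,75,45,185,1.1\n"
            "worse,dog,30,180,75,45,185,1.1\n"
        )
        recs, errors = read_cohort_csv(path)
        assert len(recs) == 1 and recs[0].id == "ok"
        assert [i for i, _ in errors] == [1, 2]

    def test_sex_codes_case_insensitive(self, tmp_path):
        path = tmp_path / "codes.csv"
        path.write_text(
            "id,sex,age,height,weight,vo2max_rel,hrmax,rer\n"
            "a,M,30,180,75,45,185,1.1\n"
            "b,Female,30,170,65,38,180,1.1\n"
        )
        recs, errors = read_cohort_csv(path)
        assert errors == []
        assert [r.sex for r in recs] == [Sex.MALE, Sex.FEMALE]

    def test_missing_required_column_rejected(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("id,sex,age\n1,male,30\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_cohort_csv(path)
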