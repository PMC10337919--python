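import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenovar import (
    Analysis,
    Sex,
    StrainClass,
    StrainGroupRecord,
    Trait,
    behavior_parameter_level_mean_cv,
    compute_cv,
    dataset_level_mean_cv,
    project_level_mean_cv,
    sex_cv_ratio,
    sex_direction_test,
    subset_by_group_size,
    trimmed_range,
)


def rec(cv, project="p1", parameter="param", trait=Trait.CLINICAL_CHEMISTRY,
        test=None, sex=Sex.FEMALE, n=10, strain="S0"):
    return compute_cv(StrainGroupRecord(
        project_id=project, parameter_id=parameter, trait=trait, test_id=test,
        strain=strain, strain_class=StrainClass.INBRED, sex=sex,
        n=n, mean=100.0, sd=100.0 * cv, age_weeks=12.0))


class TestDatasetLevel:
    def test_mean_and_sample_sd(self):
        s = dataset_level_mean_cv([rec(c, strain=f"S{i}")
                                   for i, c in enumerate((0.1, 0.2, 0.3))], "param")
        assert s.mean_cv == pytest.approx(0.2)
        assert s.sd_cv == pytest.approx(0.1)
        assert s.analysis is Analysis.DATASET_LEVEL

    def test_single_record_sd_degenerate(self):
        s = dataset_level_mean_cv([rec(0.4)], "param")
        assert s.mean_cv == pytest.approx(0.4) and s.sd_cv == 0.0 and s.sd_degenerate

    def test_counts(self):
        records = [rec(0.1, project=p, strain=f"S{i}", n=n)
                   for i, (p, n) in enumerate([("p1", 5), ("p1", 15), ("p2", 10)])]
        s = dataset_level_mean_cv(records, "param")
        assert (s.n_projects, s.n_datasets, s.n_mice) == (2, 3, 30)
        assert s.mean_group_size == pytest.approx(10.0)

    def test_no_records_errors(self):
        with pytest.raises(ValueError):
            dataset_level_mean_cv([], "param")


class TestProjectLevel:
    def test_two_step_mean(self):
        records = [rec(0.1, "A", strain="S0"), rec(0.3, "A", strain="S1"),
                   rec(0.2, "B", strain="S2")]
        s = project_level_mean_cv(records, "param")
        assert s.mean_cv == pytest.approx(0.2)
        assert s.sd_cv == pytest.approx(0.0)

    def test_single_project_reduces_to_dataset_level(self):
        records = [rec(c, "A", strain=f"S{i}") for i, c in enumerate((0.1, 0.25, 0.4))]
        assert (project_level_mean_cv(records, "param").mean_cv
                == pytest.approx(dataset_level_mean_cv(records, "param").mean_cv))

    def test_behavior_per_parameter_within_project(self):
        records = [
            rec(0.2, "A", parameter="P1", trait=Trait.BEHAVIOR, test="tst", strain="S0"),
            rec(0.4, "A", parameter="P1", trait=Trait.BEHAVIOR, test="tst", strain="S1"),
            rec(0.6, "A", parameter="P2", trait=Trait.BEHAVIOR, test="tst", strain="S0"),
        ]
        s = project_level_mean_cv(records, "tst")
        assert s.mean_cv == pytest.approx((0.3 + 0.6) / 2)  # = 0.45


class TestBehaviorParameterLevel:
    def test_pooled_per_parameter_then_mean(self):
        records = [
            rec(0.2, "A", parameter="P1", trait=Trait.BEHAVIOR, test="tst", strain="S0"),
            rec(0.4, "B", parameter="P1", trait=Trait.BEHAVIOR, test="tst", strain="S0"),
            rec(0.6, "B", parameter="P2", trait=Trait.BEHAVIOR, test="tst", strain="S0"),
        ]
        s = behavior_parameter_level_mean_cv(records, "tst")
        assert s.mean_cv == pytest.approx(0.45)

    def test_single_parameter_reduces_to_dataset_level(self):
        records = [rec(c, p, parameter="P1", trait=Trait.BEHAVIOR, test="tst", strain=f"S{i}")
                   for i, (c, p) in enumerate([(0.2, "A"), (0.5, "B"), (0.8, "B")])]
        assert (behavior_parameter_level_mean_cv(records, "tst").mean_cv
                == pytest.approx(dataset_level_mean_cv(records, "tst").mean_cv))

    def test_permutation_invariant(self):
        records = [rec(c, p, parameter=q, trait=Trait.BEHAVIOR, test="tst", strain=f"S{i}")
                   for i, (c, p, q) in enumerate(
                       [(0.2, "A", "P1"), (0.4, "B", "P1"), (0.6, "B", "P2")])]
        fwd = behavior_parameter_level_mean_cv(records, "tst")
        rev = behavior_parameter_level_mean_cv(records[::-1], "tst")
        assert fwd.mean_cv == rev.mean_cv and fwd.sd_cv == rev.sd_cv


class TestTrimmedRange:
    def _per_sex(self, m):
        out = []
        for sex in (Sex.FEMALE, Sex.MALE):
            out += [rec(0.01 * (i + 1), sex=sex, strain=f"S{i}") for i in range(m)]
        return out

    def test_tail_counting_40_per_sex(self):
        """2.5% of 40 = 1 record per tail per sex; 76 of 80 remain."""
        tr = trimmed_range(self._per_sex(40), "param", coverage=0.95)
        assert tr.n_remaining == 76
        assert tr.min_cv == pytest.approx(0.02)
        assert tr.max_cv == pytest.approx(0.39)

    def test_coverage_one_is_identity(self):
        records = self._per_sex(10)
        tr = trimmed_range(records, "param", coverage=1.0)
        cvs = [r.cv for r in records]
        assert tr.n_remaining == len(records)
        assert tr.min_cv == pytest.approx(min(cvs))
        assert tr.max_cv == pytest.approx(max(cvs))
        assert tr.mean_cv == pytest.approx(float(np.mean(cvs)))

    def test_small_groups_lose_nothing(self):
        # per-sex m = 10: floor(0.025 * 10) = 0 removed
        tr = trimmed_range(self._per_sex(10), "param", coverage=0.95)
        assert tr.n_remaining == 20

    @settings(max_examples=50, deadline=None)
    @given(cvs=st.lists(st.floats(min_value=0, max_value=2.9), min_size=2, max_size=120))
    def test_containment_90_in_95_in_full(self, cvs):
        records = [rec(c, sex=Sex.FEMALE if i % 2 else Sex.MALE, strain=f"S{i}")
                   for i, c in enumerate(cvs)]
        full = trimmed_range(records, "param", 1.0)
        t95 = trimmed_range(records, "param", 0.95)
        t90 = trimmed_range(records, "param", 0.90)
        assert full.min_cv <= t95.min_cv <= t90.min_cv
        assert t90.max_cv <= t95.max_cv <= full.max_cv
        for tr in (full, t95, t90):
            assert tr.min_cv <= tr.mean_cv <= tr.max_cv or math.isclose(tr.min_cv, tr.max_cv)

    def test_all_trimmed_away_errors(self):
        with pytest.raises(ValueError):
            trimmed_range([], None, 0.95)


class TestSubsets:
    def test_threshold(self):
        records = [rec(0.1, n=n, strain=f"S{n}") for n in (5, 10, 15)]
        assert [r.n for r in subset_by_group_size(records, 10)] == [10, 15]
        assert subset_by_group_size(records, 5) == records


class TestSexStats:
    @pytest.mark.parametrize("f,m,expected", [(0.2, 0.2, 0.5), (0.3, 0.2, 0.6), (0.0, 0.4, 0.0)])
    def test_cv_ratio(self, f, m, expected):
        assert sex_cv_ratio(f, m) == pytest.approx(expected)

    def test_cv_ratio_both_zero_errors(self):
        with pytest.raises(ValueError):
            sex_cv_ratio(0.0, 0.0)

    def test_direction_counts_near_even_not_significant(self):
        """31 vs 27 parameters: chi-squared 8/29, p ~ 0.60 (no sex effect)."""
        pairs = [(0.3, 0.2)] * 31 + [(0.2, 0.3)] * 27
        cmpn = sex_direction_test(pairs)
        assert (cmpn.n_female_higher, cmpn.n_male_higher, cmpn.n_tied) == (31, 27, 0)
        assert cmpn.chi_squared_stat == pytest.approx(8 / 29)
        assert cmpn.p_value == pytest.approx(0.5994, abs=1e-3)
        assert cmpn.p_value > 0.05

    def test_symmetric_counts(self):
        cmpn = sex_direction_test([(0.3, 0.2)] * 10 + [(0.2, 0.3)] * 10)
        assert cmpn.chi_squared_stat == 0.0 and cmpn.p_value == pytest.approx(1.0)

    def test_extreme_counts(self):
        cmpn = sex_direction_test([(0.3, 0.2)] * 20)
        assert cmpn.chi_squared_stat == pytest.approx(20.0)
        assert cmpn.p_value < 1e-3

    def test_ties_excluded_from_test(self):
        cmpn = sex_direction_test([(0.3, 0.2), (0.2, 0.3), (0.25, 0.25)])
        assert cmpn.n_tied == 1
        assert cmpn.chi_squared_stat == 0.0

    def test_all_tied_errors(self):
        with pytest.raises(ValueError):
            sex_direction_test([(0.2, 0.2)])


class TestCrossAnalysisConsistency:
    def test_identical_project_multisets_make_levels_coincide(self):
        cvs = (0.1, 0.2, 0.4)
        records = [rec(c, project=p, strain=f"S{i}")
                   for p in ("A", "B", "C") for i, c in enumerate(cvs)]
        ds = dataset_level_mean_cv(records, "param")
        pj = project_level_mean_cv(records, "param")
        assert ds.mean_cv == pytest.approx(pj.mean_cv)
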