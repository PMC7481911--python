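import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemovisc import (
    CohortSpec,
    GeneratorConfig,
    SubjectRecord,
    check_balance,
    exclude_outliers,
    generate,
    pearson,
    random_split,
    run_validation,
)
from hemovisc.calibration import CalibrationModel, reference_models
from hemovisc.errors import DomainError
from hemovisc.validation import SplitResult, subject_parameter


def _records_from_heights(heights, prefix="s"):
    """Minimal valid records varying only in height (for balance tests)."""
    return [
        SubjectRecord(f"{prefix}{i}", float(h), 74.0, 72.0, 128.0, 74.0, 50.0, 34.0)
        for i, h in enumerate(heights)
    ]


def brute_force_pearson(x, y):
    """Independent oracle: the definitional covariance formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float(np.sum(dx * dy) / np.sqrt(np.sum(dx**2) * np.sum(dy**2)))


class TestPearson:
    def test_perfect_linearity(self):
        x = [1.0, 2.0, 5.0, 9.0]
        y = [2 * v + 1 for v in x]
        res = pearson(x, y)
        assert res.r == pytest.approx(1.0, abs=1e-15)
        assert res.n == 4

    def test_hand_computed_example(self):
        res = pearson([1, 2, 3], [1, 2, 4])
        assert res.r == pytest.approx(0.98198, abs=1e-5)

    def test_constant_input_rejected(self):
        with pytest.raises(DomainError):
            pearson([1, 2, 3], [5, 5, 5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(DomainError):
            pearson([1, 2, 3], [1, 2])

    def test_too_short_rejected(self):
        with pytest.raises(DomainError):
            pearson([1, 2], [1, 2])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = rng.integers(3, 50)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert pearson(x, y).r == pytest.approx(
                brute_force_pearson(x, y), abs=1e-12)

    @given(
        seed=st.integers(0, 10_000),
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    @settings(max_examples=50)
    def test_affine_invariance_and_sign_flip(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r0 = pearson(x, y).r
        assert pearson(a * x + b, y).r == pytest.approx(r0, abs=1e-9)
        assert pearson(-a * x + b, y).r == pytest.approx(-r0, abs=1e-9)


class TestRandomSplit:
    def test_40_38_split(self):
        subjects = _records_from_heights(range(150, 228))  # n = 78
        split = random_split(subjects, ratio=40 / 78, seed=5)
        assert len(split.experimental_ids) == 40
        assert len(split.validation_ids) == 38

    def test_deterministic_for_equal_seeds(self):
        subjects = _records_from_heights(range(150, 228))
        a = random_split(subjects, 0.5, seed=3)
        b = random_split(subjects, 0.5, seed=3)
        assert a == b

    def test_different_seeds_differ(self):
        subjects = _records_from_heights(range(150, 228))
        a = random_split(subjects, 0.5, seed=3)
        b = random_split(subjects, 0.5, seed=4)
        assert a.experimental_ids != b.experimental_ids

    def test_partition_property(self):
        subjects = _records_from_heights(range(150, 229))
        split = random_split(subjects, 0.4, seed=1)
        all_ids = sorted(split.experimental_ids + split.validation_ids)
        assert all_ids == sorted(s.subject_id for s in subjects)
        assert not set(split.experimental_ids) & set(split.validation_ids)

    def test_near_even_at_half(self):
        subjects = _records_from_heights(range(150, 227))  # n = 77
        split = random_split(subjects, 0.5, seed=0)
        assert abs(len(split.experimental_ids) - len(split.validation_ids)) <= 2

    def test_degenerate_inputs_rejected(self):
        subjects = _records_from_heights(range(150, 228))
        with pytest.raises(DomainError):
            random_split(subjects, 0.0, seed=1)
        with pytest.raises(DomainError):
            random_split(subjects, 1.0, seed=1)
        with pytest.raises(DomainError):
            random_split(subjects[:4], 0.5, seed=1)


class TestExcludeOutliers:
    def test_planted_pp_outlier_79_to_78(self):
        cohort, _ = generate(CohortSpec(n=79), GeneratorConfig(seed=21))
        # replace one subject with a 6-SD-high pulse pressure
        pps = [subject_parameter(s, "pp") for s in cohort]
        sd = float(np.std(pps, ddof=1))
        victim = cohort[10]
        planted = SubjectRecord(
            victim.subject_id, victim.height_cm, victim.weight_kg,
            victim.heart_rate_bpm,
            sbp_mmHg=victim.dbp_mmHg + float(np.mean(pps)) + 6 * sd,
            dbp_mmHg=victim.dbp_mmHg,
            lv_edd_mm=victim.lv_edd_mm, lv_esd_mm=victim.lv_esd_mm,
            measured_viscosity_cp=victim.measured_viscosity_cp)
        cohort = cohort[:10] + [planted] + cohort[11:]
        kept, excluded = exclude_outliers(cohort, "pp", 3.0)
        assert len(kept) == 78
        assert len(excluded) == 1
        assert excluded[0][0].subject_id == planted.subject_id
        assert "pp" in excluded[0][1]

    def test_homogeneous_cohort_untouched(self):
        cohort = _records_from_heights(np.linspace(160, 180, 20))
        kept, excluded = exclude_outliers(cohort, "height", 3.0)
        assert len(kept) == 20 and excluded == []

    def test_zero_sd_no_exclusions(self):
        cohort = _records_from_heights([170.0] * 10)
        kept, excluded = exclude_outliers(cohort, "height", 3.0)
        assert len(kept) == 10 and excluded == []

    def test_zero_threshold_rejected(self):
        cohort = _records_from_heights(range(160, 170))
        with pytest.raises(DomainError):
            exclude_outliers(cohort, "height", 0.0)


class TestCheckBalance:
    def _split_of(self, subjects, n_exp):
        ids = [s.subject_id for s in subjects]
        return SplitResult(tuple(ids[:n_exp]), tuple(ids[n_exp:]),
                           seed=0, ratio=n_exp / len(ids))

    def test_identical_groups_balanced(self):
        heights = list(np.linspace(160, 180, 10))
        subjects = (_records_from_heights(heights, "a")
                    + _records_from_heights(heights, "b"))
        split = self._split_of(subjects, 10)
        [report] = check_balance(split, subjects, ["height"])
        assert report.balanced
        assert report.group_variances[0] == pytest.approx(
            report.group_variances[1], rel=1e-12)

    def test_planted_mean_shift_flagged(self):
        rng = np.random.default_rng(8)
        a = rng.normal(170, 5, 50)
        b = rng.normal(170 + 3 * 5, 5, 50)  # 3-SD shift
        subjects = (_records_from_heights(a, "a") + _records_from_heights(b, "b"))
        split = self._split_of(subjects, 50)
        [report] = check_balance(split, subjects, ["height"])
        assert not report.balanced
        assert report.mean_test_p < 0.05

    def test_small_group_rejected(self):
        subjects = _records_from_heights(range(160, 170))
        split = self._split_of(subjects, 2)
        with pytest.raises(DomainError):
            check_balance(split, subjects, ["height"])

    def test_null_rejection_rate_near_alpha(self):
        # Under one population, each test's rejection rate ~ alpha = 0.05.
        rng = np.random.default_rng(123)
        n_rep, n_per_group = 2000, 50
        var_rej = mean_rej = 0
        from scipy import stats
        for _ in range(n_rep):
            a = rng.normal(170, 5, n_per_group)
            b = rng.normal(170, 5, n_per_group)
            if stats.levene(a, b).pvalue < 0.05:
                var_rej += 1
            if stats.ttest_ind(a, b, equal_var=False).pvalue < 0.05:
                mean_rej += 1
        assert abs(var_rej / n_rep - 0.05) <= 0.02
        assert abs(mean_rej / n_rep - 0.05) <= 0.02

    def test_check_balance_agrees_with_direct_tests(self):
        # check_balance must report exactly the scipy Levene/Welch p-values
        rng = np.random.default_rng(77)
        a = rng.normal(170, 5, 30)
        b = rng.normal(171, 6, 30)
        subjects = (_records_from_heights(a, "a") + _records_from_heights(b, "b"))
        split = self._split_of(subjects, 30)
        [report] = check_balance(split, subjects, ["height"])
        from scipy import stats
        assert report.variance_test_p == pytest.approx(
            stats.levene(a, b).pvalue, rel=1e-12)
        assert report.mean_test_p == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue, rel=1e-12)


class TestRunValidation:
    def test_noiseless_cohort_perfect_correlations(self, noiseless_records,
                                                   ref_models, constants):
        report = run_validation(noiseless_records, ref_models, constants)
        assert report.r_r6.r == pytest.approx(1.0, abs=1e-12)
        assert report.r_mu.r == pytest.approx(1.0, abs=1e-12)
        assert report.n_valid == len(noiseless_records)
        assert report.n_excluded == 0

    def test_missing_viscosity_rejected(self, ref_models, constants):
        cohort = _records_from_heights(range(160, 170))
        with pytest.raises(DomainError):
            run_validation(cohort, ref_models, constants)

    def test_invalid_predictions_excluded_and_counted(self, noiseless_records,
                                                      constants):
        # rig the group-0 model so every normal subject predicts negative R^6
        bad0 = CalibrationModel(group=0, intercept=-100.0, coeff_sv_pp=0.1,
                                coeff_second=0.001, second_predictor_name="W")
        m1, _ = reference_models()
        report = run_validation(noiseless_records, (m1, bad0), constants)
        n_normal = sum(1 for r in report.rows if r.group_indicator == 0)
        assert n_normal > 0
        assert report.n_excluded == n_normal
        assert report.n_valid == len(noiseless_records) - n_normal
        for row in report.rows:
            if row.group_indicator == 0:
                assert not row.valid and "R^6" in row.reason

    def test_summary_keys(self, noiseless_records, ref_models, constants):
        summary = run_validation(noiseless_records, ref_models, constants).summary()
        assert set(summary) == {"r_r6", "p_r6", "r_mu", "p_mu",
                                "n_valid", "n_excluded"}
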