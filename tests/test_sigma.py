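"""Sigma-metric computations, matrix correction, and QC-plan stratification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemaqc.sigma import (adjusted_sigma, assess, compute_bias, compute_cv,
                          compute_sigma, grade_sigma,
                          matrix_correction_factor, stratify_plan,
                          summarize_centers)


class TestBias:
    @pytest.mark.parametrize("lab,ref,expected", [
        (100, 100, 0.0), (105, 100, 5.0), (95, 100, 5.0)])
    def test_absolute_percent_deviation(self, lab, ref, expected):
        assert compute_bias(lab, ref) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_bias(100, 0)


class TestCV:
    def test_constant_series_zero(self):
        assert compute_cv([100, 100, 100]) == 0.0

    def test_sample_sd_denominator(self):
        # SD of [98,100,102] with n-1 is exactly 2, mean 100
        assert compute_cv([98, 100, 102]) == pytest.approx(2.0)

    def test_recovers_generator_cv(self, rng):
        draws = rng.normal(250, 0.028 * 250, size=5000)
        assert compute_cv(draws) == pytest.approx(2.8, abs=0.15)

    def test_insufficient_data(self):
        with pytest.raises(ValueError):
            compute_cv([1.0])


class TestSigma:
    @pytest.mark.parametrize("tea,bias,cv,expected", [
        (25, 5, 4, 5.0), (7, 0, 7, 1.0), (10, 10, 2, 0.0)])
    def test_formula(self, tea, bias, cv, expected):
        assert compute_sigma(tea, bias, cv) == pytest.approx(expected)

    @given(tea=st.floats(5, 50), bias=st.floats(0, 4.9),
           cv=st.floats(0.1, 10), delta=st.floats(0.01, 1))
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_bias_and_cv(self, tea, bias, cv, delta):
        base = compute_sigma(tea, bias, cv)
        assert compute_sigma(tea, bias + delta, cv) < base
        if base > 0:
            assert compute_sigma(tea, bias, cv + delta) < base

    def test_negative_sigma_flagged_not_error(self):
        a = assess("PLT", 280, 250, 4.0, 2.8)  # bias 12% > TEa 4%
        assert a.sigma < 0 and a.negative_sigma_flag and a.grade == "low"


class TestGrading:
    @pytest.mark.parametrize("sigma,grade", [
        (6.71, "high"), (4.72, "moderate"), (2.55, "low"),
        (6.0, "high"), (3.0, "moderate"),  # boundary: right-closed at 3, 6
        (5.999, "moderate"), (2.999, "low")])
    def test_bands(self, sigma, grade):
        assert grade_sigma(sigma) == grade


class TestMatrixCorrection:
    @pytest.mark.parametrize("cv_iqc,cv_pat,expected", [
        (2.8, 3.5, 1.25), (0.9, 0.9, 1.00), (1.5, 1.6, 1.07)])
    def test_reported_factor(self, cv_iqc, cv_pat, expected):
        assert matrix_correction_factor(cv_iqc, cv_pat) == expected

    @pytest.mark.parametrize("sigma,f,expected", [
        (3.19, 1.25, 2.55), (6.71, 1.00, 6.71), (4.65, 1.07, 4.35)])
    def test_adjusted_sigma_reporting(self, sigma, f, expected):
        assert adjusted_sigma(sigma, f) == expected

    @given(tea=st.floats(5, 50), bias=st.floats(0, 4),
           cv=st.floats(0.5, 5), f=st.floats(0.5, 2))
    @settings(max_examples=100, deadline=None)
    def test_correction_coherence(self, tea, bias, cv, f):
        # dividing sigma by F equals recomputing sigma with CV inflated by F
        sigma = compute_sigma(tea, bias, cv)
        assert adjusted_sigma(sigma, f, exact=True) == pytest.approx(
            compute_sigma(tea, bias, cv * f), abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            matrix_correction_factor(0, 1)
        with pytest.raises(ValueError):
            adjusted_sigma(3.0, 0)


class TestCenterSummaries:
    # full six-center rows: printed mean reproduced from printed cells
    @pytest.mark.parametrize("cells,mean,grade", [
        ([6.72, 6.91, 6.55, 6.33, 7.05, 6.68], 6.71, "high"),      # Hb
        ([6.41, 6.79, 6.58, 6.15, 6.94, 5.87], 6.46, "high"),      # WBC
        ([5.12, 4.63, 5.47, 4.84, 5.01, 5.18], 5.04, "moderate"),  # RBC
        ([4.85, 5.32, 4.12, 4.47, 5.06, 4.53], 4.72, "moderate"),  # HCT
        ([3.42, 3.19, 2.96, 2.88, 3.22, 3.01], 3.11, "moderate"),  # PLT
        ([5.0], 5.00, "moderate")])
    def test_row_means(self, cells, mean, grade):
        assert summarize_centers(cells) == (mean, grade)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_centers([])


class TestStratification:
    def test_high_tier_single_rule_daily(self):
        a = assess("Hb", 150, 150, 7.0, 7.0 / 6.71)
        plan = stratify_plan(a)
        assert (plan.tier, plan.qc_frequency) == ("high", "once_daily")
        assert plan.rules == ("1-2s",) and not plan.ma_enabled

    def test_moderate_tier_multirule_per_batch(self):
        a = assess("HCT", 42, 42, 6.0, 6.0 / 4.72)
        plan = stratify_plan(a)
        assert (plan.tier, plan.qc_frequency) == ("moderate", "per_batch")
        assert set(plan.rules) == {"1-2s", "R-4s"} and not plan.ma_enabled

    def test_adjusted_sigma_overrides_for_tiering(self):
        # PLT: raw sigma 3.19 (moderate) demoted to low by patient-CV
        a = assess("PLT", 250, 250, 2.8 * 3.19, 2.8, cv_patient_pct=3.5)
        assert a.sigma == pytest.approx(3.19)
        assert a.correction_factor == 1.25 and a.sigma_adjusted == 2.55
        plan = stratify_plan(a)
        assert (plan.tier, plan.qc_frequency) == ("low", "every_4h")
        assert plan.ma_enabled and len(plan.rules) == 2
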