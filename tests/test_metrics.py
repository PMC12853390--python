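"""Alert-verification metrics, kappa, relative change, improvement, AUC."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemaqc.metrics import (AgreementTable, AlertVerificationTable,
                            alert_verification_metrics, cohens_kappa,
                            cross_mechanism_sensitivity,
                            improvement_classification, relative_change,
                            roc_auc)


class TestAlertVerification:
    def test_verification_mode_printed_ratios(self):
        # 57 of 69 alerts confirmed; 96 of 104 non-alerts verified normal
        m = alert_verification_metrics(AlertVerificationTable(69, 57, 104, 96))
        assert m == {"sensitivity": 82.6, "specificity": 92.3,
                     "ppv": 82.6, "npv": 92.3}

    def test_combined_mechanism_ppv(self):
        m = alert_verification_metrics(AlertVerificationTable(38, 34, 104, 96))
        assert m["ppv"] == 89.5

    def test_perfect_verification(self):
        m = alert_verification_metrics(AlertVerificationTable(10, 10, 20, 20))
        assert set(m.values()) == {100.0}

    def test_standard_mode_differs(self):
        t = AlertVerificationTable(69, 57, 104, 96)
        m = alert_verification_metrics(t, mode="standard")
        # TP=57 FN=8 -> sensitivity 87.7; distinct from verification mode
        assert m["sensitivity"] == 87.7 and m["ppv"] == 82.6

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            AlertVerificationTable(10, 12, 5, 5)
        with pytest.raises(ValueError):
            alert_verification_metrics(AlertVerificationTable(0, 0, 5, 5))


class TestCrossMechanismSensitivity:
    @pytest.mark.parametrize("det,tot,expected", [
        (39, 57, 68.4), (57, 69, 82.6), (34, 38, 89.5), (0, 7, 0.0)])
    def test_explicit_denominator(self, det, tot, expected):
        assert cross_mechanism_sensitivity(det, tot) == expected

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            cross_mechanism_sensitivity(1, 0)


def _kappa_brute(a, b, c, d):
    n = a + b + c + d
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n ** 2
    return (p_o - p_e) / (1 - p_e)


class TestKappa:
    def test_perfect_agreement(self):
        k, ci, band = cohens_kappa(AgreementTable(30, 0, 0, 20))
        assert k == pytest.approx(1.0) and band == "strong"

    def test_known_table(self):
        # p_o = 0.85, p_e = 0.50 -> kappa 0.70
        k, ci, band = cohens_kappa(AgreementTable(40, 10, 5, 45))
        assert k == pytest.approx(0.70) and band == "moderate"
        assert ci[0] < 0.70 < ci[1]

    def test_independence_gives_zero(self):
        k, _, band = cohens_kappa(AgreementTable(25, 25, 25, 25))
        assert k == pytest.approx(0.0) and band == "poor"

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError):
            cohens_kappa(AgreementTable(10, 0, 0, 0))

    @given(a=st.integers(1, 40), b=st.integers(1, 40),
           c=st.integers(1, 40), d=st.integers(1, 40))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, a, b, c, d):
        k, _, _ = cohens_kappa(AgreementTable(a, b, c, d))
        assert k == pytest.approx(_kappa_brute(a, b, c, d), abs=1e-10)


class TestRelativeChange:
    @pytest.mark.parametrize("pre,post,expected", [
        (3.9, 1.8, -53.8), (58.6, 76.9, 31.2), (60, 50, -16.7),
        (3.19, 2.55, -20.1)])
    def test_reported_changes(self, pre, post, expected):
        assert relative_change(pre, post) == expected

    @given(x=st.floats(0.1, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_identity_is_zero(self, x):
        assert relative_change(x, x) == 0.0

    def test_zero_pre_rejected(self):
        with pytest.raises(ValueError):
            relative_change(0, 1)


class TestImprovement:
    def test_thresholds(self):
        pre = {"bias_detection_rate": 14.2, "response_time_h": 3.9,
               "intervention_rate": 50.0}
        post = {"bias_detection_rate": 17.7, "response_time_h": 1.8,
                "intervention_rate": 55.0}
        out = improvement_classification(pre, post)
        assert out["bias_detection_rate"] == "improved"   # +3.5 pp >= 2
        assert out["response_time_h"] == "improved"       # -2.1 h >= 1
        assert out["intervention_rate"] == "not_improved"  # +5 pp < 10

    def test_small_time_gain_not_improved(self):
        out = improvement_classification({"response_time_h": 3.9},
                                         {"response_time_h": 3.5})
        assert out["response_time_h"] == "not_improved"


def _auc_brute(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_known_small_case(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.lists(st.tuples(st.floats(0, 1), st.integers(0, 1)),
                    min_size=4, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_pairwise_concordance(self, pairs):
        scores = [round(p[0], 3) for p in pairs]
        labels = [p[1] for p in pairs]
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) == pytest.approx(
            _auc_brute(scores, labels), abs=1e-10)
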