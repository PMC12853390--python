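"""Diagnostic-accuracy and agreement metrics for alert systems.

Two conventions are provided for alert-verification tables and kept
strictly apart:

* **verification mode** (default) — the laboratory-audit convention where
  sensitivity and PPV are both the confirmed fraction of alerts, and
  specificity and NPV are both the verified-normal fraction of non-alerts
  (the denominators are the alert and non-alert streams themselves);
* **standard mode** — the textbook confusion-matrix definitions with
  TP/FP/TN/FN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from statsmodels.stats import inter_rater


def _round1(x: float) -> float:
    return float(round(float(x), 1))


@dataclass(frozen=True)
class AlertVerificationTable:
    """Counts from alert verification: alerts (confirmed or false) and
    non-alert runs later verified normal or not."""

    n_alerts: int
    n_confirmed: int
    n_nonalerts: int
    n_verified_normal: int

    def __post_init__(self):
        if self.n_confirmed > self.n_alerts:
            raise ValueError("n_confirmed <= n_alerts required")
        if self.n_verified_normal > self.n_nonalerts:
            raise ValueError("n_verified_normal <= n_nonalerts required")
        if min(self.n_alerts, self.n_confirmed, self.n_nonalerts,
               self.n_verified_normal) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class AgreementTable:
    """2x2 agreement counts: a,d concordant; b,c discordant."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("total must be > 0")

    def as_array(self):
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def alert_verification_metrics(table: AlertVerificationTable,
                               mode: str = "verification") -> dict:
    """Sensitivity/specificity/PPV/NPV in percent, 1-decimal reporting."""
    if table.n_alerts == 0 or table.n_nonalerts == 0:
        raise ValueError("alert and non-alert denominators must be > 0")
    if mode == "verification":
        pos = 100.0 * table.n_confirmed / table.n_alerts
        neg = 100.0 * table.n_verified_normal / table.n_nonalerts
        return {"sensitivity": _round1(pos), "specificity": _round1(neg),
                "ppv": _round1(pos), "npv": _round1(neg)}
    if mode == "standard":
        tp = table.n_confirmed
        fp = table.n_alerts - table.n_confirmed
        tn = table.n_verified_normal
        fn = table.n_nonalerts - table.n_verified_normal
        if tp + fn == 0 or tn + fp == 0:
            raise ValueError("degenerate confusion matrix")
        return {
            "sensitivity": _round1(100.0 * tp / (tp + fn)),
            "specificity": _round1(100.0 * tn / (tn + fp)),
            "ppv": _round1(100.0 * tp / (tp + fp)) if tp + fp else None,
            "npv": _round1(100.0 * tn / (tn + fn)) if tn + fn else None,
        }
    raise ValueError("mode must be 'verification' or 'standard'")


def cross_mechanism_sensitivity(detected_true: int, total_true: int) -> float:
    """Detected fraction of all true out-of-control events, in percent.

    The denominator is explicit because different trigger mechanisms are
    scored against different reference totals.
    """
    if total_true <= 0:
        raise ValueError("total_true must be > 0")
    if detected_true > total_true:
        raise ValueError("detected_true <= total_true required")
    return _round1(100.0 * detected_true / total_true)


KAPPA_STRONG, KAPPA_MODERATE, KAPPA_POOR = "strong", "moderate", "poor"


def kappa_band(kappa: float) -> str:
    """>0.75 strong; 0.40-0.75 moderate; <0.40 poor."""
    if kappa > 0.75:
        return KAPPA_STRONG
    if kappa >= 0.40:
        return KAPPA_MODERATE
    return KAPPA_POOR


def cohens_kappa(table: AgreementTable, alpha: float = 0.05):
    """Chance-corrected agreement with asymptotic 95% CI and band.

    Returns ``(kappa, (ci_low, ci_high), band)``.
    """
    arr = table.as_array()
    n = arr.sum()
    p_e = float((arr.sum(0) * arr.sum(1)).sum()) / n ** 2
    if p_e >= 1.0 - 1e-12:
        raise ValueError("degenerate marginals: kappa undefined (p_e = 1)")
    res = inter_rater.cohens_kappa(arr, return_results=True)
    kappa = float(res.kappa)
    ci = (float(res.kappa_low), float(res.kappa_upp))
    return kappa, ci, kappa_band(kappa)


def relative_change(pre: float, post: float) -> float:
    """Percent change 100·(post − pre)/pre, 1-decimal reporting."""
    if pre == 0:
        raise ValueError("pre must be nonzero")
    return _round1(100.0 * (post - pre) / pre)


#: Improvement thresholds (rate deltas are percentage points).
IMPROVEMENT_RULES = {
    "bias_detection_rate": ("increase", 2.0),
    "response_time_h": ("decrease", 1.0),
    "intervention_rate": ("increase", 10.0),
}


def improvement_classification(pre_metrics: dict, post_metrics: dict) -> dict:
    """Per-indicator improved / not_improved using the fixed thresholds:
    >= 2 pp bias-detection gain, >= 1 h response-time cut, >= 10 pp
    intervention-rate gain."""
    out = {}
    for key, (direction, threshold) in IMPROVEMENT_RULES.items():
        if key not in pre_metrics or key not in post_metrics:
            continue
        delta = post_metrics[key] - pre_metrics[key]
        if direction == "decrease":
            improved = -delta >= threshold
        else:
            improved = delta >= threshold
        out[key] = "improved" if improved else "not_improved"
    return out


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie handling."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))
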