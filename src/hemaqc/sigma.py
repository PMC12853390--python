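"""Six Sigma performance assessment and sigma-stratified QC planning.

The sigma metric condenses an assay's allowable error budget into one
number::

    sigma = (TEa% - Bias%) / CV%

with Bias the absolute percent deviation of the laboratory mean from the
assigned peer-group reference value and CV the imprecision over a stable
period.  sigma >= 6 is world-class, 3 <= sigma < 6 acceptable, sigma < 3
high-risk.  Because QC materials can understate the variability of real
specimens, a matrix correction factor ``F = CV_patient / CV_IQC`` deflates
sigma to ``sigma / F`` before the tier is chosen.

Reporting rounds to 2 decimals with IEEE round-half-even (Python ``round``);
full precision is retained internally and available via ``exact=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

GRADE_HIGH, GRADE_MODERATE, GRADE_LOW = "high", "moderate", "low"


def _round2(x: float) -> float:
    return float(round(float(x), 2))


@dataclass
class PerformanceAssessment:
    """Bias/CV/sigma summary for one analyte, optionally matrix-corrected."""

    analyte: str
    bias_pct: float
    cv_pct: float
    sigma: float
    grade: str
    cv_patient_pct: Optional[float] = None
    correction_factor: Optional[float] = None
    sigma_adjusted: Optional[float] = None
    negative_sigma_flag: bool = False

    @property
    def sigma_for_tiering(self) -> float:
        """Adjusted sigma overrides raw sigma when patient CV was supplied."""
        return self.sigma_adjusted if self.sigma_adjusted is not None else self.sigma


@dataclass
class QCPlan:
    """Sigma-tiered QC schedule: frequency, rule set, MA monitoring."""

    tier: str
    qc_frequency: str
    rules: tuple
    ma_enabled: bool


#: Default rule sets per tier. The low tier's dual rule is a documented
#: package choice ({1-3s, 2-2s}); the field convention names no fixed pair.
TIER_PLANS = {
    GRADE_HIGH: dict(qc_frequency="once_daily", rules=("1-2s",),
                     ma_enabled=False),
    GRADE_MODERATE: dict(qc_frequency="per_batch", rules=("1-2s", "R-4s"),
                         ma_enabled=False),
    GRADE_LOW: dict(qc_frequency="every_4h", rules=("1-3s", "2-2s"),
                    ma_enabled=True),
}


def compute_bias(lab_mean: float, reference_value: float) -> float:
    """Absolute percent deviation of the laboratory mean from the reference."""
    if reference_value <= 0:
        raise ValueError("reference_value must be > 0")
    return abs((lab_mean - reference_value) / reference_value) * 100.0


def compute_cv(values: Sequence[float]) -> float:
    """Percent coefficient of variation, sample SD (n-1) over mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values to compute a CV")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    return float(arr.std(ddof=1) / mean * 100.0)


def compute_sigma(tea_pct: float, bias_pct: float, cv_pct: float) -> float:
    """(TEa - Bias) / CV; negative when bias exceeds TEa (flagged upstream)."""
    if cv_pct <= 0:
        raise ValueError("cv_pct must be > 0")
    return (tea_pct - bias_pct) / cv_pct


def grade_sigma(sigma: float) -> str:
    if not np.isfinite(sigma):
        raise ValueError("sigma must be finite")
    if sigma >= 6:
        return GRADE_HIGH
    if sigma >= 3:
        return GRADE_MODERATE
    return GRADE_LOW


def matrix_correction_factor(cv_iqc: float, cv_patient: float,
                             exact: bool = False) -> float:
    """F = CV_patient / CV_IQC, reported to 2 decimals unless ``exact``."""
    if cv_iqc <= 0 or cv_patient <= 0:
        raise ValueError("CVs must be > 0")
    f = cv_patient / cv_iqc
    return f if exact else _round2(f)


def adjusted_sigma(sigma: float, factor: float, exact: bool = False) -> float:
    """sigma / F.

    The default reporting mode divides by the factor as given and rounds to
    2 decimals, matching published tables where the corrected sigma derives
    from the 2-decimal F; ``exact=True`` keeps full precision.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    s = sigma / factor
    return s if exact else _round2(s)


def summarize_centers(sigmas: Sequence[float]):
    """Mean sigma across centers (2 decimals) and the grade of that mean."""
    arr = np.asarray(sigmas, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one sigma value")
    mean = _round2(arr.mean())
    return mean, grade_sigma(mean)


def assess(analyte: str, lab_mean: float, reference_value: float,
           tea_pct: float, cv_pct: float,
           cv_patient_pct: Optional[float] = None) -> PerformanceAssessment:
    """Full assessment: bias, sigma, grade and optional matrix correction."""
    bias = compute_bias(lab_mean, reference_value)
    sigma = compute_sigma(tea_pct, bias, cv_pct)
    out = PerformanceAssessment(
        analyte=analyte, bias_pct=bias, cv_pct=cv_pct, sigma=sigma,
        grade=grade_sigma(sigma), negative_sigma_flag=sigma < 0)
    if cv_patient_pct is not None:
        out.cv_patient_pct = cv_patient_pct
        out.correction_factor = matrix_correction_factor(cv_pct, cv_patient_pct)
        out.sigma_adjusted = adjusted_sigma(_round2(sigma),
                                            out.correction_factor)
    return out


def stratify_plan(assessment: PerformanceAssessment) -> QCPlan:
    """Map an assessment to its QC plan; adjusted sigma wins when present."""
    tier = grade_sigma(assessment.sigma_for_tiering)
    return QCPlan(tier=tier, **TIER_PLANS[tier])
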