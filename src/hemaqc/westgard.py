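r"""Westgard multirule engine on z-scored control points.

Rules operate on signed deviations from the target in SD units (z).
Semantics (classic multirule chart):

* ``1-2s``  — one point with \|z\| > 2 (warning inside a cascade; rejection
  when it is the only configured rule and hence the sole failure criterion)
* ``1-3s``  — one point with \|z\| > 3
* ``2-2s``  — two consecutive points beyond 2 SD on the same side
* ``R-4s``  — within one run, two points whose z-range exceeds 4 SD
* ``4-1s``  — four consecutive points beyond 1 SD on the same side
* ``10x``   — ten consecutive points on the same side of the target

R-4s is evaluated within-run across QC levels: a violation is reported at
index ``i`` when some earlier point of the same run differs from it by more
than 4 SD (cross-run application deliberately disabled).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence

import math

from .core import WESTGARD_RULE_NAMES

SEV_WARNING, SEV_REJECTION = "warning", "rejection"


@dataclass(frozen=True)
class ControlPoint:
    z: float
    run_id: str = "run0"
    level: str = "L1"
    timestamp: Optional[datetime] = None

    def __post_init__(self):
        if not math.isfinite(self.z):
            raise ValueError("z must be finite")


@dataclass(frozen=True)
class RuleViolation:
    rule: str
    index: int
    severity: str


def _severity_12s(ruleset) -> str:
    # sole-rule tiers use 1-2s as their only (hence rejecting) criterion
    return SEV_REJECTION if tuple(ruleset) == ("1-2s",) else SEV_WARNING


def evaluate_rules(points: Sequence[ControlPoint],
                   ruleset: Sequence[str] = WESTGARD_RULE_NAMES):
    """All violations of the enabled rules, earliest (then rule-order) first."""
    ruleset = tuple(ruleset)
    unknown = set(ruleset) - set(WESTGARD_RULE_NAMES)
    if unknown:
        raise ValueError(f"unknown Westgard rules: {sorted(unknown)}")
    z = [p.z for p in points]
    sev12 = _severity_12s(ruleset)
    violations = []
    for i in range(len(z)):
        for rule in ruleset:
            if rule == "1-2s" and abs(z[i]) > 2:
                violations.append(RuleViolation("1-2s", i, sev12))
            elif rule == "1-3s" and abs(z[i]) > 3:
                violations.append(RuleViolation("1-3s", i, SEV_REJECTION))
            elif rule == "2-2s" and i >= 1 and (
                    (z[i] > 2 and z[i - 1] > 2) or (z[i] < -2 and z[i - 1] < -2)):
                violations.append(RuleViolation("2-2s", i, SEV_REJECTION))
            elif rule == "R-4s" and any(
                    abs(z[i] - z[j]) > 4
                    for j in range(i)
                    if points[j].run_id == points[i].run_id):
                violations.append(RuleViolation("R-4s", i, SEV_REJECTION))
            elif rule == "4-1s" and i >= 3 and (
                    all(v > 1 for v in z[i - 3:i + 1])
                    or all(v < -1 for v in z[i - 3:i + 1])):
                violations.append(RuleViolation("4-1s", i, SEV_REJECTION))
            elif rule == "10x" and i >= 9 and (
                    all(v > 0 for v in z[i - 9:i + 1])
                    or all(v < 0 for v in z[i - 9:i + 1])):
                violations.append(RuleViolation("10x", i, SEV_REJECTION))
    # stable: already ordered by index then ruleset order
    return violations


def first_rejection(points: Sequence[ControlPoint],
                    ruleset: Sequence[str] = WESTGARD_RULE_NAMES):
    """Earliest rejection-severity violation as (rule, timestamp), or None."""
    for v in evaluate_rules(points, ruleset):
        if v.severity == SEV_REJECTION:
            return v.rule, points[v.index].timestamp
    return None


def any_violation(points: Sequence[ControlPoint],
                  ruleset: Sequence[str] = WESTGARD_RULE_NAMES,
                  include_warnings: bool = True):
    """First violation (optionally rejections only); used for verification."""
    for v in evaluate_rules(points, ruleset):
        if include_warnings or v.severity == SEV_REJECTION:
            return v
    return None
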