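"""Seeded simulator of patient and QC result streams.

Emulates the statistical structure the monitoring framework assumes:
stationary analyte streams (normal for Hb/RBC/HCT, log-normal for the
count-type WBC/PLT) with configurable CV, injectable step shifts, linear
drifts and CV inflation, sporadic gross outliers beyond ±3 SD, and
pre-analytical flags (hemolysis, lipemia, clot).  Ground-truth labels mark
the error-affected samples.

Default study conditions: PLT at 250 × 10^9/L with baseline CV 2.8%
(matching internal-QC imprecision for a low-sigma analyte) sampled at 20
patient results per hour, so a 100-sample window spans ~5 h and lead times
are naturally expressed in hours.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import AnalyteSpec, DEFAULT_ANALYTES, ResultPoint


@dataclass(frozen=True)
class ErrorSpec:
    """One injected error regime.

    kind:
      * ``step_shift``   — magnitude in multiples of target SD
      * ``linear_drift`` — magnitude in analyte units per sample
      * ``cv_inflation`` — magnitude is a CV multiplier (>1 inflates)
    """

    kind: str
    onset: int
    magnitude: float
    duration: int

    def __post_init__(self):
        if self.kind not in ("step_shift", "linear_drift", "cv_inflation"):
            raise ValueError(f"unknown error kind {self.kind!r}")
        if self.onset < 0 or self.duration <= 0:
            raise ValueError("onset >= 0 and duration > 0 required")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")


@dataclass
class ScenarioSpec:
    analyte: AnalyteSpec
    n_samples: int
    sampling_rate: float = 20.0        # samples per hour
    baseline_cv: float = 2.8           # percent
    flag_rate: float = 0.0             # per sample, per flag type
    outlier_rate: float = 0.0          # gross >3 SD errors
    errors: tuple = ()
    seed: int = 0
    distribution: Optional[str] = None  # default per analyte family
    center_id: str = "A"
    start_time: datetime = field(
        default_factory=lambda: datetime(2024, 1, 1))

    def __post_init__(self):
        if self.n_samples <= 0 or self.sampling_rate <= 0:
            raise ValueError("n_samples > 0 and sampling_rate > 0 required")
        for p in (self.flag_rate, self.outlier_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        self.errors = tuple(self.errors)
        for e in self.errors:
            if e.onset + e.duration > self.n_samples:
                raise ValueError("error extends beyond the stream")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analyte"] = dataclasses.asdict(self.analyte)
        d["errors"] = [dataclasses.asdict(e) for e in self.errors]
        d["start_time"] = self.start_time.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        d = dict(d)
        d["analyte"] = AnalyteSpec(**d["analyte"])
        d["errors"] = tuple(ErrorSpec(**e) for e in d.get("errors", []))
        d["start_time"] = datetime.fromisoformat(d["start_time"])
        return cls(**d)


def _default_distribution(analyte: AnalyteSpec) -> str:
    return "lognormal" if analyte.name in ("WBC", "PLT") else "normal"


def error_offsets(errors: Sequence[ErrorSpec], spec: AnalyteSpec,
                  n_samples: int):
    """Additive offset (units) and CV multiplier per sample index."""
    offset = np.zeros(n_samples)
    cv_mult = np.ones(n_samples)
    active = np.zeros(n_samples, dtype=bool)
    for e in errors:
        sl = slice(e.onset, e.onset + e.duration)
        active[sl] = True
        if e.kind == "step_shift":
            offset[sl] += e.magnitude * spec.target_sd
        elif e.kind == "linear_drift":
            offset[sl] += e.magnitude * np.arange(e.duration)
        elif e.kind == "cv_inflation":
            cv_mult[sl] *= e.magnitude
    return offset, cv_mult, active


def _baseline_draws(rng, dist, mean, cv_pct, n):
    sd = cv_pct / 100.0 * mean
    if dist == "normal":
        return rng.normal(mean, sd, size=n)
    c2 = (sd / mean) ** 2
    sigma = np.sqrt(np.log1p(c2))
    mu = np.log(mean) - sigma ** 2 / 2.0
    return rng.lognormal(mu, sigma, size=n)


def simulate_patient_stream(scenario: ScenarioSpec):
    """Generate (points, labels) for one patient stream.

    labels is a DataFrame with per-sample ground truth: ``in_error`` (any
    injected systematic error active), ``is_outlier`` (gross error
    injected), and ``flagged``.
    """
    spec = scenario.analyte
    dist = scenario.distribution or _default_distribution(spec)
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_samples
    offset, cv_mult, active = error_offsets(scenario.errors, spec, n)

    values = np.empty(n)
    for mult in np.unique(cv_mult):
        mask = cv_mult == mult
        values[mask] = _baseline_draws(
            rng, dist, spec.target_mean, scenario.baseline_cv * mult,
            int(mask.sum()))
    values = values + offset

    is_outlier = rng.random(n) < scenario.outlier_rate
    signs = rng.choice([-1.0, 1.0], size=n)
    magnitudes = 3.5 + np.abs(rng.normal(0.0, 1.0, size=n))
    values[is_outlier] = (spec.target_mean
                          + signs[is_outlier] * magnitudes[is_outlier]
                          * spec.target_sd)

    flag_names = ("hemolysis", "lipemia", "clot")
    flag_draws = rng.random((n, len(flag_names))) < scenario.flag_rate

    dt = timedelta(hours=1.0 / scenario.sampling_rate)
    points = []
    for i in range(n):
        flags = frozenset(f for f, hit in zip(flag_names, flag_draws[i])
                          if hit)
        points.append(ResultPoint(
            timestamp=scenario.start_time + i * dt,
            center_id=scenario.center_id, analyte=spec.name,
            value=float(values[i]), flags=flags, stream="patient"))
    labels = pd.DataFrame({
        "in_error": active,
        "is_outlier": is_outlier,
        "flagged": flag_draws.any(axis=1),
    })
    return points, labels


def simulate_qc_stream(spec: AnalyteSpec, levels: int, runs: int,
                       bias_pct: float, cv_pct: float, seed: int,
                       runs_per_day: float = 2.0,
                       start_time: Optional[datetime] = None,
                       center_id: str = "A",
                       errors: Sequence[ErrorSpec] = (),
                       patient_sampling_rate: float = 20.0) -> list:
    """QC-material draws: ``levels`` measurements per run around
    ``target·(1 + bias/100)`` with the stated CV.

    When ``errors`` are supplied (indexed on the linked patient stream),
    the same additive instrument error, mapped through the patient
    sampling rate, is applied to QC values at the corresponding times.
    """
    if cv_pct <= 0:
        raise ValueError("cv_pct must be > 0")
    rng = np.random.default_rng(seed)
    start = start_time or datetime(2024, 1, 1)
    gap = timedelta(hours=24.0 / runs_per_day)
    mean = spec.target_mean * (1.0 + bias_pct / 100.0)
    sd = cv_pct / 100.0 * mean
    horizon = max((e.onset + e.duration for e in errors), default=0)
    offset, _, _ = error_offsets(errors, spec, horizon) if errors else (
        np.zeros(0), None, None)
    points = []
    for r in range(runs):
        ts = start + r * gap
        hours = (ts - start).total_seconds() / 3600.0
        idx = int(hours * patient_sampling_rate)
        extra = float(offset[idx]) if idx < offset.size else (
            float(offset[-1]) if offset.size else 0.0)
        for lv in range(levels):
            points.append(ResultPoint(
                timestamp=ts, center_id=center_id, analyte=spec.name,
                value=float(rng.normal(mean, sd) + extra),
                stream="qc", qc_level=f"L{lv + 1}"))
    return points


def canonical_drift_scenario(seed: int = 0) -> ScenarioSpec:
    """The repo's canonical PLT drift: +0.15 × 10^9/L per sample from
    sample 400 of 800 (reaching ~8.6 SD), used for lead-time studies."""
    return ScenarioSpec(
        analyte=DEFAULT_ANALYTES["PLT"], n_samples=800,
        baseline_cv=2.8, seed=seed,
        errors=(ErrorSpec("linear_drift", onset=400, magnitude=0.15,
                          duration=400),),
        distribution="normal",
    )


def drift_training_scenarios(seed: int = 0, n_streams: int = 6,
                             n_samples: int = 900):
    """Training material for the forecaster: streams mixing stationary
    stretches with up- and down-drifts of varied slope."""
    slopes = [0.05, 0.1, 0.15, 0.25, -0.1, -0.2]
    out = []
    for k in range(n_streams):
        slope = slopes[k % len(slopes)]
        out.append(ScenarioSpec(
            analyte=DEFAULT_ANALYTES["PLT"], n_samples=n_samples,
            baseline_cv=2.8, seed=seed + 1000 + k,
            errors=(ErrorSpec("linear_drift", onset=n_samples // 3,
                              magnitude=slope,
                              duration=n_samples - n_samples // 3),),
            distribution="normal",
        ))
    return out


def make_benchmark_suite(config: Optional[dict] = None):
    """Factorial grid of shift scenarios for window-selection experiments.

    Returns ``(scenarios, manifest)``; the manifest is JSON-serialisable
    and round-trips the grid exactly.
    """
    config = config or {}
    windows = config.get("windows", (50, 100, 150))
    shifts = config.get("shift_magnitudes", (0.1, 0.25, 0.5, 1.0))
    replicates = config.get("replicates", 3)
    n_samples = config.get("n_samples", 600)
    onset = config.get("onset", 300)
    seed = config.get("seed", 0)
    analyte = config.get("analyte", DEFAULT_ANALYTES["PLT"])

    scenarios = []
    entries = []
    for w in windows:
        for s in shifts:
            for r in range(replicates):
                sc = ScenarioSpec(
                    analyte=analyte, n_samples=n_samples, baseline_cv=2.8,
                    seed=seed + 10_000 * int(w) + int(1000 * s) + r,
                    errors=(ErrorSpec("step_shift", onset=onset,
                                      magnitude=s,
                                      duration=n_samples - onset),),
                    distribution="normal")
                scenarios.append((w, sc))
                entries.append({"window": int(w), "shift": float(s),
                                "replicate": r,
                                "scenario": sc.to_dict()})
    manifest = {"grid": {"windows": [int(w) for w in windows],
                         "shift_magnitudes": [float(s) for s in shifts],
                         "replicates": int(replicates)},
                "entries": entries}
    return scenarios, manifest


def suite_from_manifest(manifest: dict):
    """Rebuild the (window, scenario) list from a manifest."""
    return [(e["window"], ScenarioSpec.from_dict(e["scenario"]))
            for e in manifest["entries"]]
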