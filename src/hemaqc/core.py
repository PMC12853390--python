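"""Domain types shared by every stage of the dynamic QC pipeline.

The toolkit monitors hematology analytes (Hb, WBC, RBC, HCT, PLT) measured
on automated analyzers.  Each analyte carries a target mean and SD (from a
stable internal-QC period), a total allowable error (TEa), and an assigned
reference value (peer-group EQA median) used for bias estimation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Sequence

import yaml

#: Recognised pre-analytical flags on a patient specimen.
FLAGS = frozenset({"hemolysis", "lipemia", "clot"})

#: Canonical Westgard rule identifiers.
WESTGARD_RULE_NAMES = ("1-2s", "1-3s", "2-2s", "R-4s", "4-1s", "10x")


@dataclass(frozen=True)
class AnalyteSpec:
    """Per-analyte constants.

    Parameters
    ----------
    name : str
        Analyte identifier (``Hb``, ``WBC``, ``RBC``, ``HCT``, ``PLT`` or a
        custom string).
    units : str
        Reporting units, e.g. ``"10^9/L"`` for PLT.
    target_mean, target_sd : float
        Stable-period mean and SD in analyte units.
    tea : float
        Total allowable error. Interpreted according to ``tea_mode``:
        ``"percent"`` (percent of target) or ``"absolute"`` (analyte units).
    reference_value : float
        Assigned peer-group value (EQA all-laboratory median) in analyte
        units; denominator of the bias computation.
    """

    name: str
    units: str
    target_mean: float
    target_sd: float
    tea: float
    reference_value: float
    tea_mode: str = "percent"

    def __post_init__(self) -> None:
        if self.target_sd <= 0:
            raise ValueError("target_sd must be > 0")
        if self.tea <= 0:
            raise ValueError("tea must be > 0")
        if self.reference_value <= 0:
            raise ValueError("reference_value must be > 0")
        if self.tea_mode not in ("percent", "absolute"):
            raise ValueError("tea_mode must be 'percent' or 'absolute'")

    @property
    def tea_pct(self) -> float:
        """TEa expressed as percent of the target mean."""
        if self.tea_mode == "percent":
            return self.tea
        return 100.0 * self.tea / self.target_mean

    @property
    def tea_units(self) -> float:
        """TEa expressed in analyte units."""
        if self.tea_mode == "absolute":
            return self.tea
        return self.tea / 100.0 * self.target_mean

    @property
    def cv_pct(self) -> float:
        return 100.0 * self.target_sd / self.target_mean


#: Default analyte registry. TEa from CLIA '88 percent limits except PLT,
#: whose allowable error is carried as an absolute ±10 × 10^9/L band.
DEFAULT_ANALYTES = {
    "Hb": AnalyteSpec("Hb", "g/L", 150.0, 1.35, 7.0, 150.0),
    "WBC": AnalyteSpec("WBC", "10^9/L", 7.0, 0.14, 15.0, 7.0),
    "RBC": AnalyteSpec("RBC", "10^12/L", 4.5, 0.054, 6.0, 4.5),
    "HCT": AnalyteSpec("HCT", "%", 42.0, 0.63, 6.0, 42.0),
    "PLT": AnalyteSpec("PLT", "10^9/L", 250.0, 7.0, 10.0, 250.0,
                       tea_mode="absolute"),
}


@dataclass(frozen=True)
class ResultPoint:
    """One measurement in a patient or QC stream."""

    timestamp: datetime
    center_id: str
    analyte: str
    value: float
    flags: frozenset = frozenset()
    stream: str = "patient"
    qc_level: Optional[str] = None

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.value):
            raise ValueError("value must be finite")
        if self.stream not in ("patient", "qc"):
            raise ValueError("stream must be 'patient' or 'qc'")
        unknown = set(self.flags) - FLAGS
        if unknown:
            raise ValueError(f"unknown flags: {sorted(unknown)}")


@dataclass
class MAConfig:
    """Moving-average monitor parameters.

    ``k_alert`` and ``k_ooc`` are multiples of the control-limit SD
    (±1.5 SD alert, ±2.5 SD out-of-control by default); ``sd_mode``
    selects what that SD is (see :mod:`hemaqc.monitor`).
    """

    baseline_window: int = 100
    min_window: int = 50
    max_window: int = 150
    k_alert: float = 1.5
    k_ooc: float = 2.5
    historical_cv_horizon: int = 1000
    sd_mode: str = "ma"   # "ma" | "ma_empirical" | "population"
    calibration_n: int = 200     # accepted samples used to fit the limits

    def validate(self) -> None:
        if not (self.min_window <= self.baseline_window <= self.max_window):
            raise ValueError("min_window <= baseline_window <= max_window required")
        if not self.k_alert < self.k_ooc:
            raise ValueError("k_alert < k_ooc required")
        if self.sd_mode not in ("ma", "ma_empirical", "population"):
            raise ValueError(
                "sd_mode must be 'ma', 'ma_empirical' or 'population'")


@dataclass
class LSTMConfig:
    """Forecaster hyper-parameters (input 100, horizon 10, 64 tanh units)."""

    input_len: int = 100
    horizon: int = 10
    hidden_units: int = 64
    activation: str = "tanh"
    split_ratio: float = 0.8
    cv_folds: int = 5
    warn_fraction_of_tea: float = 0.5
    max_epochs: int = 200
    patience: int = 10
    learning_rate: float = 3e-3
    batch_size: int = 128
    seed: int = 0
    refit_every: int = 10        # re-forecast cadence in accepted samples

    def validate(self) -> None:
        if not self.input_len > self.horizon >= 1:
            raise ValueError("input_len > horizon >= 1 required")
        if not 0.0 < self.warn_fraction_of_tea < 1.0:
            raise ValueError("warn_fraction_of_tea must lie in (0, 1)")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must lie in (0, 1)")


@dataclass
class WestgardConfig:
    enabled_rules: tuple = WESTGARD_RULE_NAMES
    #: When True, any enabled-rule violation (including a 1-2s warning)
    #: confirms an MA/LSTM alert; when False only rejections confirm.
    confirm_on_warning: bool = True

    def validate(self) -> None:
        unknown = set(self.enabled_rules) - set(WESTGARD_RULE_NAMES)
        if unknown:
            raise ValueError(f"unknown Westgard rules: {sorted(unknown)}")


@dataclass
class PreprocessConfig:
    outlier_sd: float = 3.0
    drop_flagged: bool = True


@dataclass
class RunConfig:
    """Bundle of all stage configurations, (de)serialisable to YAML/JSON."""

    ma: MAConfig = field(default_factory=MAConfig)
    lstm: LSTMConfig = field(default_factory=LSTMConfig)
    westgard: WestgardConfig = field(default_factory=WestgardConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    episode_horizon_h: float = 24.0   # event-pairing horizon for lead times
    verify_every_samples: int = 20    # re-verification cadence (simulation)

    def validate(self) -> "RunConfig":
        self.ma.validate()
        self.lstm.validate()
        self.westgard.validate()
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["westgard"]["enabled_rules"] = list(self.westgard.enabled_rules)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(
            ma=MAConfig(**d.get("ma", {})),
            lstm=LSTMConfig(**d.get("lstm", {})),
            westgard=WestgardConfig(**{
                **d.get("westgard", {}),
                "enabled_rules": tuple(
                    d.get("westgard", {}).get("enabled_rules",
                                              WESTGARD_RULE_NAMES)),
            }),
            preprocessing=PreprocessConfig(**d.get("preprocessing", {})),
            episode_horizon_h=d.get("episode_horizon_h", 24.0),
            verify_every_samples=d.get("verify_every_samples", 20),
        )
        return cfg.validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


#: Event kinds emitted by the three monitoring tiers.
EVENT_KINDS = ("lstm_warning", "ma_alert", "ma_ooc", "westgard_violation")
CLASSIFICATIONS = ("alerting", "out_of_control")
ACTIONS = ("none", "recalibration", "reagent_replacement",
           "suspend_testing", "parameter_optimization")


@dataclass
class QCEvent:
    """A typed monitoring event with its alerting/out-of-control status.

    An alerting event (MA or LSTM threshold breach) that is later confirmed
    by a Westgard failure carries BOTH classifications — the dual record
    used to score the positive predictive value of early alerts.
    """

    kind: str
    classification: tuple            # subset of CLASSIFICATIONS
    analyte: str
    center_id: str
    t_trigger: datetime
    t_confirmed: Optional[datetime] = None
    confirmed_by: Optional[str] = None
    action: str = "none"
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        self.classification = tuple(self.classification)
        if not self.classification:
            raise ValueError("classification must be populated")
        unknown = set(self.classification) - set(CLASSIFICATIONS)
        if unknown:
            raise ValueError(f"unknown classification {sorted(unknown)}")
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")

    @property
    def is_dual(self) -> bool:
        return len(self.classification) == 2


def sort_key(p: ResultPoint) -> tuple:
    """Stable stream-merge order: time, then patient before QC."""
    return (p.timestamp, 0 if p.stream == "patient" else 1)


def check_time_order(points: Sequence[ResultPoint]) -> None:
    """Reject timestamp regressions within one (center, analyte, stream)."""
    last: dict = {}
    for i, p in enumerate(points):
        key = (p.center_id, p.analyte, p.stream)
        if key in last and p.timestamp < last[key]:
            raise ValueError(
                f"timestamp regression at position {i} for stream {key}: "
                f"{p.timestamp} < {last[key]}")
        last[key] = p.timestamp
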