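"""Adaptive-window moving-average (MA) monitoring of patient-result streams.

The monitor tracks the rolling mean of accepted patient results against
dynamic control limits ``target ± k · SD_limit`` with k_alert = 1.5 and
k_ooc = 2.5.  The window starts at 100 consecutive samples and adapts each
step: it shrinks to 50 when the real-time CV (over the current buffer)
exceeds the historical CV (trailing horizon), and expands to 150 otherwise.

What "SD" scales the limits is a genuine design choice: by default
(``sd_mode="ma"``) ``SD_limit`` is the sampling SD of the MA statistic,
estimated from a stable baseline as sample-SD/sqrt(W) and rescaled to the
*current* window each step, so that ±1.5 SD_limit reflects the sampling
variability of a W-sample mean and the false-alarm rate is invariant under
window adaptation.  ``sd_mode="ma_empirical"`` instead takes the empirical
SD of rolling-MA values over the baseline (downward-biased on short
baselines because the windows overlap).  ``sd_mode="population"`` uses the
raw analyte SD: those limits essentially never fire for an averaged
statistic on stationary data and make the MA tier a slow confirmatory
layer — the mode used for lead-time studies against the LSTM tier.

Escalation: three consecutive alert evaluations, or a single breach of the
out-of-control limit, suspend testing for investigation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .core import AnalyteSpec, MAConfig, PreprocessConfig, ResultPoint

IN_CONTROL, ALERT, OUT_OF_CONTROL = "in_control", "alert", "out_of_control"
CONTINUE, SUSPEND = "continue", "suspend_and_investigate"


@dataclass
class PreprocessReport:
    n_in: int
    n_flag_removed: int
    n_outlier_removed: int
    n_out: int

    def __post_init__(self):
        assert self.n_in == self.n_out + self.n_flag_removed + self.n_outlier_removed


def preprocess_stream(points: Sequence[ResultPoint], spec: AnalyteSpec,
                      config: Optional[PreprocessConfig] = None):
    """Drop flagged specimens, then gross outliers beyond ±outlier_sd·SD.

    A specimen that is both flagged and an outlier counts as flag-removed.
    The outlier reference is the fixed analyte target/SD (not rolling
    statistics), so genuine shifts are not masked.
    """
    config = config or PreprocessConfig()
    kept, n_flag, n_out = [], 0, 0
    lo = spec.target_mean - config.outlier_sd * spec.target_sd
    hi = spec.target_mean + config.outlier_sd * spec.target_sd
    for p in points:
        if config.drop_flagged and p.flags:
            n_flag += 1
        elif not (lo <= p.value <= hi):
            n_out += 1
        else:
            kept.append(p)
    report = PreprocessReport(n_in=len(points), n_flag_removed=n_flag,
                              n_outlier_removed=n_out, n_out=len(kept))
    return kept, report


@dataclass
class MAState:
    """Rolling state of the monitor at one evaluation."""

    window_size: int
    buffer: list = field(default_factory=list)
    ma_value: Optional[float] = None
    realtime_cv: Optional[float] = None
    historical_cv: Optional[float] = None
    status: Optional[str] = None          # None during warm-up
    consecutive_alerts: int = 0


def adapt_window(state: MAState, config: Optional[MAConfig] = None) -> int:
    """CV-driven window choice: 50 if rt CV > hist CV, 150 if <=, else 100."""
    config = config or MAConfig()
    if state.realtime_cv is None or state.historical_cv is None:
        return config.baseline_window
    if state.realtime_cv > state.historical_cv:
        return config.min_window
    return config.max_window


def escalation_decision(state: MAState) -> str:
    """Suspend on >= 3 consecutive alerts or any out-of-control breach."""
    if state.status == OUT_OF_CONTROL or state.consecutive_alerts >= 3:
        return SUSPEND
    return CONTINUE


class MovingAverageMonitor(BaseEstimator):
    """Sklearn-style adaptive MA monitor.

    ``fit`` calibrates the control-limit SD and the initial historical CV on
    a stable baseline sequence of accepted values; ``monitor`` then streams
    a value sequence and returns the per-sample trace.

    Parameters mirror :class:`hemaqc.core.MAConfig`.
    """

    def __init__(self, spec: Optional[AnalyteSpec] = None,
                 baseline_window: int = 100, min_window: int = 50,
                 max_window: int = 150, k_alert: float = 1.5,
                 k_ooc: float = 2.5, historical_cv_horizon: int = 1000,
                 sd_mode: str = "ma"):
        self.spec = spec
        self.baseline_window = baseline_window
        self.min_window = min_window
        self.max_window = max_window
        self.k_alert = k_alert
        self.k_ooc = k_ooc
        self.historical_cv_horizon = historical_cv_horizon
        self.sd_mode = sd_mode

    def _config(self) -> MAConfig:
        cfg = MAConfig(baseline_window=self.baseline_window,
                       min_window=self.min_window, max_window=self.max_window,
                       k_alert=self.k_alert, k_ooc=self.k_ooc,
                       historical_cv_horizon=self.historical_cv_horizon,
                       sd_mode=self.sd_mode)
        cfg.validate()
        return cfg

    def fit(self, baseline_values: Sequence[float], y=None):
        """Calibrate SD_limit and historical CV from a stable baseline."""
        if self.spec is None:
            raise ValueError("an AnalyteSpec is required")
        cfg = self._config()
        base = np.asarray(baseline_values, dtype=float)
        if self.sd_mode == "population":
            self._sd_base = float(self.spec.target_sd)
        elif self.sd_mode == "ma":
            if base.size < 2:
                raise ValueError("baseline needs at least 2 values")
            sd = float(base.std(ddof=1))
            if sd <= 0:
                raise ValueError("degenerate baseline: zero SD")
            # SD of a W-mean under a stable baseline; rescaled per window
            self._sd_base = sd / np.sqrt(cfg.baseline_window)
        else:  # ma_empirical
            if base.size < cfg.baseline_window + 2:
                raise ValueError(
                    "baseline must exceed the MA window to estimate the SD "
                    "of the MA statistic")
            w = cfg.baseline_window
            ma = np.convolve(base, np.ones(w) / w, mode="valid")
            self._sd_base = float(ma.std(ddof=1))
            if self._sd_base <= 0:
                raise ValueError("degenerate baseline: SD of MA is zero")
        self.sd_limit_ = self._sd_limit(cfg.baseline_window)
        if base.size >= 2 and base.mean() != 0:  # initial historical CV
            self.historical_cv_ = float(base.std(ddof=1) / base.mean() * 100.0)
        else:
            self.historical_cv_ = None
        self._history = list(base[-cfg.historical_cv_horizon:])
        self.state_ = MAState(window_size=cfg.baseline_window)
        self._warmed = False
        return self

    def _sd_limit(self, window: int) -> float:
        """Control-limit SD for the given window size."""
        if self.sd_mode == "ma":
            return float(self._sd_base * np.sqrt(self.baseline_window)
                         / np.sqrt(window))
        if self.sd_mode == "ma_empirical":
            return float(self._sd_base
                         * np.sqrt(self.baseline_window / window))
        return self._sd_base

    def step(self, value: float) -> MAState:
        """Advance one accepted sample; returns the updated state.

        ``state.status`` stays ``None`` until the buffer first reaches the
        baseline window (warm-up).
        """
        cfg = self._config()
        st = self.state_
        st.buffer.append(float(value))
        if not self._warmed and len(st.buffer) >= cfg.baseline_window:
            self._warmed = True
        if self._warmed:
            buf = np.asarray(st.buffer, dtype=float)
            st.realtime_cv = (float(buf.std(ddof=1) / buf.mean() * 100.0)
                              if buf.mean() != 0 else None)
            hist = np.asarray(self._history, dtype=float)
            if hist.size >= 2 and hist.mean() != 0:
                st.historical_cv = float(hist.std(ddof=1) / hist.mean() * 100.0)
            st.window_size = adapt_window(st, cfg)
        if len(st.buffer) > st.window_size:
            del st.buffer[:len(st.buffer) - st.window_size]
        st.ma_value = float(np.mean(st.buffer))
        if self._warmed:
            # the MA averages len(buffer) values (<= window_size while the
            # buffer regrows after a shrink), so scale the limit by that
            z = ((st.ma_value - self.spec.target_mean)
                 / self._sd_limit(len(st.buffer)))
            if abs(z) > cfg.k_ooc:
                st.status = OUT_OF_CONTROL
            elif abs(z) > cfg.k_alert:
                st.status = ALERT
                st.consecutive_alerts += 1
            else:
                st.status = IN_CONTROL
                st.consecutive_alerts = 0
        # trailing history for the historical CV (accepted samples)
        self._history.append(float(value))
        if len(self._history) > cfg.historical_cv_horizon:
            del self._history[:len(self._history) - cfg.historical_cv_horizon]
        return st

    def monitor(self, values: Sequence[float]):
        """Stream a value sequence; returns a dict-of-lists trace."""
        trace = {"ma": [], "window": [], "status": [], "escalation": []}
        for v in values:
            st = self.step(v)
            trace["ma"].append(st.ma_value)
            trace["window"].append(st.window_size)
            trace["status"].append(st.status)
            trace["escalation"].append(
                escalation_decision(st) if st.status is not None else CONTINUE)
        return trace


def step(monitor: MovingAverageMonitor, value: float) -> MAState:
    """Functional wrapper over :meth:`MovingAverageMonitor.step`."""
    return monitor.step(value)
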