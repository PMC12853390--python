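"""Three-tier QC integration: LSTM prediction -> MA monitoring -> Westgard
verification, with event classification and lead-time computation.

An MA or LSTM threshold breach is an *alerting* event; fulfilment of a
Westgard failure rule is an *out-of-control* event.  An alerting event that
is subsequently confirmed by a Westgard violation carries both
classifications (one dual record), which is what allows scoring the
positive predictive value of early alerts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from typing import Callable, Optional, Sequence

import numpy as np

from .core import AnalyteSpec, QCEvent, RunConfig, ResultPoint, sort_key
from .forecaster import LSTMForecaster, predict_and_warn
from .monitor import (ALERT, OUT_OF_CONTROL, SUSPEND, MovingAverageMonitor,
                      escalation_decision, preprocess_stream)
from .sigma import QCPlan
from .westgard import ControlPoint, evaluate_rules


def classify_event(trigger: str, westgard_result: str) -> tuple:
    """Classification(s) for a trigger given its Westgard verification.

    ``westgard_result`` is ``"violation"``, ``"pass"`` or ``"pending"``.
    """
    if trigger == "westgard_violation":
        return ("out_of_control",)
    if trigger not in ("ma_alert", "ma_ooc", "lstm_warning"):
        raise ValueError(f"unknown trigger {trigger!r}")
    if westgard_result == "violation":
        return ("alerting", "out_of_control")
    return ("alerting",)


def _qc_z(value: float, spec: AnalyteSpec) -> float:
    return (value - spec.target_mean) / spec.target_sd


@dataclass
class _WestgardTier:
    """Incremental Westgard evaluation over the accumulated QC stream."""

    spec: AnalyteSpec
    rules: tuple
    confirm_on_warning: bool = True
    points: list = field(default_factory=list)
    _reported: set = field(default_factory=set)

    def add_run(self, run_points: Sequence[ResultPoint]):
        """Append one QC run; returns (new violations, confirming violation).

        The confirming violation is the first violation (warning included if
        configured) triggered by a point of this run.
        """
        start = len(self.points)
        run_id = f"run{start}"
        for p in run_points:
            self.points.append(ControlPoint(
                z=_qc_z(p.value, self.spec), run_id=run_id,
                level=p.qc_level or "L1", timestamp=p.timestamp))
        violations = evaluate_rules(self.points, self.rules)
        new = [v for v in violations
               if v.index >= start and (v.rule, v.index) not in self._reported]
        for v in new:
            self._reported.add((v.rule, v.index))
        confirm = None
        for v in new:
            if self.confirm_on_warning or v.severity == "rejection":
                confirm = v
                break
        return new, confirm


def run_monitoring(patient_stream: Sequence[ResultPoint],
                   qc_stream: Sequence[ResultPoint],
                   spec: AnalyteSpec,
                   plan: QCPlan,
                   config: Optional[RunConfig] = None,
                   forecaster: Optional[LSTMForecaster] = None,
                   qc_callback: Optional[Callable] = None):
    """Run the integrated monitoring pipeline over merged streams.

    Parameters
    ----------
    patient_stream, qc_stream : time-ordered ResultPoint sequences.
    plan : QCPlan
        Gates the tiers: ``plan.rules`` drives Westgard verification;
        ``plan.ma_enabled`` gates the MA tier; the LSTM tier runs when a
        trained ``forecaster`` is supplied.
    qc_callback : callable, optional
        ``qc_callback(timestamp, sample_index) -> [ResultPoint, ...]``:
        simulation hook drawing an immediate extra QC run when an MA/LSTM
        alert requires verification.  Without it, verification inspects
        the most recent scheduled QC run.

    Returns
    -------
    (events, info) : events in time order; info carries the preprocessing
    report, the MA trace, and the fitted monitor.

    Notes
    -----
    Confirmation is *subsequent*: an alerting event is upgraded to a dual
    alerting/out-of-control record by the first qualifying Westgard
    violation at or after its trigger within the episode horizon.  With a
    ``qc_callback``, an unresolved alert episode re-draws a verification
    run every ``verify_every_samples`` accepted samples until confirmed or
    back in control (repeat controls during investigation).
    """
    config = (config or RunConfig()).validate()
    accepted, report = preprocess_stream(patient_stream, spec,
                                         config.preprocessing)
    events: list = []
    wg = _WestgardTier(spec, tuple(plan.rules),
                       config.westgard.confirm_on_warning)

    ma_mon = None
    calib_n = config.ma.calibration_n
    if plan.ma_enabled:
        if len(accepted) < calib_n + config.ma.baseline_window:
            raise ValueError(
                "accepted stream too short for MA baseline calibration")
        baseline = [p.value for p in accepted[:calib_n]]
        ma_mon = MovingAverageMonitor(
            spec=spec, baseline_window=config.ma.baseline_window,
            min_window=config.ma.min_window, max_window=config.ma.max_window,
            k_alert=config.ma.k_alert, k_ooc=config.ma.k_ooc,
            historical_cv_horizon=config.ma.historical_cv_horizon,
            sd_mode=config.ma.sd_mode).fit(baseline)

    # merged iteration: patient before QC at equal timestamps
    tagged = ([("p", i, p) for i, p in enumerate(accepted)]
              + [("q", i, p) for i, p in enumerate(qc_stream)])
    tagged.sort(key=lambda t: (sort_key(t[2]), t[1]))

    trace = {"timestamp": [], "ma": [], "window": [], "status": []}
    values_so_far: list = []
    last_run_start = None
    pending_run: list = []
    prev_status = None
    lstm_red = False
    n_seen = 0
    violation_log: list = []      # (timestamp, rule) of qualifying violations
    episode_open = False
    episode_confirmed = False

    def _record_run(run_points):
        """Evaluate one QC run; log qualifying violations; emit rejections."""
        new, confirm = wg.add_run(run_points)
        for v in new:
            qualifies = config.westgard.confirm_on_warning or \
                v.severity == "rejection"
            if qualifies:
                violation_log.append((wg.points[v.index].timestamp, v.rule))
            if v.severity == "rejection":
                events.append(QCEvent(
                    kind="westgard_violation",
                    classification=classify_event("westgard_violation",
                                                  "violation"),
                    analyte=spec.name, center_id=run_points[0].center_id,
                    t_trigger=wg.points[v.index].timestamp,
                    confirmed_by=v.rule, action="recalibration"))
        return confirm

    def verify(t_trigger, idx):
        """Immediate verification run for an MA/LSTM trigger."""
        if qc_callback is None:
            return None, None
        extra = qc_callback(t_trigger, idx)
        if not extra:
            return None, None
        confirm = _record_run(extra)
        if confirm is not None:
            return confirm, wg.points[confirm.index].timestamp
        return None, None

    def flush_qc_run():
        nonlocal pending_run
        if pending_run:
            _record_run(pending_run)
            pending_run = []

    for tag, idx, point in tagged:
        if tag == "q":
            # group QC points sharing a timestamp into one run
            if last_run_start is not None and point.timestamp != last_run_start:
                flush_qc_run()
            last_run_start = point.timestamp
            pending_run.append(point)
            continue
        flush_qc_run()
        values_so_far.append(point.value)
        n_seen += 1

        # --- MA tier -------------------------------------------------
        if ma_mon is not None and n_seen > calib_n:
            st = ma_mon.step(point.value)
            trace["timestamp"].append(point.timestamp)
            trace["ma"].append(st.ma_value)
            trace["window"].append(st.window_size)
            trace["status"].append(st.status)
            if st.status in (ALERT, OUT_OF_CONTROL) and st.status != prev_status:
                kind = "ma_alert" if st.status == ALERT else "ma_ooc"
                confirm, t_conf = verify(point.timestamp, n_seen - 1)
                wg_result = "violation" if confirm is not None else "pending"
                action = "none"
                if escalation_decision(st) == SUSPEND:
                    action = "suspend_testing"
                elif confirm is not None:
                    action = "recalibration"
                events.append(QCEvent(
                    kind=kind,
                    classification=classify_event(kind, wg_result),
                    analyte=spec.name, center_id=point.center_id,
                    t_trigger=point.timestamp,
                    t_confirmed=t_conf,
                    confirmed_by=confirm.rule if confirm else None,
                    action=action))
                episode_open = True
                episode_confirmed = episode_confirmed or confirm is not None
            elif st.status not in (ALERT, OUT_OF_CONTROL):
                episode_open = False
                episode_confirmed = False
            # repeated verification while an episode is unresolved
            if (episode_open and not episode_confirmed
                    and qc_callback is not None
                    and n_seen % config.verify_every_samples == 0):
                confirm, _ = verify(point.timestamp, n_seen - 1)
                episode_confirmed = confirm is not None
            prev_status = st.status

        # --- LSTM tier -----------------------------------------------
        if (forecaster is not None
                and n_seen >= config.lstm.input_len
                and n_seen % config.lstm.refit_every == 0):
            window = values_so_far[-config.lstm.input_len:]
            fc = predict_and_warn(forecaster, window, spec, config.lstm,
                                  issued_at=point.timestamp)
            if fc.red_alert and not lstm_red:
                confirm, t_conf = verify(point.timestamp, n_seen - 1)
                wg_result = "violation" if confirm is not None else "pending"
                events.append(QCEvent(
                    kind="lstm_warning",
                    classification=classify_event("lstm_warning", wg_result),
                    analyte=spec.name, center_id=point.center_id,
                    t_trigger=point.timestamp,
                    t_confirmed=t_conf,
                    confirmed_by=confirm.rule if confirm else None,
                    action="recalibration" if confirm else "none"))
            lstm_red = fc.red_alert

    flush_qc_run()

    # subsequent-confirmation pass: upgrade alerting events whose first
    # qualifying violation falls within the episode horizon after trigger
    violation_log.sort()
    horizon = timedelta(hours=config.episode_horizon_h)
    for e in events:
        if e.kind == "westgard_violation" or e.is_dual:
            continue
        for t_v, rule in violation_log:
            if e.t_trigger <= t_v <= e.t_trigger + horizon:
                e.classification = ("alerting", "out_of_control")
                e.t_confirmed = t_v
                e.confirmed_by = rule
                if e.action == "none":
                    e.action = "recalibration"
                break

    events.sort(key=lambda e: e.t_trigger)
    info = {"preprocess_report": report, "trace": trace,
            "monitor": ma_mon, "n_accepted": len(accepted)}
    return events, info


def event_counts(events: Sequence[QCEvent]) -> dict:
    """Counts used by the event-log conservation check."""
    n_alerting = sum(1 for e in events if "alerting" in e.classification)
    n_ooc = sum(1 for e in events if "out_of_control" in e.classification)
    n_dual = sum(1 for e in events if e.is_dual)
    return {"n_events": len(events), "n_alerting": n_alerting,
            "n_out_of_control": n_ooc, "n_dual": n_dual}


def compute_lead_times(events: Sequence[QCEvent],
                       episode_horizon_h: float = 24.0) -> dict:
    """Per-episode lead times in hours.

    Events are grouped into episodes: a new episode starts when an event
    triggers more than ``episode_horizon_h`` hours after the episode began.
    Within each episode the lead times are

    * LSTM -> MA: first MA alert/OOC trigger minus first LSTM warning;
    * MA -> Westgard: first confirmation time minus first MA trigger.

    Episodes lacking the downstream event are excluded and counted.
    """
    if not events:
        return {"lstm_to_ma_h": _summary([]), "ma_to_westgard_h": _summary([]),
                "n_episodes": 0, "n_unconfirmed": 0}
    ordered = sorted(events, key=lambda e: e.t_trigger)
    episodes = []
    current = [ordered[0]]
    for e in ordered[1:]:
        if (e.t_trigger - current[0].t_trigger
                > timedelta(hours=episode_horizon_h)):
            episodes.append(current)
            current = [e]
        else:
            current.append(e)
    episodes.append(current)

    lstm_ma, ma_wg = [], []
    unconfirmed = 0
    for ep in episodes:
        t_lstm = min((e.t_trigger for e in ep if e.kind == "lstm_warning"),
                     default=None)
        t_ma = min((e.t_trigger for e in ep
                    if e.kind in ("ma_alert", "ma_ooc")), default=None)
        conf_times = [e.t_confirmed for e in ep if e.t_confirmed is not None]
        conf_times += [e.t_trigger for e in ep
                       if e.kind == "westgard_violation"]
        t_wg = min(conf_times, default=None)
        complete = False
        if t_lstm is not None and t_ma is not None:
            lstm_ma.append((t_ma - t_lstm).total_seconds() / 3600.0)
            complete = True
        if t_ma is not None and t_wg is not None:
            ma_wg.append((t_wg - t_ma).total_seconds() / 3600.0)
            complete = True
        if not complete:
            unconfirmed += 1
    return {"lstm_to_ma_h": _summary(lstm_ma),
            "ma_to_westgard_h": _summary(ma_wg),
            "n_episodes": len(episodes), "n_unconfirmed": unconfirmed}


def _summary(xs) -> dict:
    if not xs:
        return {"n": 0, "mean": None, "median": None}
    arr = np.asarray(xs, dtype=float)
    return {"n": int(arr.size), "mean": float(arr.mean()),
            "median": float(np.median(arr))}
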