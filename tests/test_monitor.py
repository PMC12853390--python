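"""Preprocessing and the adaptive-window MA monitor."""

from datetime import datetime, timedelta

import numpy as np
import pytest

from hemaqc.core import PreprocessConfig, ResultPoint
from hemaqc.monitor import (ALERT, CONTINUE, IN_CONTROL, OUT_OF_CONTROL,
                            SUSPEND, MAState, MovingAverageMonitor,
                            adapt_window, escalation_decision,
                            preprocess_stream)


def _stream(values, flags=None):
    t0 = datetime(2024, 1, 1)
    flags = flags or [frozenset()] * len(values)
    return [ResultPoint(t0 + timedelta(minutes=3 * i), "A", "PLT",
                        float(v), flags=f)
            for i, (v, f) in enumerate(zip(values, flags))]


class TestPreprocess:
    def test_clean_stream_untouched(self, plt_spec):
        pts = _stream([250, 252, 248])
        kept, rep = preprocess_stream(pts, plt_spec)
        assert kept == pts
        assert (rep.n_flag_removed, rep.n_outlier_removed) == (0, 0)

    def test_flagged_sample_removed(self, plt_spec):
        pts = _stream([250, 250], flags=[frozenset({"clot"}), frozenset()])
        kept, rep = preprocess_stream(pts, plt_spec)
        assert len(kept) == 1 and rep.n_flag_removed == 1

    def test_outlier_beyond_3sd_removed(self, plt_spec):
        # target 250, SD 7: 271.5 is 3.07 SD -> out; 270 is 2.86 SD -> kept
        kept, rep = preprocess_stream(_stream([271.5, 270.0]), plt_spec)
        assert rep.n_outlier_removed == 1 and kept[0].value == 270.0

    def test_flagged_not_dropped_when_disabled(self, plt_spec):
        pts = _stream([250], flags=[frozenset({"lipemia"})])
        kept, _ = preprocess_stream(pts, plt_spec,
                                    PreprocessConfig(drop_flagged=False))
        assert len(kept) == 1

    def test_report_counts_reconcile(self, plt_spec, rng):
        vals = rng.normal(250, 7, 200)
        vals[::17] = 400.0
        pts = _stream(vals)
        kept, rep = preprocess_stream(pts, plt_spec)
        assert rep.n_in == rep.n_out + rep.n_flag_removed + rep.n_outlier_removed
        assert rep.n_out == len(kept)


class TestAdaptWindow:
    def test_shrinks_when_realtime_cv_higher(self):
        st = MAState(window_size=100, realtime_cv=3.6, historical_cv=2.8)
        assert adapt_window(st) == 50

    def test_expands_on_tie_or_lower(self):
        st = MAState(window_size=100, realtime_cv=2.8, historical_cv=2.8)
        assert adapt_window(st) == 150

    def test_baseline_during_warmup(self):
        assert adapt_window(MAState(window_size=100)) == 100


class TestEscalation:
    def test_three_consecutive_alerts_suspend(self):
        st = MAState(window_size=100, status=ALERT, consecutive_alerts=3)
        assert escalation_decision(st) == SUSPEND

    def test_single_ooc_suspends(self):
        st = MAState(window_size=100, status=OUT_OF_CONTROL,
                     consecutive_alerts=0)
        assert escalation_decision(st) == SUSPEND

    def test_counter_reset_continues(self):
        st = MAState(window_size=100, status=IN_CONTROL,
                     consecutive_alerts=0)
        assert escalation_decision(st) == CONTINUE


class TestMonitor:
    def _fit(self, plt_spec, rng, **kw):
        mon = MovingAverageMonitor(spec=plt_spec, **kw)
        return mon.fit(rng.normal(250, 7, 400))

    def test_constant_stream_stays_in_control(self, plt_spec, rng):
        mon = self._fit(plt_spec, rng)
        trace = mon.monitor([250.0] * 150)
        emitted = [s for s in trace["status"] if s is not None]
        assert emitted and set(emitted) == {IN_CONTROL}
        assert trace["ma"][-1] == pytest.approx(250.0)

    def test_no_status_during_warmup(self, plt_spec, rng):
        mon = self._fit(plt_spec, rng)
        trace = mon.monitor([250.0] * 120)
        assert all(s is None for s in trace["status"][:99])
        assert trace["status"][99] is not None

    def test_alert_and_ooc_thresholds(self, plt_spec, rng):
        # constant offset streams: MA converges to the offset exactly
        for mult, expected in [(1.6, ALERT), (2.6, OUT_OF_CONTROL)]:
            mon = self._fit(plt_spec, rng, sd_mode="population")
            trace = mon.monitor([250.0 + mult * 7.0] * 150)
            assert trace["status"][-1] == expected

    def test_window_domain(self, plt_spec, rng):
        mon = self._fit(plt_spec, rng)
        trace = mon.monitor(rng.normal(250, 7, 600))
        assert set(trace["window"]) <= {50, 100, 150}

    def test_ma_equals_brute_force_window_mean(self, plt_spec):
        # oracle: mean over the last window-size accepted values
        for seed in range(30):
            r = np.random.default_rng(seed)
            mon = MovingAverageMonitor(spec=plt_spec).fit(r.normal(250, 7, 300))
            vals = r.normal(250, 7, 250)
            trace = mon.monitor(vals)
            # reconstruct buffer length: grows to window, trimmed on shrink
            buf_len = 0
            for i, w in enumerate(trace["window"]):
                buf_len = min(buf_len + 1, w)
                expected = vals[i + 1 - buf_len:i + 1].mean()
                assert trace["ma"][i] == pytest.approx(expected, abs=1e-12)

    def test_shift_detection_probability_monotone(self, plt_spec):
        # empirical detection rate is non-decreasing in shift magnitude
        rates = []
        for delta in (0.1, 0.25, 0.5, 1.0):
            hits = 0
            for seed in range(15):
                r = np.random.default_rng(1000 + seed)
                mon = MovingAverageMonitor(spec=plt_spec).fit(
                    r.normal(250, 7, 300))
                vals = np.concatenate([
                    r.normal(250, 7, 150),
                    r.normal(250 + delta * 7, 7, 250)])
                trace = mon.monitor(vals)
                post = trace["status"][150:]
                hits += any(s in (ALERT, OUT_OF_CONTROL) for s in post)
            rates.append(hits / 15)
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_stationary_alert_rate_within_pinned_bound(self, plt_spec):
        # calibrated bound: mean alert rate on stationary streams whose
        # generator CV equals the historical CV stays under 250/1000
        counts = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            mon = MovingAverageMonitor(spec=plt_spec).fit(r.normal(250, 7, 300))
            trace = mon.monitor(r.normal(250, 7, 1100))
            emitted = [s for s in trace["status"] if s is not None][:1000]
            counts.append(sum(s == ALERT for s in emitted))
        assert np.mean(counts) < 250
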