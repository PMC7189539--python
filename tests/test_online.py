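import json

import numpy as np
import pytest

import sitpress.online as online_mod
from sitpress.io import MotionClass, PressureFrame, Side, Task
from sitpress.online import (
    DetectionEvent,
    OnlineDetector,
    StreamConfig,
    detect_stream,
    emit_feedback,
)

from conftest import make_trial


class _ScriptedModel:
    """Stand-in with the attributes the detector touches."""

    n_features = 10


def scripted_detector(monkeypatch, decisions, config):
    """Detector whose raw per-window predictions follow a script."""
    script = iter(decisions)
    monkeypatch.setattr(online_mod, "predict", lambda m, x: [next(script)])
    monkeypatch.setattr(
        online_mod, "decision_confidence", lambda m, x: np.array([0.9])
    )
    return OnlineDetector(_ScriptedModel(), config)


def feed_frames(detector, n, rate=50.0):
    values = np.ones((32, 32))
    out = []
    for k in range(n):
        out.append(detector.step(PressureFrame(values, timestamp=k / rate)))
    return out


class TestStreamConfig:
    def test_defaults(self):
        cfg = StreamConfig()
        assert (cfg.window_len, cfg.stride, cfg.smoothing_k) == (50, 10, 5)

    @pytest.mark.parametrize(
        "kw", [{"window_len": 0}, {"stride": 0}, {"stride": 60}, {"debounce_m": 0}]
    )
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            StreamConfig(**kw)


class TestEventLogic:
    def test_all_nc_no_events(self, monkeypatch):
        cfg = StreamConfig(window_len=10, stride=5, smoothing_k=1)
        det = scripted_detector(monkeypatch, ["NC"] * 20, cfg)
        feed_frames(det, 100)
        assert det.events == []

    def test_single_spurious_decision_no_event(self, monkeypatch):
        cfg = StreamConfig(window_len=10, stride=5, smoothing_k=1, debounce_m=3)
        script = ["NC"] * 5 + ["TLF"] + ["NC"] * 10
        det = scripted_detector(monkeypatch, script, cfg)
        feed_frames(det, 85)
        assert det.events == []

    def test_sustained_class_opens_one_event(self, monkeypatch):
        cfg = StreamConfig(window_len=10, stride=5, smoothing_k=1, debounce_m=3)
        script = ["NC"] * 4 + ["TLF"] * 8
        det = scripted_detector(monkeypatch, script, cfg)
        feed_frames(det, 10 + 5 * (len(script) - 1))
        assert len(det.events) == 1
        event = det.events[0]
        assert event.comp_class == "TLF"
        assert event.is_open  # never returned to NC

    def test_event_closes_after_close_m_nc(self, monkeypatch):
        cfg = StreamConfig(
            window_len=10, stride=5, smoothing_k=1, debounce_m=2, close_m=2
        )
        script = ["TR"] * 4 + ["NC"] * 4
        det = scripted_detector(monkeypatch, script, cfg)
        feed_frames(det, 10 + 5 * (len(script) - 1))
        (event,) = det.events
        assert not event.is_open
        # offset = time of first NC decision of the closing run
        nc_first_decision_idx = 4
        expected_offset = (10 + 5 * nc_first_decision_idx - 1) / 50.0
        assert event.offset_time == pytest.approx(expected_offset)

    def test_class_switch_closes_and_reopens(self, monkeypatch):
        cfg = StreamConfig(
            window_len=10, stride=5, smoothing_k=1, debounce_m=2, close_m=2
        )
        script = ["TR"] * 4 + ["SE"] * 4
        det = scripted_detector(monkeypatch, script, cfg)
        feed_frames(det, 10 + 5 * (len(script) - 1))
        assert [e.comp_class for e in det.events] == ["TR", "SE"]
        assert det.events[0].offset_time == pytest.approx(det.events[1].onset_time)

    def test_events_time_ordered_non_overlapping(self, monkeypatch):
        cfg = StreamConfig(
            window_len=10, stride=5, smoothing_k=1, debounce_m=2, close_m=2
        )
        script = ["TR"] * 3 + ["NC"] * 3 + ["TLF"] * 3 + ["NC"] * 3
        det = scripted_detector(monkeypatch, script, cfg)
        feed_frames(det, 10 + 5 * (len(script) - 1))
        assert len(det.events) == 2
        first, second = det.events
        assert first.offset_time <= second.onset_time
        assert first.onset_time < first.offset_time

    def test_majority_smoothing_suppresses_flicker(self, monkeypatch):
        cfg = StreamConfig(window_len=10, stride=5, smoothing_k=3, debounce_m=2)
        # raw flickers TLF every other window: isolated TLF majorities
        # survive smoothing but never persist, so debounce blocks events
        script = ["NC", "TLF", "NC", "TLF", "NC", "TLF", "NC"]
        det = scripted_detector(monkeypatch, script, cfg)
        feed_frames(det, 10 + 5 * (len(script) - 1))
        assert det.events == []
        smoothed = [d["smoothed"] for d in det.decisions]
        assert smoothed == ["NC", "NC", "NC", "TLF", "NC", "TLF", "NC"]

    def test_no_nc_event_possible(self):
        with pytest.raises(ValueError):
            DetectionEvent(comp_class="NC", onset_time=0.0)


class TestDetectStream:
    def test_stream_batch_equivalence(self, small_model, small_cohort):
        trials, _ = small_cohort
        cfg = StreamConfig(window_len=50, stride=10, smoothing_k=3)
        for trial in trials[:4]:
            events, trace = detect_stream(trial, small_model, cfg)
            det = OnlineDetector(small_model, cfg, trial.affected_side)
            for frame in trial.frames:
                det.step(frame)
            assert det.events == events
            assert [d["smoothed"] for d in det.decisions] == trace["smoothed"].tolist()

    def test_reduction_to_batch_predict(self, small_model, small_cohort):
        from sitpress.classify import predict
        from sitpress.features import extract_features

        trials, _ = small_cohort
        trial = trials[0]
        cfg = StreamConfig(window_len=50, stride=50, smoothing_k=1, debounce_m=1)
        _, trace = detect_stream(trial, small_model, cfg)
        arr = trial.stack()
        expected = []
        for start in range(0, len(arr) - 50 + 1, 50):
            fv = extract_features(arr[start : start + 50], trial.affected_side)
            expected.append(predict(small_model, fv.as_array())[0])
        assert trace["raw"].tolist() == expected
        assert trace["smoothed"].tolist() == expected

    def test_short_sequence_rejected(self, small_model, small_cohort):
        trials, _ = small_cohort
        with pytest.raises(ValueError, match="shorter"):
            detect_stream(trials[0].frames[:30], small_model, StreamConfig())

    def test_decision_cadence(self, small_model, small_cohort):
        trials, _ = small_cohort
        trial = trials[0]
        cfg = StreamConfig(window_len=50, stride=10)
        _, trace = detect_stream(trial, small_model, cfg)
        assert len(trace) == (len(trial.frames) - 50) // 10 + 1

    def test_confidence_in_unit_interval(self, small_model, small_cohort):
        trials, _ = small_cohort
        _, trace = detect_stream(trials[0], small_model)
        assert trace["confidence"].between(0, 1).all()


class TestLatency:
    def test_step_change_latency_bound(self, profile, cfg, small_model):
        stream_cfg = StreamConfig()
        nc = make_trial(profile, cfg, cls=MotionClass.NC, duration=4.0, seed=21)
        tlf = make_trial(
            profile, cfg, cls=MotionClass.TLF, magnitude=0.9, duration=4.0, seed=21
        )
        frames = np.concatenate([nc.stack(), tlf.stack()])
        t0 = len(nc.frames) / 50.0
        trial_frames = [
            PressureFrame(v, timestamp=k / 50.0) for k, v in enumerate(frames)
        ]
        events, _ = detect_stream(trial_frames, small_model, stream_cfg)
        tlf_events = [e for e in events if e.comp_class == "TLF"]
        assert len(tlf_events) == 1
        lag_frames = (
            stream_cfg.window_len
            + (stream_cfg.debounce_m - 1 + stream_cfg.smoothing_k - 1)
            * stream_cfg.stride
        )
        assert t0 < tlf_events[0].onset_time <= t0 + lag_frames / 50.0


class TestEmitFeedback:
    def event(self):
        return DetectionEvent("TLF", onset_time=1.0, offset_time=2.5, peak_confidence=0.8)

    def test_json_fields(self):
        payload = json.loads(self.event().to_json())
        assert set(payload) == {
            "comp_class", "onset_time", "offset_time", "peak_confidence",
        }
        assert payload["comp_class"] == "TLF"

    def test_file_sink_line_count(self, tmp_path):
        sink = tmp_path / "events.jsonl"
        for _ in range(3):
            assert emit_feedback(self.event(), sink)
        assert len(sink.read_text().splitlines()) == 3

    def test_callable_sink(self):
        got = []
        emit_feedback(self.event(), got.append)
        assert json.loads(got[0]) ["comp_class"] == "TLF"

    def test_malformed_sink_errors_after_retries(self, tmp_path):
        calls = []

        def bad_sink(line):
            calls.append(line)
            raise ConnectionError("down")

        with pytest.raises(IOError, match="after 2 attempts"):
            emit_feedback(self.event(), bad_sink, n_retries=2, retry_delay_s=0.0)
        assert len(calls) == 2
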