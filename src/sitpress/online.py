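"""Sliding-window streaming detection of compensation episodes.

A detector buffers incoming frames; once the buffer holds one full
window it makes a raw prediction every ``stride`` frames, smooths the
last ``smoothing_k`` raw decisions by majority vote (ties broken by the
class order NC < TR < TLF < SE), and applies debounce logic: an event
opens when a non-NC smoothed class persists ``debounce_m`` consecutive
decisions (onset = time of the first decision in the run) and closes
after ``close_m`` consecutive NC decisions.  Events are non-overlapping,
time-ordered and never carry class NC.

``detect_stream`` is literally a fold of ``step`` over the sequence, so
stream and batch behaviour are identical by construction.
"""

from __future__ import annotations

import collections
import dataclasses
import json
import socket
import time
import urllib.parse
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from sitpress.classify import TrainedModel, decision_confidence, predict
from sitpress.features import extract_features
from sitpress.io import CLASS_ORDER, LabeledTrial, MotionClass, PressureFrame, Side

__all__ = [
    "StreamConfig",
    "DetectionEvent",
    "OnlineDetector",
    "detect_stream",
    "emit_feedback",
]

_CLASS_RANK = {c.value: k for k, c in enumerate(CLASS_ORDER)}


@dataclasses.dataclass(frozen=True)
class StreamConfig:
    window_len: int = 50  # frames; 1 s at 50 Hz
    stride: int = 10
    smoothing_k: int = 5
    debounce_m: int = 3
    close_m: int = 3

    def __post_init__(self):
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if not 1 <= self.stride <= self.window_len:
            raise ValueError("stride must satisfy 1 <= stride <= window_len")
        if min(self.smoothing_k, self.debounce_m, self.close_m) < 1:
            raise ValueError("smoothing_k, debounce_m, close_m must be >= 1")


@dataclasses.dataclass
class DetectionEvent:
    """One compensation episode; ``offset_time`` is None while open."""

    comp_class: str
    onset_time: float
    offset_time: float | None = None
    peak_confidence: float = 0.0

    def __post_init__(self):
        if self.comp_class == MotionClass.NC.value:
            raise ValueError("events never carry class NC")

    @property
    def is_open(self) -> bool:
        return self.offset_time is None

    def to_json(self) -> str:
        return json.dumps(
            {
                "comp_class": self.comp_class,
                "onset_time": self.onset_time,
                "offset_time": self.offset_time,
                "peak_confidence": self.peak_confidence,
            }
        )


def _majority(decisions: Sequence[str]) -> str:
    """Majority vote; ties broken by class order NC < TR < TLF < SE."""
    counts = collections.Counter(decisions)
    top = max(counts.values())
    return min(
        (c for c, n in counts.items() if n == top), key=lambda c: _CLASS_RANK[c]
    )


class OnlineDetector:
    """Stateful frame-by-frame detector around a trained model."""

    def __init__(
        self,
        model: TrainedModel,
        config: StreamConfig | None = None,
        affected_side: Side = Side.RIGHT,
        mirror: bool = True,
    ):
        if model is None:
            raise ValueError("a trained model must be loaded before stepping")
        self.model = model
        self.config = config or StreamConfig()
        self.affected_side = Side(affected_side)
        self.mirror = mirror
        self._buffer: collections.deque = collections.deque(
            maxlen=self.config.window_len
        )
        self._raw: collections.deque = collections.deque(
            maxlen=self.config.smoothing_k
        )
        self._n_frames = 0
        self._run_class: str | None = None  # current smoothed run (non-NC, closed ev.)
        self._run_start: float = 0.0
        self._run_len = 0
        self._nc_run_len = 0
        self._nc_run_start: float = 0.0
        self._open_event: DetectionEvent | None = None
        self.events: list[DetectionEvent] = []
        self.decisions: list[dict] = []

    def step(
        self, frame: PressureFrame
    ) -> tuple[str | None, DetectionEvent | None]:
        """Feed one frame; returns (smoothed decision, newly opened event),
        either of which may be None."""
        self._buffer.append(frame)
        self._n_frames += 1
        cfg = self.config
        if self._n_frames < cfg.window_len:
            return None, None
        if (self._n_frames - cfg.window_len) % cfg.stride != 0:
            return None, None

        window = np.stack([f.values for f in self._buffer])
        fv = extract_features(window, self.affected_side, mirror=self.mirror)
        x = fv.as_array()[None, :]
        raw = predict(self.model, x)[0]
        confidence = float(decision_confidence(self.model, x)[0])
        self._raw.append(raw)
        smoothed = _majority(list(self._raw))
        t = float(frame.timestamp)
        self.decisions.append(
            {"time": t, "raw": raw, "smoothed": smoothed, "confidence": confidence}
        )

        opened = self._update_events(smoothed, t, confidence)
        return smoothed, opened

    def _update_events(
        self, smoothed: str, t: float, confidence: float
    ) -> DetectionEvent | None:
        cfg = self.config
        nc = MotionClass.NC.value
        opened: DetectionEvent | None = None

        if smoothed == nc:
            if self._nc_run_len == 0:
                self._nc_run_start = t
            self._nc_run_len += 1
            self._run_class, self._run_len = None, 0
            if self._open_event is not None and self._nc_run_len >= cfg.close_m:
                self._open_event.offset_time = self._nc_run_start
                self._open_event = None
        else:
            self._nc_run_len = 0
            if self._open_event is not None and smoothed == self._open_event.comp_class:
                self._open_event.peak_confidence = max(
                    self._open_event.peak_confidence, confidence
                )
                self._run_class, self._run_len = None, 0
            else:
                if smoothed != self._run_class:
                    self._run_class, self._run_start, self._run_len = smoothed, t, 0
                self._run_len += 1
                if self._run_len >= cfg.debounce_m:
                    if self._open_event is not None:
                        # class switch: close the current episode at the
                        # start of the new sustained run
                        self._open_event.offset_time = self._run_start
                    opened = DetectionEvent(
                        comp_class=smoothed,
                        onset_time=self._run_start,
                        peak_confidence=confidence,
                    )
                    self.events.append(opened)
                    self._open_event = opened
                    self._run_class, self._run_len = None, 0
        return opened


def detect_stream(
    frames: Sequence[PressureFrame] | LabeledTrial,
    model: TrainedModel,
    config: StreamConfig | None = None,
    affected_side: Side | None = None,
    mirror: bool = True,
) -> tuple[list[DetectionEvent], pd.DataFrame]:
    """Run the detector over a recorded sequence.

    Returns the events plus the per-window decision trace (time, raw,
    smoothed, confidence).  Equivalent by construction to calling
    :meth:`OnlineDetector.step` frame by frame.
    """
    if isinstance(frames, LabeledTrial):
        if affected_side is None:
            affected_side = frames.affected_side
        frames = frames.frames
    if affected_side is None:
        affected_side = Side.RIGHT
    config = config or StreamConfig()
    if len(frames) < config.window_len:
        raise ValueError(
            f"sequence of {len(frames)} frames is shorter than the "
            f"{config.window_len}-frame window"
        )
    detector = OnlineDetector(model, config, affected_side, mirror=mirror)
    for frame in frames:
        detector.step(frame)
    return detector.events, pd.DataFrame(
        detector.decisions, columns=["time", "raw", "smoothed", "confidence"]
    )


def emit_feedback(
    event: DetectionEvent,
    sink: Callable[[str], None] | str | Path,
    n_retries: int = 3,
    retry_delay_s: float = 0.1,
) -> bool:
    """Deliver one event as a newline-delimited JSON message.

    ``sink`` may be a callable, a file path (appended), or a
    ``tcp://host:port`` address.  At-least-once: retries ``n_retries``
    times before raising the last error.
    """
    line = event.to_json() + "\n"
    last_error: Exception | None = None
    for _ in range(max(n_retries, 1)):
        try:
            if callable(sink):
                sink(line)
            elif isinstance(sink, (str, Path)) and str(sink).startswith("tcp://"):
                parsed = urllib.parse.urlparse(str(sink))
                with socket.create_connection(
                    (parsed.hostname, parsed.port), timeout=2.0
                ) as sock:
                    sock.sendall(line.encode())
            else:
                with open(sink, "a") as fh:
                    fh.write(line)
            return True
        except Exception as exc:  # noqa: BLE001 - retried, then re-raised
            last_error = exc
            time.sleep(retry_delay_s)
    raise IOError(f"failed to deliver event after {n_retries} attempts") from last_error
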