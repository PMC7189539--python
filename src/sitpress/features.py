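"""The ten window-level features of a seat-pressure frame sequence.

In fixed order: AVE_SSV, MAX_SV, AVE/SD of the M/L and A/P centre of
pressure, and AVE/SD of the M/L and A/P half-grid load ratios.  COP
components are pressure-weighted centroids in grid units; ratios compare
the two 16-column (or 16-row) halves of the grid.

Frames from left-affected subjects are column-reversed before feature
computation (canonical mirroring) so that medial/lateral features are
pose-invariant when pooling subjects with different affected sides; pass
``mirror=False`` to disable.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from sitpress.io import GRID, LabeledTrial, PressureFrame, Side

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "frame_cop",
    "frame_ratios",
    "extract_features",
    "feature_table",
    "write_feature_table",
]

FEATURE_NAMES: tuple[str, ...] = (
    "ave_ssv",
    "max_sv",
    "ave_ml_cop",
    "sd_ml_cop",
    "ave_ap_cop",
    "sd_ap_cop",
    "ave_ml_ratio",
    "sd_ml_ratio",
    "ave_ap_ratio",
    "sd_ap_ratio",
)

#: Ratio denominators (and numerators) are floored at this fraction of the
#: frame's peak value so the ratios stay finite.
RATIO_FLOOR_FRAC = 1e-9

_HALF = GRID // 2
_COLS = np.arange(GRID, dtype=float)
_ROWS = np.arange(GRID, dtype=float)


class FeatureVector(NamedTuple):
    ave_ssv: float
    max_sv: float
    ave_ml_cop: float
    sd_ml_cop: float
    ave_ap_cop: float
    sd_ap_cop: float
    ave_ml_ratio: float
    sd_ml_ratio: float
    ave_ap_ratio: float
    sd_ap_ratio: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


class DegenerateFrameError(ValueError):
    pass


class DegenerateWindowError(ValueError):
    pass


def _values(frame: PressureFrame | np.ndarray) -> np.ndarray:
    v = frame.values if isinstance(frame, PressureFrame) else np.asarray(frame, float)
    if v.shape != (GRID, GRID):
        raise ValueError(f"expected ({GRID}, {GRID}) frame, got {v.shape}")
    return v


def _maybe_mirror(values: np.ndarray, affected_side: Side, mirror: bool) -> np.ndarray:
    if mirror and Side(affected_side) is Side.LEFT:
        return values[..., ::-1]
    return values


def frame_cop(frame: PressureFrame | np.ndarray) -> tuple[float, float]:
    """Pressure-weighted centroid ``(ml_cop, ap_cop)`` = (column, row).

    Raises :class:`DegenerateFrameError` on an all-zero frame.
    """
    v = _values(frame)
    total = v.sum()
    if total <= 0:
        raise DegenerateFrameError("all-zero frame has no centre of pressure")
    ml = float((v.sum(axis=0) * _COLS).sum() / total)
    ap = float((v.sum(axis=1) * _ROWS).sum() / total)
    return ml, ap


def frame_ratios(
    frame: PressureFrame | np.ndarray,
    affected_side: Side = Side.RIGHT,
    mirror: bool = True,
) -> tuple[float, float]:
    """Half-grid load ratios ``(ml_ratio, ap_ratio)`` after canonical mirroring.

    ml_ratio = load(columns 0..15) / load(columns 16..31),
    ap_ratio = load(rows 0..15) / load(rows 16..31); both numerator and
    denominator are floored at ``RATIO_FLOOR_FRAC * peak`` so the result
    is always finite and positive (total function).
    """
    v = _maybe_mirror(_values(frame), affected_side, mirror)
    peak = float(v.max())
    if peak <= 0:
        return 1.0, 1.0  # all-zero frame: symmetric by convention
    eps = RATIO_FLOOR_FRAC * peak
    left, right = float(v[:, :_HALF].sum()), float(v[:, _HALF:].sum())
    ant, post = float(v[:_HALF, :].sum()), float(v[_HALF:, :].sum())
    ml = max(left, eps) / max(right, eps)
    ap = max(ant, eps) / max(post, eps)
    return ml, ap


def extract_features(
    window: Sequence[PressureFrame] | np.ndarray | LabeledTrial,
    affected_side: Side = Side.RIGHT,
    mirror: bool = True,
) -> FeatureVector:
    """Compute the ten features of a frame window.

    ``ave_ssv`` averages every cell of every frame (zeros included);
    ``max_sv`` is the window-wide peak.  The four per-frame series (M/L
    COP, A/P COP, M/L ratio, A/P ratio) contribute their mean and
    population (N-denominator) standard deviation; frames with zero
    total pressure are excluded from these series but still count toward
    ``ave_ssv``.
    """
    if isinstance(window, LabeledTrial):
        affected_side = window.affected_side
        window = window.stack()
    elif not isinstance(window, np.ndarray):
        window = np.stack([_values(f) for f in window])
    window = np.asarray(window, dtype=float)
    if window.ndim == 2:
        window = window[None]
    if window.size == 0:
        raise DegenerateWindowError("empty window")
    if window.shape[1:] != (GRID, GRID):
        raise ValueError(f"expected (T, {GRID}, {GRID}) window, got {window.shape}")

    v = _maybe_mirror(window, affected_side, mirror)
    totals = v.sum(axis=(1, 2))
    loaded = totals > 0
    if not loaded.any():
        raise DegenerateWindowError("every frame in the window has zero total pressure")

    ave_ssv = float(v.mean())
    max_sv = float(v.max())

    vl = v[loaded]
    tot = totals[loaded]
    ml_cop = (vl.sum(axis=1) * _COLS).sum(axis=1) / tot
    ap_cop = (vl.sum(axis=2) * _ROWS).sum(axis=1) / tot

    eps = RATIO_FLOOR_FRAC * vl.max(axis=(1, 2))
    left = vl[:, :, :_HALF].sum(axis=(1, 2))
    right = vl[:, :, _HALF:].sum(axis=(1, 2))
    ant = vl[:, :_HALF, :].sum(axis=(1, 2))
    post = vl[:, _HALF:, :].sum(axis=(1, 2))
    ml_ratio = np.maximum(left, eps) / np.maximum(right, eps)
    ap_ratio = np.maximum(ant, eps) / np.maximum(post, eps)

    def _ave_sd(series: np.ndarray) -> tuple[float, float]:
        return float(series.mean()), float(series.std())  # population SD

    ave_ml_cop, sd_ml_cop = _ave_sd(ml_cop)
    ave_ap_cop, sd_ap_cop = _ave_sd(ap_cop)
    ave_ml_ratio, sd_ml_ratio = _ave_sd(ml_ratio)
    ave_ap_ratio, sd_ap_ratio = _ave_sd(ap_ratio)

    return FeatureVector(
        ave_ssv,
        max_sv,
        ave_ml_cop,
        sd_ml_cop,
        ave_ap_cop,
        sd_ap_cop,
        ave_ml_ratio,
        sd_ml_ratio,
        ave_ap_ratio,
        sd_ap_ratio,
    )


def feature_table(trials: Sequence[LabeledTrial], mirror: bool = True) -> pd.DataFrame:
    """One row per trial: subject_id, task, label, then the ten features."""
    rows = []
    for trial in trials:
        fv = extract_features(trial.stack(), trial.affected_side, mirror=mirror)
        rows.append(
            {
                "subject_id": trial.subject_id,
                "task": trial.task.value,
                "label": trial.label.value,
                **dict(zip(FEATURE_NAMES, fv)),
            }
        )
    return pd.DataFrame(rows)


def window_feature_table(
    trials: Sequence[LabeledTrial],
    window_len: int = 50,
    stride: int = 50,
    mirror: bool = True,
) -> pd.DataFrame:
    """Sliding-window feature rows (window inherits the trial's label).

    Used to train models that will be deployed on streaming windows of
    the same length, so the training and deployment feature
    distributions match; the default stride yields non-overlapping
    windows.
    """
    rows = []
    for trial in trials:
        arr = trial.stack()
        for start in range(0, len(arr) - window_len + 1, stride):
            fv = extract_features(
                arr[start : start + window_len], trial.affected_side, mirror=mirror
            )
            rows.append(
                {
                    "subject_id": trial.subject_id,
                    "task": trial.task.value,
                    "label": trial.label.value,
                    "window_start": start,
                    **dict(zip(FEATURE_NAMES, fv)),
                }
            )
    return pd.DataFrame(rows)


def write_feature_table(df: pd.DataFrame, path) -> None:
    cols = ["subject_id", "task", "label", *FEATURE_NAMES]
    df[cols].to_csv(path, index=False)
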