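"""Plain-text pressure-trial format, core domain types, and manifests.

A trial file starts with a ``key: value`` metadata header, then one block
per frame: 32 lines of 32 whitespace-separated decimal values, blocks
separated by blank lines.  Values are written with ``repr`` so that a
write/read round trip is bit-exact.

Grid convention (inherited by every other module): row index runs along
the anterior/posterior axis with row 0 at the anterior (front) edge of
the seat; column index runs left/right with column 0 at the sitter's
left.  Timestamps are not stored; they are reconstructed as
``index / sample_rate``.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GRID = 32
DEFAULT_SAMPLE_RATE = 50.0

_HEADER_MAGIC = "# sitpress trial v1"


class Task(str, enum.Enum):
    """The three seated reaching tasks."""

    BACK_AND_FORTH = "back_and_forth"
    SIDE_TO_SIDE = "side_to_side"
    UP_AND_DOWN = "up_and_down"


class MotionClass(str, enum.Enum):
    """Motion classes: noncompensation plus three compensation patterns."""

    NC = "NC"
    TR = "TR"
    TLF = "TLF"
    SE = "SE"


#: Canonical class order, also the deterministic tie-break order.
CLASS_ORDER: tuple[MotionClass, ...] = (
    MotionClass.NC,
    MotionClass.TR,
    MotionClass.TLF,
    MotionClass.SE,
)


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"

    def flipped(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


class TrialParseError(ValueError):
    """Raised when a trial file violates the dialect; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class EmptyInputError(ValueError):
    pass


@dataclasses.dataclass
class PressureFrame:
    """One 32x32 grid of non-negative sensor values at a timestamp (s)."""

    values: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def validate_frame(frame: PressureFrame | np.ndarray) -> list[str]:
    """Return a list of invariant violations (empty iff the frame is valid).

    Total function: never raises; each violation names the offending
    row/column.
    """
    values = frame.values if isinstance(frame, PressureFrame) else np.asarray(frame)
    violations: list[str] = []
    if values.ndim != 2 or values.shape != (GRID, GRID):
        violations.append(f"grid shape {values.shape} != ({GRID}, {GRID})")
        return violations
    bad = ~np.isfinite(values)
    for i, j in zip(*np.nonzero(bad)):
        violations.append(f"non-finite value at (row {i}, col {j})")
    neg = np.isfinite(values) & (values < 0)
    for i, j in zip(*np.nonzero(neg)):
        violations.append(f"negative value {values[i, j]} at (row {i}, col {j})")
    return violations


@dataclasses.dataclass
class LabeledTrial:
    """A frame sequence plus metadata; the unit of classification."""

    frames: list[PressureFrame]
    subject_id: str
    task: Task
    label: MotionClass
    sample_rate: float = DEFAULT_SAMPLE_RATE
    affected_side: Side = Side.RIGHT

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.label = MotionClass(self.label)
        self.affected_side = Side(self.affected_side)

    def stack(self) -> np.ndarray:
        """All frames as a (T, 32, 32) array."""
        return np.stack([f.values for f in self.frames])

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames])

    def validate(self) -> list[str]:
        violations: list[str] = []
        if len(self.frames) < 1:
            violations.append("trial has no frames")
        if not self.sample_rate > 0:
            violations.append(f"sample_rate {self.sample_rate} not > 0")
        for k, frame in enumerate(self.frames):
            violations += [f"frame {k}: {v}" for v in validate_frame(frame)]
        ts = self.timestamps
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            violations.append("timestamps not strictly increasing")
        return violations


def frames_from_array(
    values: np.ndarray, sample_rate: float = DEFAULT_SAMPLE_RATE
) -> list[PressureFrame]:
    """Wrap a (T, 32, 32) array into frames with index/rate timestamps."""
    return [
        PressureFrame(values=v, timestamp=k / sample_rate)
        for k, v in enumerate(np.asarray(values, dtype=float))
    ]


def _format_row(row: np.ndarray) -> str:
    return " ".join(repr(float(v)) for v in row)


def write_trial(trial: LabeledTrial, path: str | Path) -> Path:
    """Write a trial to `path` in the plain-text dialect. Lossless."""
    path = Path(path)
    violations = trial.validate()
    if violations:
        raise ValueError("invalid trial: " + "; ".join(violations[:5]))
    lines = [
        _HEADER_MAGIC,
        f"subject_id: {trial.subject_id}",
        f"task: {trial.task.value}",
        f"label: {trial.label.value}",
        f"sample_rate: {trial.sample_rate!r}",
        f"affected_side: {trial.affected_side.value}",
    ]
    for frame in trial.frames:
        lines.append("")
        lines.extend(_format_row(row) for row in frame.values)
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trial(path: str | Path, metadata: dict | None = None) -> LabeledTrial:
    """Read a trial file; `metadata` entries override the file header.

    Raises :class:`TrialParseError` (with a line number) on malformed
    grids and :class:`EmptyInputError` on files with no frames.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyInputError(f"{path}: empty trial file")
    lines = text.splitlines()

    header: dict[str, str] = {}
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            break
        if line.startswith("#"):
            i += 1
            continue
        if ":" not in line:
            break  # first frame row if no blank line after header
        key, _, value = line.partition(":")
        header[key.strip()] = value.strip()
        i += 1

    meta = dict(header)
    if metadata:
        meta.update({k: v for k, v in metadata.items() if v is not None})

    sample_rate = float(meta.get("sample_rate", DEFAULT_SAMPLE_RATE))

    grids: list[np.ndarray] = []
    rows: list[np.ndarray] = []
    row_start_line = None
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            if rows:
                if len(rows) != GRID:
                    raise TrialParseError(
                        f"frame block has {len(rows)} rows, expected {GRID}",
                        line=row_start_line,
                    )
                grids.append(np.array(rows))
                rows = []
            continue
        parts = line.split()
        try:
            values = np.array([float(p) for p in parts])
        except ValueError:
            raise TrialParseError(f"non-numeric value in row: {line[:60]!r}", line=lineno)
        if len(values) != GRID:
            raise TrialParseError(
                f"row has {len(values)} values, expected {GRID}", line=lineno
            )
        if not np.all(np.isfinite(values)):
            raise TrialParseError("non-finite value in row", line=lineno)
        if np.any(values < 0):
            raise TrialParseError("negative pressure value in row", line=lineno)
        if not rows:
            row_start_line = lineno
        rows.append(values)
    if rows:
        if len(rows) != GRID:
            raise TrialParseError(
                f"frame block has {len(rows)} rows, expected {GRID}", line=row_start_line
            )
        grids.append(np.array(rows))

    if not grids:
        raise EmptyInputError(f"{path}: no frame blocks found")

    required = ("subject_id", "task", "label")
    missing = [k for k in required if k not in meta]
    if missing:
        raise TrialParseError(f"missing metadata fields: {missing}")

    return LabeledTrial(
        frames=frames_from_array(np.stack(grids), sample_rate=sample_rate),
        subject_id=str(meta["subject_id"]),
        task=Task(meta["task"]),
        label=MotionClass(meta["label"]),
        sample_rate=sample_rate,
        affected_side=Side(meta.get("affected_side", "right")),
    )


MANIFEST_COLUMNS = ["path", "subject_id", "task", "label", "affected_side"]


def write_manifest(records: Iterable[dict], path: str | Path) -> Path:
    """Write a dataset manifest CSV (path, subject_id, task, label, side...)."""
    path = Path(path)
    df = pd.DataFrame(list(records))
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"manifest record missing column {col!r}")
    lead = MANIFEST_COLUMNS + [c for c in df.columns if c not in MANIFEST_COLUMNS]
    df[lead].to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    return df


def load_dataset(manifest_path: str | Path) -> list[LabeledTrial]:
    """Read every trial referenced by a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    trials = []
    for rec in df.to_dict("records"):
        p = Path(rec["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        trials.append(read_trial(p))
    return trials


def trials_to_records(trials: Sequence[LabeledTrial], paths: Sequence[Path]) -> list[dict]:
    return [
        {
            "path": str(p),
            "subject_id": t.subject_id,
            "task": t.task.value,
            "label": t.label.value,
            "affected_side": t.affected_side.value,
        }
        for t, p in zip(trials, paths)
    ]
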