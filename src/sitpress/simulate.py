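"""Synthetic seated-pressure trial generator.

Each frame is the sum of four anisotropic Gaussian blobs (two ischial
tuberosities posterior, two thighs anterior) whose centres and
amplitudes are modulated by a task-dependent reach cycle and a
class-dependent compensation signature:

* NC  — baseline blobs plus a small periodic centre-of-pressure excursion;
* TLF — all blobs translated anteriorly, load transferred from the
  ischial to the thigh blobs;
* TR  — load transferred between the left and right blob pairs toward
  the side opposite the affected arm, plus a lateral translation;
* SE  — ipsilateral thigh blob unloaded and frame-to-frame amplitude
  jitter added to the ipsilateral pair.

Every effect scales linearly with ``magnitude``, so magnitude 0 with the
same seed reproduces the NC frames exactly.  Each noise-free frame is
rescaled to a per-frame load target ``weight_scale * (1 + u)``,
``|u| <= load_tolerance``, conserving body weight.  Sensor noise
(multiplicative, additive, dropout) is applied last and clipped at 0.

Randomness is fully determined by a master seed via stable sub-seeding
(subject index, trial index), so datasets are reproducible piecewise.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from sitpress.io import (
    DEFAULT_SAMPLE_RATE,
    GRID,
    CLASS_ORDER,
    LabeledTrial,
    MotionClass,
    Side,
    Task,
    frames_from_array,
)

__all__ = [
    "SubjectProfile",
    "CompensationSpec",
    "NoiseSpec",
    "default_config",
    "load_config",
    "make_subject",
    "mirror_profile",
    "simulate_trial",
    "simulate_dataset",
]

# Blob index convention used throughout this module.
ISCH_L, ISCH_R, THIGH_L, THIGH_R = 0, 1, 2, 3
_SIDE_BLOBS = {Side.LEFT: (ISCH_L, THIGH_L), Side.RIGHT: (ISCH_R, THIGH_R)}


class ConfigurationError(ValueError):
    pass


def default_config() -> dict:
    """The packaged default configuration as a nested dict."""
    text = importlib.resources.files("sitpress").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path=None) -> dict:
    """Load a simulator config file, falling back to packaged defaults.

    User files only need to state overrides; they are merged (one level
    deep per section) onto the defaults.
    """
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


@dataclasses.dataclass(frozen=True)
class SubjectProfile:
    """Per-subject blob geometry and loading; the source of inter-subject
    variability."""

    subject_id: str
    blob_centers: np.ndarray  # (4, 2) [row, col] for [isch_L, isch_R, thigh_L, thigh_R]
    blob_amplitudes: np.ndarray  # (4,) > 0
    blob_widths: np.ndarray  # (4,) column sigma, grid units
    weight_scale: float
    seed: int

    def validate(self) -> list[str]:
        v = []
        c = np.asarray(self.blob_centers)
        if c.shape != (4, 2):
            v.append("blob_centers must be (4, 2)")
            return v
        if np.any(c < 0) or np.any(c > GRID - 1):
            v.append("blob centers outside [0, 31]^2")
        if np.any(np.asarray(self.blob_amplitudes) <= 0):
            v.append("non-positive blob amplitude")
        if np.any(np.asarray(self.blob_widths) <= 0):
            v.append("non-positive blob width")
        if not self.weight_scale > 0:
            v.append("non-positive weight_scale")
        for l, r in ((ISCH_L, ISCH_R), (THIGH_L, THIGH_R)):
            if abs(c[l, 1] + c[r, 1] - (GRID - 1)) > 4:
                v.append(f"blob pair ({l},{r}) not approximately mirror-symmetric")
        return v


@dataclasses.dataclass(frozen=True)
class CompensationSpec:
    comp_class: MotionClass
    magnitude: float = 1.0
    affected_side: Side = Side.RIGHT

    def __post_init__(self):
        if not 0.0 <= self.magnitude <= 1.0:
            raise ConfigurationError(f"magnitude {self.magnitude} outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    multiplicative_sd: float = 0.0
    additive_sd: float = 0.0
    dropout_prob: float = 0.0

    def __post_init__(self):
        if self.multiplicative_sd < 0 or self.additive_sd < 0:
            raise ConfigurationError("noise SDs must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ConfigurationError("dropout_prob must be in [0, 1)")

    @classmethod
    def from_config(cls, cfg: dict) -> "NoiseSpec":
        n = cfg["noise"]
        return cls(
            multiplicative_sd=float(n["multiplicative_sd"]),
            additive_sd=float(n["additive_sd"]),
            dropout_prob=float(n["dropout_prob"]),
        )


def _sub_seed(*entropy: int) -> int:
    """Stable derived seed from a tuple of integers."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0])


def _draw(rng: np.random.Generator, lo_hi) -> float:
    lo, hi = float(lo_hi[0]), float(lo_hi[1])
    if hi < lo:
        raise ConfigurationError(f"infeasible range [{lo}, {hi}]")
    return float(rng.uniform(lo, hi)) if hi > lo else lo


def make_subject(
    population_params: dict, seed: int, subject_id: str | None = None
) -> SubjectProfile:
    """Draw one subject profile; deterministic in (params, seed).

    Left-side blob positions are drawn from the configured ranges and
    right-side partners mirror them about column 15.5, each perturbed by
    a small asymmetry jitter.
    """
    p = population_params
    rng = np.random.default_rng(seed)
    mirror_j = float(p.get("mirror_jitter", 1.0))
    row_j = float(p.get("row_jitter", 0.6))
    asym_j = float(p.get("asymmetry_jitter", 0.05))

    # Amplitudes and widths are drawn per blob *pair* with a small
    # left/right asymmetry factor; fully independent per-blob draws would
    # make baseline load ratios vary across subjects as much as the
    # compensation effects themselves.
    centers = np.zeros((4, 2))
    amps = np.zeros(4)
    widths = np.zeros(4)
    for left, right, row_rng, col_rng, amp_rng, wid_rng in (
        (ISCH_L, ISCH_R, p["ischial_row"], p["ischial_col_left"],
         p["ischial_amplitude"], p["ischial_width"]),
        (THIGH_L, THIGH_R, p["thigh_row"], p["thigh_col_left"],
         p["thigh_amplitude"], p["thigh_width"]),
    ):
        row = _draw(rng, row_rng)
        col_l = _draw(rng, col_rng)
        centers[left] = (row + rng.uniform(-row_j, row_j), col_l)
        centers[right] = (
            row + rng.uniform(-row_j, row_j),
            (GRID - 1) - col_l + rng.uniform(-mirror_j, mirror_j),
        )
        amp = _draw(rng, amp_rng)
        amps[left] = amp * (1.0 + rng.uniform(-asym_j, asym_j))
        amps[right] = amp * (1.0 + rng.uniform(-asym_j, asym_j))
        width = _draw(rng, wid_rng)
        widths[left] = width * (1.0 + rng.uniform(-asym_j, asym_j))
        widths[right] = width * (1.0 + rng.uniform(-asym_j, asym_j))

    # Quantise centres to 1/1024 grid units so that the reflection
    # 31 - c and the offsets j - c are exact in floating point; this is
    # what makes mirrored simulations bit-identical to mirrored frames.
    centers = np.round(centers * 1024.0) / 1024.0

    profile = SubjectProfile(
        subject_id=subject_id if subject_id is not None else f"S{seed}",
        blob_centers=centers,
        blob_amplitudes=amps,
        blob_widths=widths,
        weight_scale=_draw(rng, p["weight_scale"]),
        seed=int(seed),
    )
    violations = profile.validate()
    if violations:
        raise ConfigurationError(
            "population ranges produced invalid profile: " + "; ".join(violations)
        )
    return profile


def mirror_profile(profile: SubjectProfile) -> SubjectProfile:
    """Reflect a profile about the grid's vertical midline (swap L/R blobs)."""
    swap = [ISCH_R, ISCH_L, THIGH_R, THIGH_L]
    centers = profile.blob_centers[swap].copy()
    centers[:, 1] = (GRID - 1) - centers[:, 1]
    return dataclasses.replace(
        profile,
        blob_centers=centers,
        blob_amplitudes=profile.blob_amplitudes[swap].copy(),
        blob_widths=profile.blob_widths[swap].copy(),
    )


def _reach_offsets(task: Task, cfg: dict, t: np.ndarray):
    """Per-frame (row, lateral) centre offsets for the reach cycle.

    The lateral component is expressed in the affected-side frame
    (positive = toward the affected/reaching side); the caller applies
    the side sign in a single multiplication, which keeps the whole
    construction exactly mirror-equivariant.
    """
    rc = cfg["reach_cycle"]
    phase = np.sin(2.0 * np.pi * t / float(rc["period_s"]))
    if task is Task.BACK_AND_FORTH:
        return -float(rc["ap_amplitude_rows"]) * phase, np.zeros_like(phase)
    if task is Task.SIDE_TO_SIDE:
        return np.zeros_like(phase), float(rc["ml_amplitude_cols"]) * phase
    if task is Task.UP_AND_DOWN:
        a = float(rc["mixed_amplitude"])
        return -a * phase, 0.5 * a * phase
    raise ConfigurationError(f"unknown task {task!r}")


def simulate_trial(
    profile: SubjectProfile,
    task: Task,
    spec: CompensationSpec,
    noise: NoiseSpec,
    duration_s: float,
    seed: int,
    config: dict | None = None,
) -> LabeledTrial:
    """Generate one labelled trial at 50 Hz (or the configured rate)."""
    if not duration_s > 0:
        raise ConfigurationError("duration_s must be > 0")
    cfg = config if config is not None else default_config()
    task = Task(task)
    eff = cfg["effects"]
    rate = float(cfg.get("sample_rate", DEFAULT_SAMPLE_RATE))
    tol = float(cfg["load_tolerance"])
    aniso = float(cfg["anisotropy_row"])

    n = int(round(duration_s * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)
    # Fixed draw order, independent of class and side, so that magnitude 0
    # reproduces NC exactly and mirrored runs consume identical streams.
    # Per-frame load factor, correlated within the trial (slow component w
    # plus fast component v) but always inside the +/-tol envelope, so the
    # trial-mean load varies between repetitions of the same subject.
    load_w = rng.uniform(-tol, tol)
    load_v = rng.uniform(-tol, tol, size=n)
    load_u = 0.7 * load_w + 0.3 * load_v
    jitter_z = rng.standard_normal(n)
    # Per-trial posture offset: small whole-body translation so repeated
    # trials of one subject do not sit at a single point in feature space.
    # The lateral component is expressed in the affected-side frame (sign
    # flips with the side) to keep the construction mirror-equivariant.
    posture = cfg.get("trial", {})
    posture_dr = rng.normal(0.0, float(posture.get("posture_sd_rows", 0.0)))
    posture_dc = rng.normal(0.0, float(posture.get("posture_sd_cols", 0.0)))

    m = 0.0 if spec.comp_class is MotionClass.NC else float(spec.magnitude)
    side = spec.affected_side
    side_sign = 1.0 if side is Side.RIGHT else -1.0  # +columns = sitter's right
    ipsi = _SIDE_BLOBS[side]
    contra = _SIDE_BLOBS[side.flipped()]

    centers = profile.blob_centers.astype(float).copy()
    amps = profile.blob_amplitudes.astype(float).copy()
    widths = profile.blob_widths.astype(float)

    cls = spec.comp_class
    lat_static = 0.0  # static lateral shift in the affected-side frame
    if cls is MotionClass.TLF:
        centers[:, 0] -= m * float(eff["ap_shift_max_rows"])  # anterior = row 0
        shift = m * float(eff["tlf_load_shift"])
        amps[[ISCH_L, ISCH_R]] *= 1.0 - shift
        amps[[THIGH_L, THIGH_R]] *= 1.0 + shift
    elif cls is MotionClass.TR:
        lat_static = -m * float(eff["ml_shift_max_cols"])  # toward contralateral
        shift = m * float(eff["tr_load_shift"])
        amps[list(ipsi)] *= 1.0 - shift
        amps[list(contra)] *= 1.0 + shift
    elif cls is MotionClass.SE:
        amps[ipsi[1]] *= 1.0 - m * float(eff["se_unload"])  # ipsilateral thigh
    elif cls is not MotionClass.NC:
        raise ConfigurationError(f"unknown compensation class {cls!r}")

    d_row, lat = _reach_offsets(task, cfg, t)
    d_row = d_row + posture_dr
    # One sign multiplication converts the lateral dynamics to grid
    # columns; negation is exact, so a side flip negates d_col bitwise.
    d_col = side_sign * (lat + (posture_dc + lat_static))

    # Per-frame blob amplitudes; SE adds jitter to the ipsilateral pair.
    amps_t = np.broadcast_to(amps, (n, 4)).copy()
    jitter_factor = np.maximum(1.0 + m * float(eff["se_jitter_sd"]) * jitter_z, 0.1)
    if cls is MotionClass.SE:
        amps_t[:, list(ipsi)] *= jitter_factor[:, None]

    # Separable Gaussian evaluation, (n, 4, 32) row and column profiles.
    # The column argument is (j - centre) - offset: with quantised
    # centres the static part is exact under reflection, and rounding is
    # odd under negation, so mirrored runs produce bit-identical grids.
    axis = np.arange(GRID, dtype=float)
    row_off = (axis[None, None, :] - centers[:, 0][None, :, None]) - d_row[:, None, None]
    col_off = (axis[None, None, :] - centers[:, 1][None, :, None]) - d_col[:, None, None]
    sig_r = (widths * aniso)[None, :, None]
    sig_c = widths[None, :, None]
    row_g = np.exp(-(row_off**2) / (2.0 * sig_r**2))
    col_g = np.exp(-(col_off**2) / (2.0 * sig_c**2))
    blob = amps_t[:, :, None, None] * row_g[:, :, :, None] * col_g[:, :, None, :]
    # Pairwise left+right combination is invariant under the pair swap.
    frames = (blob[:, ISCH_L] + blob[:, ISCH_R]) + (blob[:, THIGH_L] + blob[:, THIGH_R])

    # Conserve body weight: rescale each frame to its load target.  Frame
    # totals are reduced with symmetric column pairing (c, 31-c) so the
    # reduction is invariant under column reversal.
    col_sums = frames.sum(axis=1)
    totals = (col_sums[:, : GRID // 2] + col_sums[:, : GRID // 2 - 1 : -1]).sum(axis=1)
    target = profile.weight_scale * (1.0 + load_u)
    frames = frames * (target / totals)[:, None, None]

    if noise.multiplicative_sd > 0:
        frames = frames * (
            1.0 + rng.normal(0.0, noise.multiplicative_sd, size=frames.shape)
        )
    if noise.additive_sd > 0:
        frames = frames + rng.normal(0.0, noise.additive_sd, size=frames.shape)
    np.clip(frames, 0.0, None, out=frames)
    if noise.dropout_prob > 0:
        frames = frames * (rng.random(size=frames.shape) >= noise.dropout_prob)

    return LabeledTrial(
        frames=frames_from_array(frames, sample_rate=rate),
        subject_id=profile.subject_id,
        task=task,
        label=spec.comp_class,
        sample_rate=rate,
        affected_side=side,
    )


def simulate_dataset(
    n_subjects: int,
    reps_per_cell: int,
    config: dict | None = None,
    seed: int = 0,
) -> tuple[list[LabeledTrial], pd.DataFrame]:
    """Simulate a balanced cohort: subjects x 3 tasks x 4 classes x reps.

    Returns the trials plus a manifest dataframe (one row per trial, in
    generation order).  Fully reproducible from ``seed``; per-trial
    compensation magnitudes are drawn from the configured range for
    non-NC classes.  Affected side alternates across subjects.
    """
    if n_subjects < 2:
        raise ConfigurationError("n_subjects must be >= 2")
    if reps_per_cell < 1:
        raise ConfigurationError("reps_per_cell must be >= 1")
    cfg = config if config is not None else default_config()
    noise = NoiseSpec.from_config(cfg)
    duration = float(cfg["trial"]["duration_s"])
    mag_lo, mag_hi = (float(x) for x in cfg["trial"]["magnitude_range"])

    trials: list[LabeledTrial] = []
    records: list[dict] = []
    for si in range(n_subjects):
        profile = make_subject(
            cfg["population"], seed=_sub_seed(seed, 1, si), subject_id=f"S{si + 1:02d}"
        )
        side = Side.LEFT if si % 2 else Side.RIGHT
        trial_index = 0
        for task in Task:
            for cls in CLASS_ORDER:
                for _ in range(reps_per_cell):
                    trial_seed = _sub_seed(seed, 2, si, trial_index)
                    mag_rng = np.random.default_rng(_sub_seed(seed, 3, si, trial_index))
                    magnitude = (
                        0.0
                        if cls is MotionClass.NC
                        else float(mag_rng.uniform(mag_lo, mag_hi))
                    )
                    spec = CompensationSpec(
                        comp_class=cls, magnitude=magnitude, affected_side=side
                    )
                    trial = simulate_trial(
                        profile, task, spec, noise, duration, trial_seed, config=cfg
                    )
                    trials.append(trial)
                    records.append(
                        {
                            "path": f"{profile.subject_id}_{task.value}_{cls.value}_{trial_index:03d}.txt",
                            "subject_id": profile.subject_id,
                            "task": task.value,
                            "label": cls.value,
                            "affected_side": side.value,
                            "magnitude": magnitude,
                            "seed": trial_seed,
                        }
                    )
                    trial_index += 1
    return trials, pd.DataFrame(records)
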