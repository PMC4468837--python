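"""Kinematic trial reduction: velocity, movement detection, movement time.

A reach is segmented with a velocity-threshold rule: movement start is the
first sample of the earliest run of ``run_length`` consecutive samples with
speed strictly above ``speed_threshold`` (30 mm/s, 5 samples by default), and
movement end is the first sample of the earliest subsequent run strictly below
the threshold.  Everything after the detected end is ignored, so delayed
corrections or the return toward the home position never extend a trial.  All
dependent measures are taken on the primary (first) movement axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MEASURES_COLUMNS = [
    "participant", "session", "amplitude_mm", "width_mm", "trial",
    "start_idx", "end_idx", "mt_ms", "endpoint_mm", "valid", "reason",
]


class DetectionError(ValueError):
    """Movement onset/offset could not be found.

    ``reason`` is ``"no_onset"`` (no qualifying above-threshold run) or
    ``"no_offset"`` (onset found, but speed never settled below threshold).
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class ReductionConfig:
    """Parameters of the velocity-threshold segmentation.

    ``onset_convention`` selects which sample of the qualifying run is
    reported: ``"run_start"`` (default; keeps onset and offset symmetric) or
    ``"run_end"`` (the fifth-sample reading).
    """

    speed_threshold: float = 30.0      # mm/s
    run_length: int = 5                # consecutive samples
    sample_rate: float = 200.0         # Hz
    speed_basis: str = "resultant"     # or "primary"
    differentiation: str = "central"   # or "forward"
    onset_convention: str = "run_start"

    def __post_init__(self) -> None:
        if self.speed_threshold <= 0:
            raise ValueError("speed_threshold must be > 0")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.speed_basis not in ("resultant", "primary"):
            raise ValueError("speed_basis must be 'resultant' or 'primary'")
        if self.differentiation not in ("central", "forward"):
            raise ValueError("differentiation must be 'central' or 'forward'")
        if self.onset_convention not in ("run_start", "run_end"):
            raise ValueError("onset_convention must be 'run_start' or 'run_end'")


@dataclass
class TrialMeasures:
    """Reduced trial: detected indices, MT and primary-axis endpoint."""

    start_index: int | None
    end_index: int | None
    movement_time_ms: float
    endpoint_primary_mm: float
    valid: bool
    invalid_reason: str = ""


def differentiate(position: np.ndarray, config: ReductionConfig) -> np.ndarray:
    """First-order differentiation of displacement into speed (mm/s).

    ``position`` is ``(n,)`` or ``(n, 3)`` with the primary axis first.  The
    output has the same length as the input: central differences use one-sided
    stencils at the edges, forward differences repeat the last interior value.
    Resultant speed is the Euclidean norm of the per-axis velocities; the
    primary basis returns ``|dx/dt|``.
    """
    pos = np.asarray(position, dtype=float)
    if pos.ndim == 1:
        pos = pos[:, None]
    if pos.ndim != 2 or pos.shape[0] < 3:
        raise ValueError("position requires >= 3 uniformly sampled rows")
    if not np.all(np.isfinite(pos)):
        raise ValueError("position contains non-finite values")
    dt = 1.0 / config.sample_rate
    if config.differentiation == "central":
        vel = np.gradient(pos, dt, axis=0)
    else:
        vel = np.empty_like(pos)
        vel[:-1] = np.diff(pos, axis=0) / dt
        vel[-1] = vel[-2]
    if config.speed_basis == "primary":
        return np.abs(vel[:, 0])
    return np.linalg.norm(vel, axis=1)


def _first_run(mask: np.ndarray, length: int, start: int = 0) -> int | None:
    """Index of the first run of ``length`` consecutive True at >= start."""
    m = np.asarray(mask[start:], dtype=bool)
    if m.size < length:
        return None
    if length == 1:
        hits = np.flatnonzero(m)
    else:
        counts = np.convolve(m.astype(np.int64), np.ones(length, dtype=np.int64),
                             mode="valid")
        hits = np.flatnonzero(counts == length)
    if hits.size == 0:
        return None
    return start + int(hits[0])


def detect_movement(speed: np.ndarray, config: ReductionConfig) -> tuple[int, int]:
    """Locate movement start and end with the consecutive-run threshold rule.

    Ties at the threshold (speed exactly equal) break the run in both
    directions: onset requires strictly-above samples, offset strictly-below.

    Raises
    ------
    DetectionError
        With ``reason="no_onset"`` or ``reason="no_offset"``.
    """
    speed = np.asarray(speed, dtype=float)
    if not np.all(np.isfinite(speed)):
        raise ValueError("speed contains non-finite values")
    L = config.run_length
    above = speed > config.speed_threshold
    i = _first_run(above, L)
    if i is None:
        raise DetectionError("no_onset")
    start = i if config.onset_convention == "run_start" else i + L - 1
    below = speed < config.speed_threshold
    j = _first_run(below, L, start + 1)
    if j is None:
        raise DetectionError("no_offset")
    end = j if config.onset_convention == "run_start" else j + L - 1
    return start, end


def reduce_trial(trajectory, config: ReductionConfig | None = None) -> TrialMeasures:
    """Reduce one trial to start/end indices, MT and the primary endpoint.

    ``trajectory`` is a :class:`~fittslab.synthetic_data.TrialTrajectory` or
    any object with ``position`` (n x 3) -- the per-sample positions in mm.
    Invalid trials (no onset or no offset) are flagged, never imputed.
    """
    config = config or ReductionConfig()
    pos = np.asarray(trajectory.position, dtype=float)
    speed = differentiate(pos, config)
    try:
        start, end = detect_movement(speed, config)
    except DetectionError as exc:
        return TrialMeasures(None, None, np.nan, np.nan, False, exc.reason)
    mt_ms = (end - start) / config.sample_rate * 1000.0
    endpoint = pos[end, 0] if pos.ndim == 2 else pos[end]
    return TrialMeasures(start, end, mt_ms, float(endpoint), True)


def reduce_frame(trajectories: pd.DataFrame,
                 config: ReductionConfig | None = None) -> pd.DataFrame:
    """Reduce a long-format trajectory table to one row per trial.

    Expects the columns written by the synthetic generator (accepted from any
    source): ``participant, session, amplitude_mm, width_mm, trial, t_s,
    x_mm, y_mm, z_mm``.  Sampling must be uniform within each trial at the
    configured rate.
    """
    config = config or ReductionConfig()
    keys = ["participant", "session", "amplitude_mm", "width_mm", "trial"]
    missing = [c for c in keys + ["t_s", "x_mm", "y_mm", "z_mm"]
               if c not in trajectories.columns]
    if missing:
        raise ValueError(f"trajectory table lacks columns: {missing}")
    dt = 1.0 / config.sample_rate
    rows = []
    for key, grp in trajectories.groupby(keys, sort=False):
        t = grp["t_s"].to_numpy()
        if t.size >= 2 and not np.allclose(np.diff(t), dt, rtol=1e-6, atol=1e-9):
            raise ValueError(f"non-uniform sampling in trial {key}")
        pos = grp[["x_mm", "y_mm", "z_mm"]].to_numpy()
        m = reduce_trial(_PositionOnly(pos), config)
        rows.append(dict(zip(keys, key)) | {
            "start_idx": m.start_index, "end_idx": m.end_index,
            "mt_ms": m.movement_time_ms, "endpoint_mm": m.endpoint_primary_mm,
            "valid": m.valid, "reason": m.invalid_reason,
        })
    out = pd.DataFrame(rows, columns=MEASURES_COLUMNS)
    return out


def invalid_counts(measures: pd.DataFrame) -> pd.DataFrame:
    """Dropped-trial counts per condition (the exclusion rule's audit trail)."""
    bad = measures[~measures["valid"]]
    if bad.empty:
        return pd.DataFrame(columns=["participant", "session", "amplitude_mm",
                                     "width_mm", "reason", "n"])
    return (bad.groupby(["participant", "session", "amplitude_mm", "width_mm",
                         "reason"], sort=False)
               .size().rename("n").reset_index())


class _PositionOnly:
    """Minimal trajectory wrapper for :func:`reduce_trial`."""

    def __init__(self, position: np.ndarray):
        self.position = position
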