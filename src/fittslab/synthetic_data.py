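"""Synthetic reaching-trajectory generator.

Emulates a discrete goal-directed pointing study: a 4 (amplitude) x 4 (width)
target grid, two sessions (terminal feedback present / absent), 10 trials per
condition, and ~19 participants split into accuracy-prone and speed-prone
strategy groups.  Mean movement time follows Welford's two-slope form

    MT = a + beta_amp * log2(A) + beta_width * log2(1/W)

so that amplitude- and width-based difficulty manipulations can carry distinct
slopes (the phenomenon the downstream slope decomposition is built to detect).
Each trial's fingertip displacement is a minimum-jerk quintic from the home
position to a noisy endpoint, sampled at the design rate with quiescent
padding on both sides.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

ACCURACY_PRONE = "accuracy-prone"
SPEED_PRONE = "speed-prone"
TF_ABSENT = "TF-Absent"
TF_PRESENT = "TF-Present"

#: Smallest admissible planted movement duration (ms); the truncation point of
#: the Gaussian trial-duration noise.  Avoids degenerate two-sample reaches.
MIN_DURATION_MS = 100.0

TRAJECTORY_COLUMNS = [
    "participant", "session", "amplitude_mm", "width_mm", "trial",
    "t_s", "x_mm", "y_mm", "z_mm",
]


class SimulationError(RuntimeError):
    """Raised when a trial cannot be generated under the given parameters."""


@dataclass(frozen=True)
class StudyDesign:
    """The factorial layout of the reaching study.

    Defaults reproduce the study conditions: amplitudes 155/190/266/380 mm,
    widths 20/30/40/50 mm, 10 trials per condition, two feedback sessions,
    12 accuracy-prone + 7 speed-prone participants, 200 Hz sampling.
    """

    amplitudes: tuple[float, ...] = (155.0, 190.0, 266.0, 380.0)
    widths: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0)
    trials_per_condition: int = 10
    sessions: tuple[str, ...] = (TF_ABSENT, TF_PRESENT)
    n_accuracy: int = 12
    n_speed: int = 7
    sample_rate: float = 200.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in self.amplitudes))
        object.__setattr__(self, "widths", tuple(float(w) for w in self.widths))
        object.__setattr__(self, "sessions", tuple(self.sessions))
        for name in ("amplitudes", "widths"):
            vals = getattr(self, name)
            if len(vals) == 0 or any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be strictly positive")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.n_accuracy < 0 or self.n_speed < 0:
            raise ValueError("n_accuracy and n_speed must be non-negative")
        if len(self.sessions) < 1:
            raise ValueError("sessions must name at least one session")

    @property
    def conditions(self) -> list[tuple[float, float]]:
        """All (amplitude, width) combinations, amplitude-major order."""
        return [(a, w) for a in self.amplitudes for w in self.widths]

    @property
    def n_conditions(self) -> int:
        return len(self.amplitudes) * len(self.widths)

    @property
    def trials_per_session(self) -> int:
        return self.n_conditions * self.trials_per_condition

    @property
    def n_participants(self) -> int:
        return self.n_accuracy + self.n_speed

    def participant_ids(self) -> list[str]:
        return [f"P{i + 1:02d}" for i in range(self.n_participants)]

    def strategy_of(self, participant_index: int) -> str:
        return ACCURACY_PRONE if participant_index < self.n_accuracy else SPEED_PRONE


def make_design(**overrides) -> StudyDesign:
    """Build a :class:`StudyDesign`, overriding any subset of its fields."""
    try:
        return StudyDesign(**overrides)
    except TypeError as exc:  # unknown field name
        raise ValueError(str(exc)) from exc


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one strategy group.

    ``intercept_ms`` plus the two Welford slopes define the noise-free mean
    movement duration; ``tf_effect_ms`` shifts it when terminal feedback is
    present (negative = faster).  Endpoint scatter on the primary axis uses
    ``width_utilization * W / 2`` for accuracy-prone performers and
    ``noise_base_mm + noise_amp_gain * A`` for speed-prone performers, so only
    the speed-prone group's endpoint SD grows with movement amplitude.
    """

    intercept_ms: float = -114.0
    beta_amp_ms_per_bit: float = 106.0
    beta_width_ms_per_bit: float = 48.0
    tf_effect_ms: float = -23.0
    mt_trial_sd_ms: float = 40.0
    participant_sd_ms: float = 85.0
    endpoint_bias_mm: float = 0.3
    noise_base_mm: float = 6.0
    noise_amp_gain: float = 0.008
    width_utilization: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mt_trial_sd_ms", "participant_sd_ms", "noise_base_mm",
                     "noise_amp_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.width_utilization <= 1.0):
            raise ValueError("width_utilization must be in (0, 1]")

    def replace(self, **changes) -> "SimParams":
        return dataclasses.replace(self, **changes)


def default_accuracy_params() -> SimParams:
    """Default parameters for the accuracy-prone group."""
    return SimParams()


def default_speed_params() -> SimParams:
    """Default parameters for the speed-prone group.

    Speed-prone performers are faster overall (lower intercept) and carry
    amplitude-scaled endpoint noise large enough to exceed the 5 % endpoint
    error criterion used downstream to segregate strategies.
    """
    return SimParams(intercept_ms=-223.0, mt_trial_sd_ms=30.0,
                     participant_sd_ms=45.0)


@dataclass
class TrialTrajectory:
    """One sampled reach plus its design condition and planted truth."""

    participant_id: str
    session: str
    amplitude: float
    width: float
    trial_index: int
    time: np.ndarray          # seconds, uniform at the design sample rate
    position: np.ndarray      # (n, 3) mm, primary axis first
    planted_duration_ms: float
    planted_endpoint_mm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant": self.participant_id,
            "session": self.session,
            "amplitude_mm": self.amplitude,
            "width_mm": self.width,
            "trial": self.trial_index,
            "t_s": self.time,
            "x_mm": self.position[:, 0],
            "y_mm": self.position[:, 1],
            "z_mm": self.position[:, 2],
        })


# ---------------------------------------------------------------------------
# Minimum-jerk primitives


def minimum_jerk_position(tau):
    """Normalized quintic displacement s(tau) = 10 t^3 - 15 t^4 + 6 t^5."""
    tau = np.asarray(tau, dtype=float)
    return tau**3 * (10.0 + tau * (-15.0 + 6.0 * tau))


def minimum_jerk_speed(tau, distance: float = 1.0, duration: float = 1.0):
    """Speed of the quintic profile: (D/T) * (30 t^2 - 60 t^3 + 30 t^4).

    Peaks at tau = 0.5 with value 1.875 * D / T.
    """
    tau = np.asarray(tau, dtype=float)
    return (distance / duration) * 30.0 * tau**2 * (1.0 - tau) ** 2


def mean_duration_ms(params: SimParams, amplitude: float, width: float,
                     tf_present: bool = False) -> float:
    """Noise-free planted movement duration under the Welford two-slope form."""
    mt = (params.intercept_ms
          + params.beta_amp_ms_per_bit * math.log2(amplitude)
          + params.beta_width_ms_per_bit * math.log2(1.0 / width))
    if tf_present:
        mt += params.tf_effect_ms
    return mt


def endpoint_sd_mm(params: SimParams, strategy: str, amplitude: float,
                   width: float) -> float:
    """Primary-axis endpoint SD for a strategy group at one condition."""
    if strategy == ACCURACY_PRONE:
        return params.width_utilization * width / 2.0
    if strategy == SPEED_PRONE:
        return params.noise_base_mm + params.noise_amp_gain * amplitude
    raise ValueError(f"unknown strategy label: {strategy!r}")


def _draw_trial(params: SimParams, strategy: str, amplitude: float,
                width: float, tf_present: bool, participant_offset_ms: float,
                rng: np.random.Generator,
                max_retries: int = 100) -> tuple[float, float, float, float]:
    """Draw (duration_ms, endpoint_mm, y_end_mm, z_end_mm) for one trial."""
    mean_mt = mean_duration_ms(params, amplitude, width, tf_present)
    mean_mt += participant_offset_ms
    duration = -np.inf
    for _ in range(max_retries):
        duration = mean_mt + params.mt_trial_sd_ms * rng.standard_normal()
        if duration >= MIN_DURATION_MS:
            break
    else:
        raise SimulationError(
            f"could not draw a duration >= {MIN_DURATION_MS} ms "
            f"(mean {mean_mt:.1f} ms) in {max_retries} tries")
    sigma = endpoint_sd_mm(params, strategy, amplitude, width)
    endpoint = amplitude + params.endpoint_bias_mm + sigma * rng.standard_normal()
    # Orthogonal axes carry small independent endpoint jitter (SD 2 mm); all
    # reduced measures live on the primary axis.
    y_end, z_end = 2.0 * rng.standard_normal(2)
    return duration, endpoint, y_end, z_end


def _render_trajectory(duration_ms: float, endpoint: float, y_end: float,
                       z_end: float, sample_rate: float, pad_pre_s: float,
                       pad_post_s: float,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample the continuous minimum-jerk reach onto the acquisition grid."""
    dt = 1.0 / sample_rate
    n_pre = max(int(round(pad_pre_s * sample_rate)), 1)
    n_post = max(int(round(pad_post_s * sample_rate)), 1)
    mt_s = duration_ms / 1000.0
    n_move = int(math.floor(mt_s * sample_rate))  # samples with t <= MT
    tau = np.arange(1, n_move + 1) * dt / mt_s
    tau = np.clip(tau, 0.0, 1.0)
    shape = minimum_jerk_position(tau)
    x = np.concatenate([np.zeros(n_pre), endpoint * shape,
                        np.full(n_post, endpoint)])
    y = np.concatenate([np.zeros(n_pre), y_end * shape, np.full(n_post, y_end)])
    z = np.concatenate([np.zeros(n_pre), z_end * shape, np.full(n_post, z_end)])
    n = x.size
    # Sub-threshold measurement jitter in the quiescent padding only: the
    # bound 6/fs mm keeps the central-difference resultant speed below
    # sqrt(3) * 2 * (6/fs) / (2/fs) ~ 10.4 mm/s, under half the 30 mm/s
    # detection threshold, so padding can never trigger movement detection.
    jitter_amp = 6.0 / sample_rate
    pad_idx = np.concatenate([np.arange(n_pre), np.arange(n - n_post, n)])
    jitter = rng.uniform(-jitter_amp, jitter_amp, size=(pad_idx.size, 3))
    pos = np.column_stack([x, y, z])
    pos[pad_idx] += jitter
    time = np.arange(n) * dt
    return time, pos


def simulate_trial(design: StudyDesign, params: SimParams,
                   condition: tuple[float, float], strategy: str,
                   rng: np.random.Generator, *, session: str = TF_ABSENT,
                   participant_id: str = "P01", trial_index: int = 0,
                   participant_offset_ms: float = 0.0,
                   pad_pre_s: float = 0.2,
                   pad_post_s: float = 0.2) -> TrialTrajectory:
    """Simulate one reach of the study.

    Parameters
    ----------
    condition
        ``(amplitude, width)`` pair; must belong to the design grid.
    strategy
        ``"accuracy-prone"`` or ``"speed-prone"``; selects the endpoint-noise
        model.
    rng
        Source of randomness for this trial (one substream per trial in
        :func:`simulate_study`).
    """
    amplitude, width = condition
    if (amplitude, width) not in design.conditions:
        raise ValueError(f"condition {condition} not in the design grid")
    if session not in design.sessions:
        raise ValueError(f"session {session!r} not in the design")
    tf_present = session == TF_PRESENT
    duration, endpoint, y_end, z_end = _draw_trial(
        params, strategy, amplitude, width, tf_present,
        participant_offset_ms, rng)
    time, pos = _render_trajectory(duration, endpoint, y_end, z_end,
                                   design.sample_rate, pad_pre_s, pad_post_s,
                                   rng)
    return TrialTrajectory(participant_id, session, amplitude, width,
                           trial_index, time, pos, duration, endpoint)


def _trial_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_study(design: StudyDesign | None = None,
                   params_accuracy: SimParams | None = None,
                   params_speed: SimParams | None = None, *,
                   seed: int | None = None, trajectories: bool = True,
                   pad_pre_s: float = 0.2, pad_post_s: float = 0.2,
                   ) -> tuple[pd.DataFrame | None, dict[str, pd.DataFrame]]:
    """Simulate the full study: every trial of every participant and session.

    Returns
    -------
    trajectories : DataFrame or None
        Long-format trajectory table (one row per sample) with columns
        ``participant, session, amplitude_mm, width_mm, trial, t_s, x_mm,
        y_mm, z_mm``; ``None`` when ``trajectories=False`` (truth-only fast
        path -- the same random substreams are consumed for the planted
        values, so the truth table is identical either way).
    truth : dict of DataFrame
        ``"participants"``: strategy labels, planted betas and intercept
        offsets; ``"trials"``: planted duration and endpoint per trial.

    Deterministic given ``seed``: every participant/session/condition/trial
    owns a seed substream, so regenerating any subset reproduces it exactly.
    """
    design = design or StudyDesign()
    params_accuracy = params_accuracy or default_accuracy_params()
    params_speed = params_speed or default_speed_params()
    if seed is None:
        seed = params_accuracy.seed
    if design.n_accuracy + design.n_speed < 1:
        raise ValueError("at least one participant is required")

    part_rows = []
    trial_rows = []
    frames = []
    for p_idx, pid in enumerate(design.participant_ids()):
        strategy = design.strategy_of(p_idx)
        params = params_accuracy if strategy == ACCURACY_PRONE else params_speed
        offset = (params.participant_sd_ms
                  * _trial_rng(seed, 1, p_idx).standard_normal())
        part_rows.append({
            "participant": pid, "strategy": strategy,
            "intercept_offset_ms": offset,
            "beta_amp_ms_per_bit": params.beta_amp_ms_per_bit,
            "beta_width_ms_per_bit": params.beta_width_ms_per_bit,
        })
        for s_idx, session in enumerate(design.sessions):
            tf_present = session == TF_PRESENT
            for c_idx, (a, w) in enumerate(design.conditions):
                for t in range(design.trials_per_condition):
                    rng = _trial_rng(seed, 2, p_idx, s_idx, c_idx, t)
                    duration, endpoint, y_end, z_end = _draw_trial(
                        params, strategy, a, w, tf_present, offset, rng)
                    trial_rows.append({
                        "participant": pid, "session": session,
                        "amplitude_mm": a, "width_mm": w, "trial": t,
                        "planted_duration_ms": duration,
                        "planted_endpoint_mm": endpoint,
                    })
                    if trajectories:
                        time, pos = _render_trajectory(
                            duration, endpoint, y_end, z_end,
                            design.sample_rate, pad_pre_s, pad_post_s, rng)
                        frames.append((pid, session, a, w, t, time, pos))

    truth = {"participants": pd.DataFrame(part_rows),
             "trials": pd.DataFrame(trial_rows)}
    if not trajectories:
        return None, truth

    n_total = sum(time.size for *_, time, _pos in frames)
    out = {
        "participant": np.empty(n_total, dtype=object),
        "session": np.empty(n_total, dtype=object),
        "amplitude_mm": np.empty(n_total),
        "width_mm": np.empty(n_total),
        "trial": np.empty(n_total, dtype=np.int64),
        "t_s": np.empty(n_total),
        "x_mm": np.empty(n_total),
        "y_mm": np.empty(n_total),
        "z_mm": np.empty(n_total),
    }
    i = 0
    for pid, session, a, w, t, time, pos in frames:
        j = i + time.size
        out["participant"][i:j] = pid
        out["session"][i:j] = session
        out["amplitude_mm"][i:j] = a
        out["width_mm"][i:j] = w
        out["trial"][i:j] = t
        out["t_s"][i:j] = time
        out["x_mm"][i:j] = pos[:, 0]
        out["y_mm"][i:j] = pos[:, 1]
        out["z_mm"][i:j] = pos[:, 2]
        i = j
    return pd.DataFrame(out, columns=TRAJECTORY_COLUMNS), truth
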