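"""Synthetic session generator with known ground truth.

The clinical data behind this pipeline cannot be redistributed, so every
downstream stage is exercised against simulated sessions that reproduce the
statistical structure the method assumes:

* a bilaterally symmetric neutral face of 21 POI;
* per exercise, a rest - bumps - rest activation profile (raised-cosine
  bumps, one per repetition, 2-4 repetitions);
* paresis modelled as an *attenuation* of the affected half's motion,
  a reduced global range of motion, and a slower, back-loaded execution
  (monotone power distortion of the time axis) - all worsening with the
  adjusted House-Brackmann grade;
* variable per-session sampling rate and additive i.i.d. Gaussian sensor
  noise on every coordinate.

Synkinesis (involuntary co-contraction) is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core_io import (
    Exercise,
    ExerciseRecording,
    FacekinError,
    HOMOLOGOUS_PAIRS,
    INDICATOR_EXERCISES,
    LEFT_POINTS,
    N_POI,
    RIGHT_POINTS,
    Session,
)

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "neutral_face",
    "simulate_session",
    "simulate_cohort",
    "DEFAULT_ATTENUATION",
    "DEFAULT_INTENSITY",
    "DEFAULT_SPEED_GAMMA",
    "DEFAULT_NOISE_SD",
    "DEFAULT_SAMPLING_HZ",
    "DEFAULT_CLASS_MIX",
    "activation_profile",
    "bump_layout",
    "EXERCISE_DISPLACEMENTS",
]

# ---------------------------------------------------------------------------
# Grade-conditional defaults.
#
# Attenuation multiplies the affected side's motion (1 = symmetric, 0 =
# plegic); intensity_scale multiplies everyone's range of motion; the speed
# exponent gamma distorts normalized time as u -> u**gamma evaluated at
# real-time fraction, so gamma < 1 front-loads the exercise (healthy, brisk
# onset) and gamma > 1 delays it (slow, effortful onset).
# ---------------------------------------------------------------------------

DEFAULT_ATTENUATION = {1: 1.0, 2: 0.8, 3: 0.5, 6: 0.05}
# The intensity decline is deliberately milder than the attenuation decline:
# the asymmetric motion amplitude scales as intensity * (1 - attenuation),
# so a steep global intensity drop for bad grades would cancel the asymmetry
# contrast between grades 3 and 6 that the symmetry indicators rely on.
DEFAULT_INTENSITY = {1: 1.0, 2: 0.95, 3: 0.85, 6: 0.7}
DEFAULT_SPEED_GAMMA = {1: 0.7, 2: 0.85, 3: 1.0, 6: 1.3}
DEFAULT_NOISE_SD = 0.0005  # meters (0.5 mm), per coordinate
DEFAULT_SAMPLING_HZ = (8.0, 30.0)
# observed cohort class proportions for adjusted grades (1, 2, 3, 6)
DEFAULT_CLASS_MIX = (58 / 122, 21 / 122, 23 / 122, 20 / 122)

ACTIVATION_THRESHOLD = 0.15  # landmark definition: activation crosses this

# timeline layout (fractions of the nominal session duration)
_LEAD_REST = 0.15
_TRAIL_REST = 0.15
_GAP_OVER_WIDTH = 0.3  # inter-bump gap as a fraction of bump width


@dataclass
class SimulationParams:
    """Ground-truth parameters for one simulated session."""

    grade: int = 1  # adjusted HB level in {1, 2, 3, 6}
    affected_side: Literal["left", "right"] = "left"
    asymmetry_attenuation: float = 1.0
    intensity_scale: float = 1.0
    speed_profile: float = 1.0  # gamma exponent of the time distortion
    n_repetitions: int = 3
    sampling_hz_range: tuple[float, float] = DEFAULT_SAMPLING_HZ
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 6):
            raise FacekinError(f"grade {self.grade} not an adjusted level")
        if not 0.0 <= self.asymmetry_attenuation <= 1.0:
            raise FacekinError("asymmetry_attenuation must be in [0, 1]")
        if self.intensity_scale <= 0:
            raise FacekinError("intensity_scale must be positive")
        if self.speed_profile <= 0:
            raise FacekinError("speed_profile must be positive")
        if self.n_repetitions not in (2, 3, 4):
            raise FacekinError("n_repetitions must be 2, 3 or 4")
        if self.noise_sd < 0:
            raise FacekinError("noise_sd must be nonnegative")
        lo, hi = self.sampling_hz_range
        if not 0 < lo <= hi:
            raise FacekinError("invalid sampling_hz_range")
        if self.affected_side not in ("left", "right"):
            raise FacekinError("affected_side must be 'left' or 'right'")


@dataclass
class GroundTruth:
    """Oracle information for one simulated session."""

    params: SimulationParams
    sampling_hz: float
    duration: float  # seconds, indicator-bearing exercises
    # per indicator-bearing exercise: 2*k strictly increasing landmark times
    # (seconds) at which the activation crosses ACTIVATION_THRESHOLD
    landmark_times: dict[Exercise, np.ndarray] = field(default_factory=dict)
    # nominal (pre-distortion) bump starts and width on [0, 1]
    bump_starts: np.ndarray = field(default_factory=lambda: np.empty(0))
    bump_width: float = 0.0


# ---------------------------------------------------------------------------
# Neutral face geometry
# ---------------------------------------------------------------------------

# patient's left = +x; y up; z out of the face plane (toward camera)
_NEUTRAL_LEFT_AND_MID = {
    0: (0.030, 0.022, 0.008),   # left eye, bottom
    1: (0.030, 0.038, 0.008),   # left eye, top
    2: (0.014, 0.030, 0.005),   # left eye, inner corner
    3: (0.046, 0.030, 0.005),   # left eye, outer corner
    4: (0.018, 0.055, 0.010),   # left eyebrow, inner
    5: (0.036, 0.060, 0.010),   # left eyebrow, centre
    12: (0.000, 0.000, 0.030),  # nose tip
    13: (0.000, -0.046, 0.012),  # lower lip, centre-bottom
    14: (0.025, -0.035, 0.010),  # mouth, left corner
    16: (0.000, -0.024, 0.014),  # upper lip, centre-top
    17: (0.000, -0.070, 0.010),  # chin
    18: (0.000, 0.090, 0.005),   # forehead
    19: (0.052, -0.010, 0.000),  # left cheek
}


def neutral_face() -> np.ndarray:
    """Bilaterally symmetric 21 x 3 resting-face template (meters).

    Left/right homologue pairs mirror each other about the midsagittal
    plane x = 0; midline points sit on it.
    """
    face = np.zeros((N_POI, 3))
    for idx, xyz in _NEUTRAL_LEFT_AND_MID.items():
        face[idx] = xyz
    for left, right in HOMOLOGOUS_PAIRS:
        face[right] = face[left] * np.array([-1.0, 1.0, 1.0])
    return face


# ---------------------------------------------------------------------------
# Exercise motion model: unit-activation displacement per POI (meters)
# ---------------------------------------------------------------------------

def _mirror(d: dict[int, tuple[float, float, float]]) -> dict[int, np.ndarray]:
    """Complete a left-side/midline displacement map with mirrored right side."""
    left_to_right = dict(HOMOLOGOUS_PAIRS)
    out = {i: np.asarray(v, dtype=float) for i, v in d.items()}
    for left, vec in list(out.items()):
        if left in left_to_right:
            out[left_to_right[left]] = vec * np.array([-1.0, 1.0, 1.0])
    return out


EXERCISE_DISPLACEMENTS: dict[Exercise, dict[int, np.ndarray]] = {
    # eyebrows up
    Exercise.RAISING: _mirror({4: (0.0, 0.012, 0.0), 5: (0.0, 0.010, 0.0)}),
    # inner eyebrows down and inward
    Exercise.FROWNING: _mirror({4: (-0.004, -0.008, 0.0), 5: (0.0, -0.004, 0.0)}),
    # mouth corners out and up
    Exercise.SMILING: _mirror({14: (0.010, 0.008, 0.0), 19: (0.004, 0.004, 0.0)}),
    # mouth opens: corners out, lips apart
    Exercise.BARING: _mirror({
        14: (0.008, 0.004, 0.0),
        13: (0.0, -0.006, 0.0),
        16: (0.0, 0.006, 0.0),
    }),
    # mouth corners pulled inward, lips protrude
    Exercise.PURSING: _mirror({14: (-0.012, 0.0, 0.004)}),
}


# ---------------------------------------------------------------------------
# Activation timeline
# ---------------------------------------------------------------------------

def bump_layout(k: int) -> tuple[np.ndarray, float]:
    """Nominal bump start fractions and width on [0, 1] for k repetitions."""
    active = 1.0 - _LEAD_REST - _TRAIL_REST
    width = active / (k + _GAP_OVER_WIDTH * (k - 1))
    gap = _GAP_OVER_WIDTH * width
    starts = _LEAD_REST + np.arange(k) * (width + gap)
    return starts, width


def activation_profile(u: np.ndarray, k: int) -> np.ndarray:
    """Raised-cosine activation (0..1) at nominal time fractions ``u``."""
    starts, width = bump_layout(k)
    u = np.asarray(u, dtype=float)
    a = np.zeros_like(u)
    for s in starts:
        inside = (u >= s) & (u <= s + width)
        a[inside] = np.maximum(
            a[inside], 0.5 * (1.0 - np.cos(2.0 * np.pi * (u[inside] - s) / width))
        )
    return a


def _threshold_offsets(width: float, threshold: float) -> float:
    """Offset from bump start at which the raised cosine reaches threshold."""
    return width * np.arccos(1.0 - 2.0 * threshold) / (2.0 * np.pi)


def _landmark_times(
    k: int, duration: float, gamma: float, threshold: float = ACTIVATION_THRESHOLD
) -> np.ndarray:
    """Threshold-crossing instants (seconds) of each bump, speed-distorted.

    The recording's activation at real time t is a(h(t/T)) with
    h(v) = v**gamma, so a nominal crossing u maps to t = T * u**(1/gamma).
    """
    starts, width = bump_layout(k)
    off = _threshold_offsets(width, threshold)
    nominal = np.sort(np.concatenate([starts + off, starts + width - off]))
    return duration * nominal ** (1.0 / gamma)


def _side_scale(params: SimulationParams) -> np.ndarray:
    """Per-POI motion multiplier implementing one-sided attenuation."""
    scale = np.ones(N_POI)
    affected = LEFT_POINTS if params.affected_side == "left" else RIGHT_POINTS
    for idx in affected:
        scale[idx] = params.asymmetry_attenuation
    return scale


def simulate_session(params: SimulationParams) -> tuple[Session, GroundTruth]:
    """Simulate one session (all nine exercises) plus its ground truth.

    Indicator-bearing exercises follow the bump model; the four unscored
    exercises are emitted as rest plus noise. Deterministic given the seed.
    """
    rng = np.random.default_rng(params.seed)
    rate = rng.uniform(*params.sampling_hz_range)
    k = params.n_repetitions
    duration = 3.0 + 2.5 * k
    face = neutral_face()
    side = _side_scale(params)
    gamma = params.speed_profile

    truth = GroundTruth(params=params, sampling_hz=rate, duration=duration)
    truth.bump_starts, truth.bump_width = bump_layout(k)

    recordings: dict[Exercise, ExerciseRecording] = {}
    for ex in Exercise:
        if ex.indicator_bearing:
            times = np.arange(0.0, duration, 1.0 / rate)
            phase = (times / duration) ** gamma  # h(v) = v**gamma
            act = activation_profile(phase, k) * params.intensity_scale
            pos = np.broadcast_to(face, (times.size, N_POI, 3)).copy()
            for idx, vec in EXERCISE_DISPLACEMENTS[ex].items():
                pos[:, idx, :] += np.outer(act, vec) * side[idx]
            truth.landmark_times[ex] = _landmark_times(k, duration, gamma)
        else:
            times = np.arange(0.0, 5.0, 1.0 / rate)
            pos = np.broadcast_to(face, (times.size, N_POI, 3)).copy()
        if params.noise_sd > 0:
            pos = pos + rng.normal(0.0, params.noise_sd, size=pos.shape)
        recordings[ex] = ExerciseRecording(ex, times, pos)

    session = Session(
        session_id=f"sim-{params.seed}",
        patient_id=f"simpat-{params.seed}",
        recordings=recordings,
        hb_clinician=params.grade,
    )
    return session, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    n: int,
    class_mix: tuple[float, float, float, float] = DEFAULT_CLASS_MIX,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    sampling_hz_range: tuple[float, float] = DEFAULT_SAMPLING_HZ,
) -> tuple[list[Session], list[GroundTruth]]:
    """Simulate ``n`` sessions with grade-conditional parameter draws.

    Grades are drawn from ``class_mix`` over the adjusted levels (1, 2, 3, 6);
    attenuation, intensity and speed get small per-session jitter around
    their grade defaults so classes overlap realistically.
    """
    mix = np.asarray(class_mix, dtype=float)
    if n < 1:
        raise FacekinError("n must be >= 1")
    if mix.size != 4 or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
        raise FacekinError("class_mix must be 4 nonnegative probabilities summing to 1")
    rng = np.random.default_rng(seed)
    levels = np.array([1, 2, 3, 6])
    sessions: list[Session] = []
    truths: list[GroundTruth] = []
    for i in range(n):
        grade = int(rng.choice(levels, p=mix))
        att = float(np.clip(rng.normal(DEFAULT_ATTENUATION[grade], 0.05), 0.0, 1.0))
        inten = float(np.clip(rng.normal(DEFAULT_INTENSITY[grade], 0.07), 0.05, 1.5))
        gamma = float(DEFAULT_SPEED_GAMMA[grade] * np.exp(rng.normal(0.0, 0.1)))
        params = SimulationParams(
            grade=grade,
            affected_side="left" if rng.random() < 0.5 else "right",
            asymmetry_attenuation=att,
            intensity_scale=inten,
            speed_profile=gamma,
            n_repetitions=int(rng.choice([2, 3, 4], p=[0.3, 0.5, 0.2])),
            sampling_hz_range=sampling_hz_range,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        session, truth = simulate_session(params)
        session.session_id = f"S{i:04d}"
        session.patient_id = f"P{i:04d}"
        sessions.append(session)
        truths.append(truth)
    return sessions, truths
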