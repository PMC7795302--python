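"""Stage-1 output: the 14 indicator curves.

Each indicator is a time curve on the registered unit grid summarising one
clinically meaningful aspect of one exercise:

* **symmetry** - ratio of the smaller to the larger of the homologous
  left/right distances, SI(t) = min(vL, vR) / max(vL, vR), in (0, 1];
* **intensity** - range of motion relative to rest; for Raising, Frowning
  and Smiling I(t) = 1 - 1 / max(vL(t)/vL(0), vR(t)/vR(0)); for Baring the
  mouth-ellipse area ratio I(t) = 1 - [v(14,15)(0) v(13,16)(0)] /
  [v(14,15)(t) v(13,16)(t)] (the pi/4 ellipse constant cancels); for
  Pursing I(t) = 1 - v(14,15)(0)/v(14,15)(t);
* **speed** - the exercise's warping function rescaled to the unit square
  (a patient-specific time-distortion signature).

Distance roles: Raising/Frowning compare inner eyebrow to inner eye corner
(4-2 left, 10-8 right); Smiling/Baring compare mouth corner to outer eye
corner (14-3 left, 15-9 right) - the eye corners being the most stable
reference points.  Pursing uses the mouth-corner distance 14-15.  Closing,
Blowing and the combined exercises carry no indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Exercise, ExerciseRecording, FacekinError, distance_curve
from .registration import RegisteredSession, WarpingFunction

__all__ = [
    "DegenerateGeometryError",
    "IndicatorCurve",
    "IndicatorSet",
    "INDICATOR_LABELS",
    "SYMMETRY_PAIRS",
    "IndicatorConfig",
    "baseline_value",
    "symmetry",
    "intensity_ratio",
    "intensity_baring",
    "intensity_pursing",
    "speed",
    "compute_all",
    "indicator_table",
]


class DegenerateGeometryError(FacekinError):
    """A distance needed by an indicator vanished at some sample."""


# the 14 indicator labels, by exercise
INDICATOR_LABELS: tuple[str, ...] = (
    "eyebrows.symmetry", "eyebrows.intensity", "eyebrows.speed",
    "frowning.symmetry", "frowning.intensity", "frowning.speed",
    "smiling.symmetry", "smiling.intensity", "smiling.speed",
    "teeth.symmetry", "teeth.intensity", "teeth.speed",
    "lips.intensity", "lips.speed",
)

_EXERCISE_PREFIX = {
    Exercise.RAISING: "eyebrows",
    Exercise.FROWNING: "frowning",
    Exercise.SMILING: "smiling",
    Exercise.BARING: "teeth",
    Exercise.PURSING: "lips",
}

# (left pair, right pair) for symmetry and the ratio intensities
SYMMETRY_PAIRS = {
    Exercise.RAISING: ((4, 2), (10, 8)),
    Exercise.FROWNING: ((4, 2), (10, 8)),
    Exercise.SMILING: ((14, 3), (15, 9)),
    Exercise.BARING: ((14, 3), (15, 9)),
}

_MOUTH_CORNERS = (14, 15)
_MOUTH_VERTICAL = (13, 16)


@dataclass
class IndicatorCurve:
    """One indicator as a function on the registered unit grid."""

    label: str
    times: np.ndarray
    values: np.ndarray
    session_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise FacekinError("times and values must have equal length")
        if self.label not in INDICATOR_LABELS:
            raise FacekinError(f"unknown indicator label {self.label!r}")


@dataclass
class IndicatorConfig:
    """Baseline handling for the intensity denominators.

    ``rest_window`` (default) averages the first ``baseline_window`` grid
    points of the selected repetition's rest margin, damping sensor noise;
    ``first_sample`` uses the literal first sample.
    """

    baseline_mode: str = "rest_window"
    baseline_window: int = 5


def baseline_value(values: np.ndarray, config: IndicatorConfig | None = None) -> float:
    config = config or IndicatorConfig()
    if config.baseline_mode == "first_sample":
        return float(values[0])
    if config.baseline_mode != "rest_window":
        raise FacekinError(f"unknown baseline mode {config.baseline_mode!r}")
    n = min(config.baseline_window, values.size)
    return float(np.mean(values[:n]))


def _positive(values: np.ndarray, what: str) -> np.ndarray:
    if np.any(values <= 0):
        raise DegenerateGeometryError(f"{what} vanished at some sample")
    return values


# ---------------------------------------------------------------------------
# Indicator formulas
# ---------------------------------------------------------------------------

def symmetry(rec: ExerciseRecording,
             left_pair: tuple[int, int],
             right_pair: tuple[int, int],
             label: str = "smiling.symmetry",
             session_id: str = "") -> IndicatorCurve:
    """Pointwise min/max ratio of the left and right distance curves."""
    vl = _positive(distance_curve(rec, *left_pair), "left distance")
    vr = _positive(distance_curve(rec, *right_pair), "right distance")
    values = np.minimum(vl, vr) / np.maximum(vl, vr)
    return IndicatorCurve(label, rec.times, values, session_id)


def intensity_ratio(rec: ExerciseRecording,
                    left_pair: tuple[int, int],
                    right_pair: tuple[int, int],
                    label: str = "smiling.intensity",
                    session_id: str = "",
                    config: IndicatorConfig | None = None) -> IndicatorCurve:
    """I(t) = 1 - 1 / max(vL(t)/vL(0), vR(t)/vR(0))."""
    vl = _positive(distance_curve(rec, *left_pair), "left distance")
    vr = _positive(distance_curve(rec, *right_pair), "right distance")
    vl0 = baseline_value(vl, config)
    vr0 = baseline_value(vr, config)
    if vl0 <= 0 or vr0 <= 0:
        raise DegenerateGeometryError("zero baseline distance")
    values = 1.0 - 1.0 / np.maximum(vl / vl0, vr / vr0)
    return IndicatorCurve(label, rec.times, values, session_id)


def intensity_baring(rec: ExerciseRecording, session_id: str = "",
                     config: IndicatorConfig | None = None) -> IndicatorCurve:
    """Mouth-ellipse area change: I(t) = 1 - [a(0) b(0)] / [a(t) b(t)]."""
    a = _positive(distance_curve(rec, *_MOUTH_CORNERS), "mouth-corner distance")
    b = _positive(distance_curve(rec, *_MOUTH_VERTICAL), "mouth-vertical distance")
    a0 = baseline_value(a, config)
    b0 = baseline_value(b, config)
    values = 1.0 - (a0 * b0) / (a * b)
    return IndicatorCurve("teeth.intensity", rec.times, values, session_id)


def intensity_pursing(rec: ExerciseRecording, session_id: str = "",
                      config: IndicatorConfig | None = None) -> IndicatorCurve:
    """Mouth-corner distance change: I(t) = 1 - v(0)/v(t)."""
    v = _positive(distance_curve(rec, *_MOUTH_CORNERS), "mouth-corner distance")
    v0 = baseline_value(v, config)
    values = 1.0 - v0 / v
    return IndicatorCurve("lips.intensity", rec.times, values, session_id)


def speed(w: WarpingFunction, grid: np.ndarray,
          label: str = "smiling.speed", session_id: str = "",
          orientation: str = "inverse") -> IndicatorCurve:
    """The warping function rescaled affinely onto the unit square.

    By default the *measured-time* parametrization (the inverse map,
    aligned time as a function of measured time) is used: a patient who
    rushes through the exercise yields a curve that climbs steeply at the
    beginning and flattens, sitting above the diagonal early on - the
    signature of brisk, healthy execution.  ``orientation="forward"``
    gives the reference-to-sample map instead; either way the identity
    warp maps to the diagonal.
    """
    grid = np.asarray(grid, dtype=float)
    g0, g1 = grid[0], grid[-1]
    u = (grid - g0) / (g1 - g0)
    t0 = w.reference_knots
    if orientation == "forward":
        raw = np.asarray(w(t0[0] + u * (t0[-1] - t0[0])), dtype=float)
    elif orientation == "inverse":
        s0, s1 = float(w(t0[0])), float(w(t0[-1]))
        raw = np.asarray(w.inverse(s0 + u * (s1 - s0)), dtype=float)
    else:
        raise FacekinError(f"unknown speed orientation {orientation!r}")
    values = (raw - raw[0]) / (raw[-1] - raw[0])
    return IndicatorCurve(label, u, values, session_id)


# ---------------------------------------------------------------------------
# Full indicator set
# ---------------------------------------------------------------------------

@dataclass
class IndicatorSet:
    """The (up to) 14 indicator curves of one session, plus absence flags."""

    session_id: str
    hb_clinician: int | None = None
    curves: dict[str, IndicatorCurve] = field(default_factory=dict)
    absent: dict[str, str] = field(default_factory=dict)  # label -> reason


def compute_all(reg: RegisteredSession,
                config: IndicatorConfig | None = None) -> IndicatorSet:
    """Compute every available indicator of a registered session.

    Missing or failed exercises yield flagged absences rather than errors
    so one bad exercise never voids the session.
    """
    out = IndicatorSet(reg.session_id, reg.hb_clinician)
    for ex, prefix in _EXERCISE_PREFIX.items():
        labels = [f"{prefix}.{kind}" for kind in ("symmetry", "intensity", "speed")]
        if ex is Exercise.PURSING:
            labels = [f"{prefix}.intensity", f"{prefix}.speed"]
        rex = reg.exercises.get(ex)
        if rex is None:
            for lab in labels:
                out.absent[lab] = "exercise missing"
            continue
        rec = rex.recording
        sid = reg.session_id
        try:
            if ex is not Exercise.PURSING:
                lp, rp = SYMMETRY_PAIRS[ex]
                out.curves[f"{prefix}.symmetry"] = symmetry(
                    rec, lp, rp, f"{prefix}.symmetry", sid)
            if ex in (Exercise.RAISING, Exercise.FROWNING, Exercise.SMILING):
                lp, rp = SYMMETRY_PAIRS[ex]
                out.curves[f"{prefix}.intensity"] = intensity_ratio(
                    rec, lp, rp, f"{prefix}.intensity", sid, config)
            elif ex is Exercise.BARING:
                out.curves["teeth.intensity"] = intensity_baring(rec, sid, config)
            else:
                out.curves["lips.intensity"] = intensity_pursing(rec, sid, config)
            out.curves[f"{prefix}.speed"] = speed(
                rex.warping, rec.times, f"{prefix}.speed", sid)
        except FacekinError as err:
            for lab in labels:
                if lab not in out.curves:
                    out.absent[lab] = str(err)
    return out


def indicator_table(sets: list[IndicatorSet]) -> pd.DataFrame:
    """Long-format export: one row per (session, label, t)."""
    rows = []
    for s in sets:
        for label, curve in s.curves.items():
            for t, v in zip(curve.times, curve.values):
                rows.append((s.session_id, label, t, v))
    return pd.DataFrame(rows, columns=["session_id", "label", "t", "value"])
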