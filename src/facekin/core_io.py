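"""Domain types and the on-disk session dialect.

A *session* is one clinical measurement: the patient performs a fixed series
of nine mimetic-muscle exercises in front of a depth camera while 21 facial
points of interest (POI) are tracked in 3D.  A complete session therefore
carries 3 axes x 21 POI x 9 exercises = 567 coordinate curves, sampled at a
variable (possibly irregular) rate.

The on-disk dialect is a directory with a ``manifest.txt`` (flat key=value
lines: ids, optional clinician House-Brackmann grade, outlier flag, and one
``exercise.<Name>=<file>`` entry per recording) plus one delimited-text
trajectory file per exercise with header ``time,p00x,p00y,p00z,...,p20z``
(64 columns).  Units are seconds and meters; the downstream indicators are
ratios, so the pipeline is unit-agnostic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "FacekinError",
    "MissingManifestError",
    "MissingTrajectoryFileError",
    "NonMonotoneTimeError",
    "ColumnCountError",
    "UnknownExerciseError",
    "InvalidGradeError",
    "Exercise",
    "INDICATOR_EXERCISES",
    "POI",
    "POI_TABLE",
    "N_POI",
    "HOMOLOGOUS_PAIRS",
    "LEFT_POINTS",
    "RIGHT_POINTS",
    "MIDLINE_POINTS",
    "ExerciseRecording",
    "Session",
    "HBGrade",
    "adjust_grade",
    "distance_curve",
    "read_session",
    "write_session",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class FacekinError(Exception):
    """Base class for all package errors."""


class MissingManifestError(FacekinError):
    """Session directory has no manifest.txt."""


class MissingTrajectoryFileError(FacekinError):
    """Manifest references a trajectory file that does not exist."""


class NonMonotoneTimeError(FacekinError):
    """Timestamps in a trajectory are not strictly increasing."""


class ColumnCountError(FacekinError):
    """Trajectory file does not have the 64 expected columns."""


class UnknownExerciseError(FacekinError):
    """Exercise name is not one of the nine defined exercises."""


class InvalidGradeError(FacekinError):
    """House-Brackmann grade outside 1..6."""


# ---------------------------------------------------------------------------
# Exercises
# ---------------------------------------------------------------------------

class Exercise(enum.Enum):
    """The nine instructed exercises.

    Five of them (Raising, Frowning, Smiling, Baring, Pursing) carry
    indicators; the remaining four stay in the data model but produce no
    indicator curves (their tracked motion proved too unreliable to score).
    """

    RAISING = "Raising"
    FROWNING = "Frowning"
    CLOSING = "Closing"
    SMILING = "Smiling"
    BARING = "Baring"
    PURSING = "Pursing"
    BLOWING = "Blowing"
    CLOSING_AND_BARING = "Closing and Baring"
    RAISING_AND_PURSING = "Raising and Pursing"

    @property
    def instruction(self) -> str:
        return _INSTRUCTIONS[self]

    @property
    def indicator_bearing(self) -> bool:
        return self in INDICATOR_EXERCISES


_INSTRUCTIONS = {
    Exercise.RAISING: "Raise your eyebrows",
    Exercise.FROWNING: "Frown",
    Exercise.CLOSING: "Close your eyes tightly",
    Exercise.SMILING: "Smile at me",
    Exercise.BARING: "Bare your teeth",
    Exercise.PURSING: "Purse your lips",
    Exercise.BLOWING: "Blow out your cheeks",
    Exercise.CLOSING_AND_BARING: "Close your eyes tightly and bare the teeth",
    Exercise.RAISING_AND_PURSING: "Raise your eyebrows and purse the lips",
}

INDICATOR_EXERCISES = (
    Exercise.RAISING,
    Exercise.FROWNING,
    Exercise.SMILING,
    Exercise.BARING,
    Exercise.PURSING,
)


# ---------------------------------------------------------------------------
# Points of interest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class POI:
    """One tracked facial landmark.

    ``sensor_index`` is the index of the point in the depth sensor's dense
    face mesh (metadata only; never used in computation).
    """

    index: int
    anatomical_label: str
    sensor_index: int


POI_TABLE: tuple[POI, ...] = (
    POI(0, "left eye, bottom", 1104),
    POI(1, "left eye, top", 241),
    POI(2, "left eye, inner corner", 210),
    POI(3, "left eye, outer corner", 469),
    POI(4, "left eyebrow, inner", 346),
    POI(5, "left eyebrow, centre", 222),
    POI(6, "right eye, bottom", 1090),
    POI(7, "right eye, top", 731),
    POI(8, "right eye, inner", 843),
    POI(9, "right eye, outer", 1117),
    POI(10, "right eyebrow, inner", 803),
    POI(11, "right eyebrow, centre", 849),
    POI(12, "nose tip", 18),
    POI(13, "mouth lower lip, centre-bottom", 8),
    POI(14, "mouth, left corner", 91),
    POI(15, "mouth, right corner", 687),
    POI(16, "mouth upper lip, centre-top", 19),
    POI(17, "chin, centre", 4),
    POI(18, "forehead, centre", 28),
    POI(19, "left cheek, centre", 412),
    POI(20, "right cheek, centre", 933),
)

N_POI = 21

# left/right anatomical homologue pairs (left index, right index)
HOMOLOGOUS_PAIRS = ((0, 6), (1, 7), (2, 8), (3, 9), (4, 10), (5, 11), (14, 15), (19, 20))
LEFT_POINTS = frozenset(l for l, _ in HOMOLOGOUS_PAIRS)
RIGHT_POINTS = frozenset(r for _, r in HOMOLOGOUS_PAIRS)
MIDLINE_POINTS = frozenset((12, 13, 16, 17, 18))


# ---------------------------------------------------------------------------
# Recordings and sessions
# ---------------------------------------------------------------------------

@dataclass
class ExerciseRecording:
    """Raw (or registered) 3D trajectories of the 21 POI for one exercise.

    ``times`` is a strictly increasing vector of sample instants (seconds);
    ``positions`` has shape ``(len(times), 21, 3)`` in meters.
    """

    exercise: Exercise
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise FacekinError("recording needs at least 2 samples")
        if np.any(np.diff(self.times) <= 0):
            raise NonMonotoneTimeError(
                f"{self.exercise.value}: timestamps not strictly increasing"
            )
        if self.positions.shape != (self.times.size, N_POI, 3):
            raise FacekinError(
                f"positions shape {self.positions.shape} != "
                f"({self.times.size}, {N_POI}, 3)"
            )
        if not np.all(np.isfinite(self.positions)):
            raise FacekinError(f"{self.exercise.value}: non-finite coordinates")

    @property
    def n_samples(self) -> int:
        return self.times.size


@dataclass
class Session:
    """One measurement session: up to nine exercise recordings.

    ``hb_clinician`` is the raw clinician grade 1-6 if available;
    ``excluded`` is a human outlier decision with a free-text reason.
    ``meta`` carries extra manifest keys (e.g. ``registered=true``).
    """

    session_id: str
    patient_id: str
    recordings: dict[Exercise, ExerciseRecording] = field(default_factory=dict)
    hb_clinician: Optional[int] = None
    excluded: bool = False
    exclusion_reason: str = ""
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hb_clinician is not None and self.hb_clinician not in range(1, 7):
            raise InvalidGradeError(f"hb_clinician={self.hb_clinician} not in 1..6")
        for ex, rec in self.recordings.items():
            if rec.exercise is not ex:
                raise FacekinError("recording keyed under wrong exercise")

    @property
    def n_coordinate_curves(self) -> int:
        """Number of scalar time curves held (3 axes x 21 POI per exercise)."""
        return 3 * N_POI * len(self.recordings)

    @property
    def is_complete(self) -> bool:
        return len(self.recordings) == len(Exercise)


# ---------------------------------------------------------------------------
# House-Brackmann grades
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBGrade:
    """Raw clinician grade and its adjusted value.

    Grades 4 and 5 are rare and clinically close to 3 and 6 respectively,
    so modelling merges them: 4 -> 3 and 5 -> 6, leaving the four adjusted
    levels {1, 2, 3, 6}.
    """

    raw: int
    adjusted: int


ADJUSTED_LEVELS = (1, 2, 3, 6)


def adjust_grade(raw: int) -> HBGrade:
    """Map a raw House-Brackmann grade 1-6 to its adjusted level."""
    if raw not in range(1, 7):
        raise InvalidGradeError(f"raw grade {raw} not in 1..6")
    adjusted = {4: 3, 5: 6}.get(raw, raw)
    return HBGrade(raw=raw, adjusted=adjusted)


# ---------------------------------------------------------------------------
# Distance curves
# ---------------------------------------------------------------------------

def distance_curve(rec: ExerciseRecording, a: int, b: int) -> np.ndarray:
    """Euclidean 3D distance between POI ``a`` and ``b`` at every sample.

    This is the v(P,Q)(t) building block of every symmetry and intensity
    indicator. Returns an array on the recording's own time grid.
    """
    if a == b:
        raise FacekinError("distance_curve requires two distinct points")
    for idx in (a, b):
        if not 0 <= idx < N_POI:
            raise FacekinError(f"POI index {idx} out of range 0..{N_POI - 1}")
    diff = rec.positions[:, a, :] - rec.positions[:, b, :]
    return np.linalg.norm(diff, axis=1)


# ---------------------------------------------------------------------------
# On-disk dialect
# ---------------------------------------------------------------------------

_MANIFEST = "manifest.txt"
_FLOAT_FMT = "%.12g"  # lossless to well below the declared 1e-9 tolerance


def _slug(exercise: Exercise) -> str:
    return exercise.value.lower().replace(" ", "_")


def _columns() -> list[str]:
    cols = ["time"]
    for p in range(N_POI):
        for ax in "xyz":
            cols.append(f"p{p:02d}{ax}")
    return cols


def write_session(session: Session, path: Path | str) -> None:
    """Write a session directory (manifest + one CSV per exercise)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lines = [
        f"session_id={session.session_id}",
        f"patient_id={session.patient_id}",
    ]
    if session.hb_clinician is not None:
        lines.append(f"hb_clinician={session.hb_clinician}")
    lines.append(f"excluded={'true' if session.excluded else 'false'}")
    if session.exclusion_reason:
        lines.append(f"exclusion_reason={session.exclusion_reason}")
    for key, value in session.meta.items():
        lines.append(f"{key}={value}")
    cols = _columns()
    for ex in Exercise:
        rec = session.recordings.get(ex)
        if rec is None:
            continue
        fname = f"{_slug(ex)}.csv"
        lines.append(f"exercise.{ex.value}={fname}")
        flat = np.column_stack([rec.times, rec.positions.reshape(rec.n_samples, -1)])
        df = pd.DataFrame(flat, columns=cols)
        df.to_csv(path / fname, index=False, float_format=_FLOAT_FMT)
    (path / _MANIFEST).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _parse_manifest(path: Path) -> dict[str, str]:
    mf = path / _MANIFEST
    if not mf.is_file():
        raise MissingManifestError(f"no {_MANIFEST} in {path}")
    entries: dict[str, str] = {}
    for line in mf.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()
    return entries


def read_session(path: Path | str) -> Session:
    """Read a session directory written in the package dialect."""
    path = Path(path)
    entries = _parse_manifest(path)
    known_names = {ex.value: ex for ex in Exercise}
    recordings: dict[Exercise, ExerciseRecording] = {}
    meta: dict[str, str] = {}
    expected_cols = _columns()
    for key, value in entries.items():
        if not key.startswith("exercise."):
            continue
        name = key[len("exercise."):]
        if name not in known_names:
            raise UnknownExerciseError(f"unknown exercise {name!r} in manifest")
        ex = known_names[name]
        fpath = path / value
        if not fpath.is_file():
            raise MissingTrajectoryFileError(f"missing trajectory file {fpath}")
        df = pd.read_csv(fpath)
        if list(df.columns) != expected_cols:
            raise ColumnCountError(
                f"{fpath.name}: expected {len(expected_cols)} columns "
                f"(time + 63 coordinates), got {len(df.columns)}"
            )
        times = df["time"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise NonMonotoneTimeError(f"{fpath.name}: non-monotone timestamps")
        positions = df.iloc[:, 1:].to_numpy(dtype=float).reshape(len(df), N_POI, 3)
        recordings[ex] = ExerciseRecording(ex, times, positions)
    reserved = {"session_id", "patient_id", "hb_clinician", "excluded", "exclusion_reason"}
    for key, value in entries.items():
        if key not in reserved and not key.startswith("exercise."):
            meta[key] = value
    hb = entries.get("hb_clinician")
    return Session(
        session_id=entries.get("session_id", path.name),
        patient_id=entries.get("patient_id", ""),
        recordings=recordings,
        hb_clinician=int(hb) if hb is not None else None,
        excluded=entries.get("excluded", "false").lower() == "true",
        exclusion_reason=entries.get("exclusion_reason", ""),
        meta=meta,
    )
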