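"""Stage 1 - curve registration.

Each patient performs each exercise at their own time and pace, and not
always the instructed three repetitions.  Registration aligns all sessions
onto a common timeline:

1. build a per-exercise scalar *alignment curve* (the distance combination
   with the most pronounced motion, including both facial halves);
2. detect the number of repetitions k in {2, 3, 4} by dynamic time warping
   (DTW) against reference rest-bump templates, picking the minimal
   path-length-normalized distance;
3. locate 2k repetition landmarks (begin/end per repetition) as
   threshold crossings of the normalized curve around the bumps matched by
   the DTW path;
4. fit a strictly monotone piecewise-cubic warping function w with
   w(reference landmark) = sample landmark (shape-preserving Hermite /
   Fritsch-Carlson slopes, linear extension outside the knots);
5. evaluate all 63 coordinate curves of the exercise at the warped grid -
   one shared w per session-exercise;
6. select a single repetition (the second by default; first and last are
   the noisiest) and renormalize its window to a fresh [0, 1] grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

from .core_io import (
    Exercise,
    ExerciseRecording,
    FacekinError,
    Session,
    distance_curve,
    read_session,
    write_session,
)

__all__ = [
    "FlatSignalError",
    "LandmarkExtractionError",
    "RepetitionIndexError",
    "AlignmentCurve",
    "LandmarkSet",
    "WarpingFunction",
    "RegistrationConfig",
    "RegisteredExercise",
    "RegisteredSession",
    "smooth",
    "alignment_curve",
    "dtw_distance",
    "reference_template",
    "reference_landmarks",
    "detect_repetitions",
    "extract_landmarks",
    "fit_warping",
    "apply_warping",
    "select_repetition",
    "register_recording",
    "register_session",
    "write_registered_session",
    "read_registered_session",
]


class FlatSignalError(FacekinError):
    """Alignment curve is (numerically) constant - no repetitions to find."""


class LandmarkExtractionError(FacekinError):
    """Could not find the required threshold-crossing intervals."""


class RepetitionIndexError(FacekinError):
    """Requested repetition index exceeds the detected repetition count."""


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def smooth(values: np.ndarray, window: int, method: str = "moving_average",
           polyorder: int = 2) -> np.ndarray:
    """Smooth a 1D curve with a centered window (truncated at the ends).

    ``method`` is ``moving_average`` (default) or ``savgol``.
    """
    if window < 1 or window % 2 == 0:
        raise FacekinError("window must be a positive odd integer")
    values = np.asarray(values, dtype=float)
    if window == 1:
        return values.copy()
    if method == "savgol":
        win = min(window, values.size if values.size % 2 == 1 else values.size - 1)
        return savgol_filter(values, win, min(polyorder, win - 1))
    if method != "moving_average":
        raise FacekinError(f"unknown smoothing method {method!r}")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    n = values.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


# ---------------------------------------------------------------------------
# Alignment curves
# ---------------------------------------------------------------------------

@dataclass
class AlignmentCurve:
    """The scalar curve used to register one exercise recording."""

    exercise: Exercise
    times: np.ndarray
    values: np.ndarray


# distance combinations with the most significant motion per exercise
_EYEBROW_PAIRS = ((4, 2), (10, 8))  # inner eyebrow to inner eye corner
_MOUTH_CORNERS = (14, 15)


def alignment_curve(rec: ExerciseRecording) -> AlignmentCurve:
    """Scalar summary curve for registration.

    Raising/Frowning: sum of left and right eyebrow-to-inner-eye-corner
    distances (covers both halves, so one-sided movers still register).
    Smiling/Baring/Pursing: distance between the mouth corners.
    """
    ex = rec.exercise
    if not ex.indicator_bearing:
        raise FacekinError(f"{ex.value} carries no alignment curve")
    if ex in (Exercise.RAISING, Exercise.FROWNING):
        values = sum(distance_curve(rec, a, b) for a, b in _EYEBROW_PAIRS)
    else:
        values = distance_curve(rec, *_MOUTH_CORNERS)
    return AlignmentCurve(ex, rec.times.copy(), np.asarray(values))


# ---------------------------------------------------------------------------
# Dynamic time warping
# ---------------------------------------------------------------------------

def _dtw_cost_matrix_py(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n, m = a.size, b.size
    acc = np.full((n, m), np.inf)
    acc[0, 0] = (a[0] - b[0]) ** 2
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + (a[i] - b[0]) ** 2
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + (a[0] - b[j]) ** 2
    for i in range(1, n):
        for j in range(1, m):
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = best + (a[i] - b[j]) ** 2
    return acc


try:  # jit the O(n*m) kernel when numba is available
    from numba import njit

    _dtw_cost_matrix = njit(cache=False)(_dtw_cost_matrix_py)
except ImportError:  # pragma: no cover - numba is a declared dependency
    _dtw_cost_matrix = _dtw_cost_matrix_py


def dtw_distance(a: np.ndarray, b: np.ndarray) -> tuple[float, list[tuple[int, int]]]:
    """Classic DTW with symmetric steps and squared-difference local cost.

    Returns the total accumulated cost and one optimal monotone path from
    (0, 0) to (n-1, m-1). The distance is 0 iff an exact monotone warping
    of one sequence onto the other exists.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise FacekinError("dtw_distance needs sequences of length >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise FacekinError("dtw_distance requires finite values")
    acc = _dtw_cost_matrix(a, b)
    # backtrack
    i, j = a.size - 1, b.size - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            moves = ((acc[i - 1, j - 1], i - 1, j - 1),
                     (acc[i - 1, j], i - 1, j),
                     (acc[i, j - 1], i, j - 1))
            _, i, j = min(moves, key=lambda t: t[0])
        path.append((i, j))
    path.reverse()
    return float(acc[-1, -1]), path


# ---------------------------------------------------------------------------
# Reference templates
# ---------------------------------------------------------------------------

_TPL_LEAD = 0.1
_TPL_TRAIL = 0.1
_TPL_GAP_OVER_WIDTH = 0.5


def _template_layout(k: int) -> tuple[np.ndarray, float]:
    """Bump start fractions and width of the k-repetition template on [0,1]."""
    if k not in (2, 3, 4):
        raise FacekinError("k must be 2, 3 or 4")
    active = 1.0 - _TPL_LEAD - _TPL_TRAIL
    width = active / (k + _TPL_GAP_OVER_WIDTH * (k - 1))
    starts = _TPL_LEAD + np.arange(k) * (width * (1 + _TPL_GAP_OVER_WIDTH))
    return starts, width


def reference_template(k: int, n_points: int = 200) -> np.ndarray:
    """Rest-bump reference pattern with k unit raised-cosine bumps."""
    starts, width = _template_layout(k)
    u = np.linspace(0.0, 1.0, n_points)
    out = np.zeros(n_points)
    for s in starts:
        inside = (u >= s) & (u <= s + width)
        out[inside] = np.maximum(
            out[inside], 0.5 * (1 - np.cos(2 * np.pi * (u[inside] - s) / width))
        )
    return out


def reference_landmarks(k: int, threshold: float = 0.15) -> np.ndarray:
    """Reference landmark instants t0j on [0, 1]: 2k bump threshold crossings."""
    starts, width = _template_layout(k)
    off = width * np.arccos(1.0 - 2.0 * threshold) / (2.0 * np.pi)
    return np.sort(np.concatenate([starts + off, starts + width - off]))


# ---------------------------------------------------------------------------
# Repetition detection
# ---------------------------------------------------------------------------

def _normalize_orient(values: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1] and orient so activity points upward.

    Exercises whose alignment distance *shrinks* during activity (Pursing,
    Frowning) produce valleys; since rest dominates the timeline, a median
    above 0.5 after normalization marks an inverted curve, which is flipped.
    """
    values = np.asarray(values, dtype=float)
    rng = values.max() - values.min()
    scale = max(abs(values.max()), abs(values.min()), 1.0)
    if rng <= 1e-12 * scale:
        raise FlatSignalError("alignment curve is constant")
    x = (values - values.min()) / rng
    if np.median(x) > 0.5:
        x = 1.0 - x
    return x


def _downsample(values: np.ndarray, max_points: int) -> np.ndarray:
    if values.size <= max_points:
        return values
    src = np.linspace(0.0, 1.0, values.size)
    dst = np.linspace(0.0, 1.0, max_points)
    return np.interp(dst, src, values)


def detect_repetitions(curve: AlignmentCurve | np.ndarray,
                       max_points: int = 150) -> int:
    """Number of repetitions in {2, 3, 4} by template matching.

    The normalized, oriented curve is compared by DTW to the reference
    templates; the candidate with the minimal average (path-length-
    normalized) distance wins, ties breaking toward 3 (the instructed
    count).
    """
    values = curve.values if isinstance(curve, AlignmentCurve) else curve
    x = _downsample(_normalize_orient(values), max_points)
    best_k, best_d = 3, np.inf
    for k in (3, 2, 4):  # 3 first so exact ties keep the instructed count
        tpl = reference_template(k, x.size)
        dist, path = dtw_distance(x, tpl)
        avg = dist / len(path)
        if avg < best_d:
            best_k, best_d = k, avg
    return best_k


# ---------------------------------------------------------------------------
# Landmark extraction
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """2k strictly increasing repetition begin/end instants (seconds)."""

    times: np.ndarray
    k_repetitions: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size != 2 * self.k_repetitions:
            raise FacekinError("landmark count must be 2 * k_repetitions")
        if np.any(np.diff(self.times) <= 0):
            raise FacekinError("landmark times must be strictly increasing")


def _crossing_time(times: np.ndarray, x: np.ndarray, i0: int, i1: int,
                   threshold: float) -> float:
    """Linear interpolation of the threshold crossing between samples i0, i1."""
    if x[i1] == x[i0]:
        return float(times[i1])
    frac = (threshold - x[i0]) / (x[i1] - x[i0])
    return float(times[i0] + frac * (times[i1] - times[i0]))


def extract_landmarks(curve: AlignmentCurve, k: int,
                      threshold: float = 0.15) -> LandmarkSet:
    """Locate 2k repetition begin/end instants on the alignment curve.

    The DTW path to the k-bump template assigns each template bump a span
    of curve samples; within each span the curve's peak is found and the
    landmark pair is the threshold crossing (default 0.15 of range) walking
    out from that peak, linearly interpolated between samples.
    """
    x = _normalize_orient(curve.values)
    times = curve.times
    tpl = reference_template(k, x.size)
    _, path = dtw_distance(x, tpl)
    starts, width = _template_layout(k)
    path_arr = np.asarray(path)
    u_tpl = np.linspace(0.0, 1.0, x.size)
    peaks: list[int] = []
    for s in starts:
        in_bump = (u_tpl[path_arr[:, 1]] >= s) & (u_tpl[path_arr[:, 1]] <= s + width)
        if not np.any(in_bump):
            raise LandmarkExtractionError("DTW path matched no samples to a bump")
        span = path_arr[in_bump, 0]
        lo, hi = int(span.min()), int(span.max())
        peak = lo + int(np.argmax(x[lo:hi + 1]))
        if x[peak] <= threshold:
            raise LandmarkExtractionError(
                f"bump peak below activation threshold {threshold}"
            )
        peaks.append(peak)
    if np.any(np.diff(peaks) <= 0):
        raise LandmarkExtractionError(
            f"fewer than {k} separated activation intervals found"
        )
    # walk boundaries: the valley between consecutive peaks (or the ends)
    bounds = [0]
    for a, b in zip(peaks[:-1], peaks[1:]):
        bounds.append(a + int(np.argmin(x[a:b + 1])))
    bounds.append(x.size - 1)
    landmarks: list[float] = []
    for b, peak in enumerate(peaks):
        lo_bound, hi_bound = bounds[b], bounds[b + 1]
        i = peak
        while i > lo_bound and x[i - 1] > threshold:
            i -= 1
        if i > lo_bound:  # crossed the threshold inside the allowed range
            begin = _crossing_time(times, x, i - 1, i, threshold)
        elif lo_bound == 0:
            begin = float(times[0])
        else:  # noise floor above threshold: nudge off the shared valley
            begin = float(0.75 * times[lo_bound] + 0.25 * times[lo_bound + 1])
        j = peak
        while j < hi_bound and x[j + 1] > threshold:
            j += 1
        if j < hi_bound:
            end = _crossing_time(times, x, j, j + 1, threshold)
        elif hi_bound == x.size - 1:
            end = float(times[-1])
        else:
            end = float(0.75 * times[hi_bound] + 0.25 * times[hi_bound - 1])
        landmarks.extend([begin, end])
    lm = np.asarray(landmarks)
    if np.any(np.diff(lm) <= 0):
        raise LandmarkExtractionError(
            f"fewer than {k} separated threshold-crossing intervals found"
        )
    return LandmarkSet(lm, k)


# ---------------------------------------------------------------------------
# Warping functions
# ---------------------------------------------------------------------------

class WarpingFunction:
    """Strictly monotone piecewise-cubic map from reference to sample time.

    Interpolates w(t0j) = tij with shape-preserving Hermite (Fritsch-
    Carlson) slopes, which keeps w strictly increasing for strictly
    increasing knots; outside the knot range w continues linearly with the
    secant slope of the end interval.
    """

    def __init__(self, reference_knots: np.ndarray, sample_knots: np.ndarray):
        t0 = np.asarray(reference_knots, dtype=float)
        ti = np.asarray(sample_knots, dtype=float)
        if t0.size != ti.size or t0.size < 2:
            raise FacekinError("need matching knot vectors of length >= 2")
        if np.any(np.diff(t0) <= 0) or np.any(np.diff(ti) <= 0):
            raise FacekinError("warping knots must be strictly increasing")
        self.reference_knots = t0
        self.sample_knots = ti
        self._pchip = PchipInterpolator(t0, ti)
        self._slope_lo = (ti[1] - ti[0]) / (t0[1] - t0[0])
        self._slope_hi = (ti[-1] - ti[-2]) / (t0[-1] - t0[-2])

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        t0, ti = self.reference_knots, self.sample_knots
        out = np.empty_like(t, dtype=float)
        below = t < t0[0]
        above = t > t0[-1]
        inside = ~(below | above)
        out[below] = ti[0] + self._slope_lo * (t[below] - t0[0])
        out[above] = ti[-1] + self._slope_hi * (t[above] - t0[-1])
        out[inside] = self._pchip(t[inside])
        return out if out.ndim else float(out)

    def inverse(self, s: np.ndarray | float, n_dense: int = 4097) -> np.ndarray | float:
        """Numerical inverse (exact linear inversion outside the knots)."""
        s = np.asarray(s, dtype=float)
        t0, ti = self.reference_knots, self.sample_knots
        out = np.empty_like(s)
        below = s < ti[0]
        above = s > ti[-1]
        inside = ~(below | above)
        out[below] = t0[0] + (s[below] - ti[0]) / self._slope_lo
        out[above] = t0[-1] + (s[above] - ti[-1]) / self._slope_hi
        grid = np.linspace(t0[0], t0[-1], n_dense)
        out[inside] = np.interp(s[inside], self._pchip(grid), grid)
        return out if out.ndim else float(out)


def fit_warping(landmarks: LandmarkSet | np.ndarray,
                reference: np.ndarray) -> WarpingFunction:
    """Fit the monotone warping through (reference t0j, sample tij) pairs."""
    tij = landmarks.times if isinstance(landmarks, LandmarkSet) else np.asarray(landmarks)
    return WarpingFunction(np.asarray(reference, dtype=float), tij)


def apply_warping(rec: ExerciseRecording, w: WarpingFunction,
                  grid: np.ndarray) -> ExerciseRecording:
    """Evaluate all 63 coordinate curves at the warped grid.

    Each coordinate curve P(t) is linearly interpolated at w(t_ref) for
    every reference grid point, clamped to the recording's time span. The
    same w (derived from the exercise's alignment curve) is shared by all
    coordinates of the exercise.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise FacekinError("grid must hold at least 2 points")
    warped = np.clip(w(grid), rec.times[0], rec.times[-1])
    flat = rec.positions.reshape(rec.n_samples, -1)
    out = np.empty((grid.size, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(warped, rec.times, flat[:, c])
    return ExerciseRecording(rec.exercise, grid, out.reshape(grid.size, -1, 3))


def select_repetition(registered: ExerciseRecording,
                      reference_marks: np.ndarray,
                      index: int = 2,
                      n_points: int | None = None) -> ExerciseRecording:
    """Cut out one repetition from a registered recording.

    ``reference_marks`` are the 2k reference landmark instants on the
    registered grid. The window around repetition ``index`` (1-based) is
    extended to the midpoints toward the neighbouring repetitions (or the
    grid edge), then re-interpolated onto a fresh ``n_points`` grid
    renormalized to [0, 1] so every session shares the same grid whatever
    its repetition count.
    """
    marks = np.asarray(reference_marks, dtype=float)
    k = marks.size // 2
    if index < 1 or index > k:
        raise RepetitionIndexError(f"repetition {index} of {k} requested")
    begin = marks[2 * (index - 1)]
    end = marks[2 * (index - 1) + 1]
    t_lo = registered.times[0]
    t_hi = registered.times[-1]
    prev_end = marks[2 * (index - 1) - 1] if index > 1 else t_lo
    next_begin = marks[2 * index] if index < k else t_hi
    lo = 0.5 * (prev_end + begin)
    hi = 0.5 * (end + next_begin)
    if n_points is None:
        n_points = registered.n_samples
    window = np.linspace(lo, hi, n_points)
    flat = registered.positions.reshape(registered.n_samples, -1)
    out = np.empty((n_points, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(window, registered.times, flat[:, c])
    unit = np.linspace(0.0, 1.0, n_points)
    return ExerciseRecording(registered.exercise, unit, out.reshape(n_points, -1, 3))


# ---------------------------------------------------------------------------
# High-level registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationConfig:
    """Tunables for stage 1 (all gap-fills where the method is unspecified)."""

    smoothing_window: int = 5
    smoothing_method: str = "moving_average"
    grid_points: int = 100
    activation_threshold: float = 0.15
    dtw_max_points: int = 150
    repetition_index: int = 2

    def validate(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise FacekinError("smoothing_window must be a positive odd integer")
        if self.grid_points < 10:
            raise FacekinError("grid_points must be >= 10")
        if not 0.0 < self.activation_threshold < 0.5:
            raise FacekinError("activation_threshold must be in (0, 0.5)")
        if self.repetition_index < 1:
            raise FacekinError("repetition_index must be >= 1")


@dataclass
class RegisteredExercise:
    """Outcome of registering one exercise recording."""

    recording: ExerciseRecording  # repetition-selected, on the unit grid
    warping: WarpingFunction
    k_repetitions: int
    landmarks: LandmarkSet


@dataclass
class RegisteredSession:
    session_id: str
    patient_id: str
    hb_clinician: int | None
    exercises: dict[Exercise, RegisteredExercise] = field(default_factory=dict)


def register_recording(rec: ExerciseRecording,
                       config: RegistrationConfig | None = None) -> RegisteredExercise:
    """Run the full stage-1 chain on one indicator-bearing recording."""
    config = config or RegistrationConfig()
    config.validate()
    ac = alignment_curve(rec)
    ac.values = smooth(ac.values, config.smoothing_window, config.smoothing_method)
    k = detect_repetitions(ac, config.dtw_max_points)
    lm = extract_landmarks(ac, k, config.activation_threshold)
    t0 = reference_landmarks(k, config.activation_threshold)
    w = fit_warping(lm, t0)
    grid = np.linspace(0.0, 1.0, config.grid_points)
    registered = apply_warping(rec, w, grid)
    rep = min(config.repetition_index, k)
    selected = select_repetition(registered, t0, rep, config.grid_points)
    return RegisteredExercise(selected, w, k, lm)


def register_session(session: Session,
                     config: RegistrationConfig | None = None,
                     strict: bool = False) -> RegisteredSession:
    """Register every indicator-bearing exercise of a session.

    Failures on single exercises are warnings (the exercise is dropped)
    unless ``strict``.
    """
    out = RegisteredSession(session.session_id, session.patient_id,
                            session.hb_clinician)
    for ex, rec in session.recordings.items():
        if not ex.indicator_bearing:
            continue
        try:
            out.exercises[ex] = register_recording(rec, config)
        except FacekinError as err:
            if strict:
                raise
            warnings.warn(
                f"{session.session_id}/{ex.value}: registration failed ({err})",
                stacklevel=2,
            )
    return out


# ---------------------------------------------------------------------------
# Serialization of registered sessions
# ---------------------------------------------------------------------------

def write_registered_session(reg: RegisteredSession, path: Path | str) -> None:
    """Write registered recordings in the session dialect plus warping knots."""
    path = Path(path)
    session = Session(
        session_id=reg.session_id,
        patient_id=reg.patient_id,
        hb_clinician=reg.hb_clinician,
        recordings={ex: r.recording for ex, r in reg.exercises.items()},
        meta={"registered": "true"},
    )
    for ex, r in reg.exercises.items():
        session.meta[f"k.{ex.value}"] = str(r.k_repetitions)
    write_session(session, path)
    for ex, r in reg.exercises.items():
        slug = ex.value.lower().replace(" ", "_")
        knots = np.column_stack([r.warping.reference_knots, r.warping.sample_knots])
        header = "t0,ti"
        np.savetxt(path / f"warping_{slug}.csv", knots, delimiter=",",
                   header=header, comments="", fmt="%.12g")


def read_registered_session(path: Path | str) -> RegisteredSession:
    """Read back a registered session directory."""
    path = Path(path)
    session = read_session(path)
    if session.meta.get("registered") != "true":
        raise FacekinError(f"{path} is not a registered session directory")
    reg = RegisteredSession(session.session_id, session.patient_id,
                            session.hb_clinician)
    for ex, rec in session.recordings.items():
        slug = ex.value.lower().replace(" ", "_")
        wfile = path / f"warping_{slug}.csv"
        if not wfile.is_file():
            raise FacekinError(f"missing warping-knot file {wfile}")
        knots = np.loadtxt(wfile, delimiter=",", skiprows=1)
        w = WarpingFunction(knots[:, 0], knots[:, 1])
        k = int(session.meta.get(f"k.{ex.value}", knots.shape[0] // 2))
        reg.exercises[ex] = RegisteredExercise(
            rec, w, k, LandmarkSet(knots[:, 1], k)
        )
    return reg
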