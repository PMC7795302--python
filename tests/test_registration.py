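"""Smoothing, DTW, repetition detection, landmarks and warping."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facekin.core_io import Exercise, FacekinError, distance_curve
from facekin.registration import (
    AlignmentCurve,
    FlatSignalError,
    LandmarkSet,
    RegistrationConfig,
    RepetitionIndexError,
    WarpingFunction,
    alignment_curve,
    apply_warping,
    detect_repetitions,
    dtw_distance,
    extract_landmarks,
    fit_warping,
    read_registered_session,
    reference_landmarks,
    reference_template,
    register_recording,
    register_session,
    select_repetition,
    smooth,
    write_registered_session,
)
from facekin.synthetic import SimulationParams, simulate_session


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def test_smooth_window_one_is_identity():
    x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
    assert np.array_equal(smooth(x, 1), x)


def test_smooth_constant_unchanged():
    x = np.full(20, 2.5)
    assert np.allclose(smooth(x, 7), x)


def test_smooth_impulse_becomes_plateau():
    x = np.zeros(9)
    x[4] = 3.0
    out = smooth(x, 3)
    assert np.allclose(out[3:6], 1.0)
    assert np.allclose(out[[0, 1, 7, 8]], 0.0)


@pytest.mark.parametrize("window", [0, 2, -3])
def test_smooth_rejects_bad_window(window):
    with pytest.raises(FacekinError):
        smooth(np.arange(5.0), window)


# ---------------------------------------------------------------------------
# Alignment curves
# ---------------------------------------------------------------------------

def test_alignment_curve_smiling_is_mouth_corner_distance(noiseless_session):
    session, _ = noiseless_session
    rec = session.recordings[Exercise.SMILING]
    ac = alignment_curve(rec)
    assert np.allclose(ac.values, distance_curve(rec, 14, 15), atol=1e-15)


def test_alignment_curve_symmetric_raising_is_twice_one_side():
    p = SimulationParams(grade=1, asymmetry_attenuation=1.0, noise_sd=0.0,
                         seed=21)
    session, _ = simulate_session(p)
    rec = session.recordings[Exercise.RAISING]
    ac = alignment_curve(rec)
    assert np.allclose(ac.values, 2.0 * distance_curve(rec, 4, 2), rtol=1e-12)


def test_alignment_curve_has_k_local_maxima(noiseless_session):
    session, truth = noiseless_session
    ac = alignment_curve(session.recordings[Exercise.SMILING])
    v = ac.values
    rest = v[0]
    peaks = [i for i in range(1, v.size - 1)
             if v[i] > v[i - 1] and v[i] > v[i + 1]
             and v[i] > rest + 0.5 * (v.max() - rest)]
    assert len(peaks) == truth.params.n_repetitions


def test_alignment_curve_rejects_nonindicator(noiseless_session):
    session, _ = noiseless_session
    with pytest.raises(FacekinError):
        alignment_curve(session.recordings[Exercise.BLOWING])


# ---------------------------------------------------------------------------
# DTW
# ---------------------------------------------------------------------------

def brute_force_dtw(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive minimum over all monotone alignment paths (tiny inputs)."""
    def best(i: int, j: int) -> float:
        cost = (a[i] - b[j]) ** 2
        if i == 0 and j == 0:
            return cost
        preds = []
        if i > 0 and j > 0:
            preds.append(best(i - 1, j - 1))
        if i > 0:
            preds.append(best(i - 1, j))
        if j > 0:
            preds.append(best(i, j - 1))
        return cost + min(preds)

    return best(a.size - 1, b.size - 1)


def test_dtw_identical_sequences_zero_diagonal():
    a = np.array([0.0, 0.3, 0.9, 0.1])
    dist, path = dtw_distance(a, a)
    assert dist == 0.0
    assert path == [(i, i) for i in range(4)]


def test_dtw_small_example_matches_enumeration():
    a = np.array([0.0, 1.0, 0.0])
    b = np.array([0.0, 1.0, 1.0, 0.0])
    dist, _ = dtw_distance(a, b)
    assert dist == pytest.approx(brute_force_dtw(a, b), abs=1e-12)
    assert dist == 0.0  # an exact warping exists


def test_dtw_symmetric():
    rng = np.random.default_rng(5)
    a, b = rng.random(12), rng.random(9)
    assert dtw_distance(a, b)[0] == pytest.approx(dtw_distance(b, a)[0],
                                                  abs=1e-12)


def test_dtw_matches_brute_force_on_random_pairs():
    rng = np.random.default_rng(123)
    for _ in range(40):
        n, m = rng.integers(2, 9, size=2)
        a, b = rng.random(n), rng.random(m)
        dist, path = dtw_distance(a, b)
        assert dist == pytest.approx(brute_force_dtw(a, b), abs=1e-12)
        # path validity: monotone steps from corner to corner
        assert path[0] == (0, 0) and path[-1] == (n - 1, m - 1)
        steps = {tuple(s) for s in np.diff(np.asarray(path), axis=0)}
        assert steps <= {(1, 0), (0, 1), (1, 1)}


def test_dtw_rejects_degenerate_input():
    with pytest.raises(FacekinError):
        dtw_distance(np.array([1.0]), np.array([1.0, 2.0]))


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k", [2, 3, 4])
def test_reference_template_bump_count_and_range(k):
    tpl = reference_template(k, 300)
    assert tpl.min() == 0.0 and tpl.max() == pytest.approx(1.0, abs=1e-3)
    above = (tpl > 0.5).astype(int)
    n_bumps = int(np.sum(np.diff(above) == 1) + above[0])
    assert n_bumps == k


def test_reference_templates_distinguishable():
    t2 = reference_template(2, 150)
    t4 = reference_template(4, 150)
    assert dtw_distance(t2, t4)[0] > 0.0


def test_reference_template_rejects_bad_k():
    with pytest.raises(FacekinError):
        reference_template(5, 100)


# ---------------------------------------------------------------------------
# Repetition detection and landmarks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k", [2, 3, 4])
def test_detect_repetitions_noiseless(k):
    p = SimulationParams(grade=2, n_repetitions=k, noise_sd=0.0, seed=50 + k)
    session, _ = simulate_session(p)
    ac = alignment_curve(session.recordings[Exercise.RAISING])
    assert detect_repetitions(ac) == k


def test_detect_repetitions_flat_signal():
    flat = AlignmentCurve(Exercise.SMILING, np.linspace(0, 1, 50),
                          np.full(50, 0.04))
    with pytest.raises(FlatSignalError):
        detect_repetitions(flat)


def test_extract_landmarks_counts_and_order(noiseless_session):
    session, truth = noiseless_session
    k = truth.params.n_repetitions
    ac = alignment_curve(session.recordings[Exercise.SMILING])
    lm = extract_landmarks(ac, k)
    assert lm.times.size == 2 * k
    assert np.all(np.diff(lm.times) > 0)


def test_extract_landmarks_recovers_ground_truth(noiseless_session):
    session, truth = noiseless_session
    dt = 1.0 / truth.sampling_hz
    for ex in (Exercise.RAISING, Exercise.SMILING, Exercise.PURSING):
        ac = alignment_curve(session.recordings[ex])
        lm = extract_landmarks(ac, truth.params.n_repetitions)
        err = np.max(np.abs(lm.times - truth.landmark_times[ex]))
        assert err <= dt


# ---------------------------------------------------------------------------
# Warping functions
# ---------------------------------------------------------------------------

def test_fit_warping_identity():
    t0 = np.array([0.1, 0.3, 0.6, 0.9])
    w = fit_warping(LandmarkSet(t0, 2), t0)
    probe = np.linspace(0.0, 1.0, 100)
    assert np.allclose(w(probe), probe, atol=1e-9)


def test_fit_warping_linear_doubling():
    t0 = np.array([0.1, 0.3, 0.6, 0.9])
    w = fit_warping(LandmarkSet(2 * t0, 2), t0)
    probe = np.linspace(0.1, 0.9, 50)
    assert np.allclose(w(probe), 2 * probe, atol=1e-9)


def test_fit_warping_interpolation_conditions_exact():
    t0 = np.array([0.1, 0.25, 0.5, 0.7, 0.8, 0.95])
    ti = np.array([0.3, 0.9, 1.4, 3.0, 3.3, 4.1])
    w = fit_warping(LandmarkSet(ti, 3), t0)
    assert np.allclose(w(t0), ti, atol=1e-12)


def test_fit_warping_rejects_non_monotone():
    t0 = np.array([0.1, 0.5, 0.9])
    with pytest.raises(FacekinError):
        WarpingFunction(t0, np.array([0.2, 0.1, 0.9]))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 0.99), min_size=4, max_size=10, unique=True),
       st.lists(st.floats(0.1, 9.9), min_size=4, max_size=10, unique=True))
def test_warping_strictly_increasing_on_dense_grid(ref, sample):
    n = min(len(ref), len(sample))
    t0 = np.sort(np.asarray(ref[:n]))
    ti = np.sort(np.asarray(sample[:n]))
    if np.any(np.diff(t0) < 1e-6) or np.any(np.diff(ti) < 1e-6):
        return
    w = WarpingFunction(t0, ti)
    probe = np.linspace(t0[0] - 0.2, t0[-1] + 0.2, 500)
    assert np.all(np.diff(w(probe)) > 0)
    assert np.allclose(w.inverse(w(probe)), probe, atol=1e-3)


# ---------------------------------------------------------------------------
# Applying warpings and selecting repetitions
# ---------------------------------------------------------------------------

def test_apply_warping_identity_keeps_recording(noiseless_session):
    session, _ = noiseless_session
    rec = session.recordings[Exercise.SMILING]
    t0 = np.array([rec.times[0], rec.times[-1]])
    w = WarpingFunction(t0, t0)
    out = apply_warping(rec, w, rec.times)
    assert np.array_equal(out.times, rec.times)
    assert np.allclose(out.positions, rec.positions, atol=1e-12)


def test_apply_warping_output_times_equal_grid(noiseless_session):
    session, _ = noiseless_session
    rec = session.recordings[Exercise.SMILING]
    reg = register_recording(rec)
    grid = np.linspace(0, 1, 73)
    w = reg.warping
    out = apply_warping(rec, w, grid)
    assert np.array_equal(out.times, grid)


def test_apply_warping_aligns_different_speed_profiles():
    """Two noiseless sessions at different tempo match after registration."""
    curves = []
    for gamma in (0.7, 1.3):
        p = SimulationParams(grade=1, speed_profile=gamma, noise_sd=0.0,
                             n_repetitions=3, seed=33)
        session, _ = simulate_session(p)
        rec = session.recordings[Exercise.SMILING]
        ac = alignment_curve(rec)
        lm = extract_landmarks(ac, 3)
        w = fit_warping(lm, reference_landmarks(3))
        grid = np.linspace(0, 1, 200)
        reg = apply_warping(rec, w, grid)
        curves.append(distance_curve(reg, 14, 15))
    a, b = curves
    rms = np.sqrt(np.mean((a - b) ** 2))
    assert rms <= 0.02 * (a.max() - a.min())


def test_select_repetition_middle_of_three(noiseless_session):
    session, truth = noiseless_session
    rec = session.recordings[Exercise.SMILING]
    reg = register_recording(rec)
    t0 = reference_landmarks(3)
    # the selected window (midpoints toward neighbours) sits strictly
    # inside the middle third of the registered timeline
    lo = 0.5 * (t0[1] + t0[2])
    hi = 0.5 * (t0[3] + t0[4])
    assert 1 / 3 < lo < hi < 2 / 3


def test_select_repetition_contains_exactly_one_bump(noiseless_session):
    session, _ = noiseless_session
    rec = session.recordings[Exercise.SMILING]
    reg = register_recording(rec)
    sel = reg.recording
    v = distance_curve(sel, 14, 15)
    rest = v[0]
    amp = v.max() - rest
    above = v > rest + 0.5 * amp
    n_intervals = int(np.sum(np.diff(above.astype(int)) == 1)
                      + (1 if above[0] else 0))
    assert n_intervals == 1


def test_select_repetition_index_out_of_range(noiseless_session):
    session, _ = noiseless_session
    rec = session.recordings[Exercise.SMILING]
    full = apply_warping(rec,
                         fit_warping(extract_landmarks(alignment_curve(rec), 3),
                                     reference_landmarks(3)),
                         np.linspace(0, 1, 100))
    with pytest.raises(RepetitionIndexError):
        select_repetition(full, reference_landmarks(3), index=5)


def test_select_repetition_index_two_of_two():
    p = SimulationParams(grade=1, n_repetitions=2, noise_sd=0.0, seed=60)
    session, _ = simulate_session(p)
    reg = register_recording(session.recordings[Exercise.SMILING])
    assert reg.k_repetitions == 2
    assert reg.recording.times[0] == 0.0 and reg.recording.times[-1] == 1.0


# ---------------------------------------------------------------------------
# Registered-session serialization
# ---------------------------------------------------------------------------

def test_registered_session_round_trip(tmp_path, noiseless_session):
    session, _ = noiseless_session
    reg = register_session(session, strict=True)
    write_registered_session(reg, tmp_path / "r")
    back = read_registered_session(tmp_path / "r")
    assert back.session_id == reg.session_id
    assert set(back.exercises) == set(reg.exercises)
    for ex in reg.exercises:
        a, b = reg.exercises[ex], back.exercises[ex]
        assert a.k_repetitions == b.k_repetitions
        assert np.allclose(a.recording.positions, b.recording.positions,
                           atol=1e-9)
        probe = np.linspace(0, 1, 50)
        assert np.allclose(a.warping(probe), b.warping(probe), atol=1e-9)
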