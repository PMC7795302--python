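"""Shared fixtures: tiny hand-built recordings and a reusable synthetic cohort."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from facekin.core_io import Exercise, ExerciseRecording, Session, adjust_grade
from facekin.health_scores import fit_all_flr, score_dataset, scores_wide
from facekin.indicators import compute_all
from facekin.registration import register_session
from facekin.synthetic import SimulationParams, simulate_cohort, simulate_session


def make_recording(exercise: Exercise, times: np.ndarray,
                   positions: np.ndarray) -> ExerciseRecording:
    return ExerciseRecording(exercise, times, positions)


@pytest.fixture
def static_recording() -> ExerciseRecording:
    """All 21 points frozen at distinct positions over 10 samples."""
    rng = np.random.default_rng(11)
    base = rng.normal(size=(21, 3))
    times = np.linspace(0.0, 1.0, 10)
    pos = np.broadcast_to(base, (10, 21, 3)).copy()
    return ExerciseRecording(Exercise.SMILING, times, pos)


@pytest.fixture
def random_recording() -> ExerciseRecording:
    rng = np.random.default_rng(42)
    times = np.sort(rng.uniform(0, 5, 40))
    times += np.arange(40) * 1e-6  # enforce strict increase
    pos = rng.normal(scale=0.05, size=(40, 21, 3))
    return ExerciseRecording(Exercise.SMILING, times, pos)


@pytest.fixture
def noiseless_session():
    """One noiseless 3-repetition grade-3 session plus ground truth."""
    params = SimulationParams(grade=3, asymmetry_attenuation=0.5,
                              intensity_scale=0.7, speed_profile=0.9,
                              n_repetitions=3, noise_sd=0.0, seed=314)
    return simulate_session(params)


@pytest.fixture(scope="session")
def pipeline120():
    """Full pipeline artifacts on the default 120-session cohort.

    Session-scoped because registration dominates the suite's runtime;
    every consumer treats the artifacts as read-only.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sessions, truths = simulate_cohort(120, seed=20260101)
        sets = [compute_all(register_session(s)) for s in sessions]
        models = fit_all_flr(sets)
        table = score_dataset(models, sets)
    wide = scores_wide(table).loc[[s.session_id for s in sessions]]
    grades = np.array([adjust_grade(s.hb_clinician).adjusted for s in sessions])
    return {
        "sessions": sessions,
        "truths": truths,
        "indicator_sets": sets,
        "flr_models": models,
        "score_table": table,
        "scores_wide": wide,
        "grades": grades,
    }
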