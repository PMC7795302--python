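"""Functional logistic regression: oracles, scoring and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import rankdata

from facekin.core_io import FacekinError
from facekin.health_scores import (
    BasisSpec,
    FLRConfig,
    GridMismatchError,
    OneClassError,
    _functional_design,
    fit_flr,
    score,
    score_correlogram,
    score_dataset,
    spearman_vs_grade,
)
from facekin.indicators import IndicatorCurve

GRID = np.linspace(0.0, 1.0, 60)


def curves_from_matrix(values: np.ndarray, label: str = "smiling.symmetry",
                       prefix: str = "s") -> list[IndicatorCurve]:
    return [IndicatorCurve(label, GRID, row, f"{prefix}{i}")
            for i, row in enumerate(values)]


# ---------------------------------------------------------------------------
# Basis
# ---------------------------------------------------------------------------

def test_bspline_basis_partition_of_unity():
    basis = BasisSpec(dim=8, degree=3)
    B = basis.design(GRID)
    assert B.shape == (GRID.size, 8)
    assert np.allclose(B.sum(axis=1), 1.0, atol=1e-12)


def test_constant_basis_integrates_to_curve_mean():
    basis = BasisSpec(dim=1, degree=0)
    x = np.sin(GRID * 3.0)[None, :]
    z = _functional_design(x, GRID, basis)
    assert z[0, 0] == pytest.approx(np.trapezoid(x[0], GRID), abs=1e-12)


# ---------------------------------------------------------------------------
# Fitting: oracles
# ---------------------------------------------------------------------------

def test_dim1_constant_curves_reduce_to_scalar_logistic():
    """With a constant basis and flat curves the FLR must coincide with
    ordinary logistic regression on the curve mean (statsmodels oracle)."""
    import statsmodels.api as sm

    rng = np.random.default_rng(2)
    means = rng.normal(size=40)
    y = (means + rng.normal(scale=1.0, size=40) > 0).astype(float)
    if y.min() == y.max():  # safeguard; not expected with this seed
        y[0] = 1 - y[0]
    values = np.repeat(means[:, None], GRID.size, axis=1)
    curves = curves_from_matrix(values)
    groups = ["Healthy" if yi else "Sick" for yi in y]
    cfg = FLRConfig(basis_dim=1, basis_degree=0, penalty=0.0)
    model = fit_flr(curves, groups, cfg)
    sm_fit = sm.Logit(y, sm.add_constant(means)).fit(disp=0)
    assert model.intercept == pytest.approx(sm_fit.params[0], abs=1e-6)
    assert model.beta_coefficients[0] == pytest.approx(sm_fit.params[1],
                                                       abs=1e-6)


def test_penalized_fit_agrees_with_generic_optimizer():
    """The L-BFGS fit must match a derivative-free optimizer on the same
    penalized objective to 1e-4 in every parameter."""
    rng = np.random.default_rng(3)
    values = rng.normal(size=(30, GRID.size))
    y = rng.integers(0, 2, size=30).astype(float)
    y[:3], y[-3:] = 1, 0
    curves = curves_from_matrix(values)
    groups = ["Healthy" if yi else "Sick" for yi in y]
    cfg = FLRConfig(basis_dim=4, basis_degree=2, penalty=0.5)
    model = fit_flr(curves, groups, cfg)

    basis = BasisSpec(4, 2)
    Z = _functional_design(values, GRID, basis)

    def objective(theta):
        eta = theta[0] + Z @ theta[1:]
        return (np.sum(np.logaddexp(0, eta) - y * eta)
                + 0.5 * cfg.penalty * theta[1:] @ theta[1:])

    res = minimize(objective, np.zeros(5), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    got = np.concatenate([[model.intercept], model.beta_coefficients])
    assert np.allclose(got, res.x, atol=1e-4)


def test_no_signal_mean_score_near_half():
    rng = np.random.default_rng(4)
    values = rng.normal(size=(40, GRID.size))
    curves = curves_from_matrix(values)
    groups = ["Healthy"] * 20 + ["Sick"] * 20
    model = fit_flr(curves, groups)
    scores = [score(model, c) for c in curves]
    assert abs(np.mean(scores) - 0.5) < 0.1


def test_separated_groups_reach_high_auc():
    """Well-separated synthetic symmetry curves give in-sample AUC >= 0.95."""
    rng = np.random.default_rng(5)
    healthy = 0.98 + 0.01 * rng.normal(size=(25, GRID.size))
    dip = np.exp(-0.5 * ((GRID - 0.5) / 0.15) ** 2)
    sick = 0.95 - 0.3 * dip[None, :] + 0.02 * rng.normal(size=(20, GRID.size))
    curves = curves_from_matrix(np.vstack([healthy, sick]))
    groups = ["Healthy"] * 25 + ["Sick"] * 20
    model = fit_flr(curves, groups)
    s = np.array([score(model, c) for c in curves])
    y = np.array([1] * 25 + [0] * 20)
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - 25 * 26 / 2) / (25 * 20)
    assert auc >= 0.95


def test_parameter_recovery_beats_null():
    """Curves simulated from a known (alpha, beta(t)): the fitted beta is
    closer to truth than the zero function in >= 19/20 replicates."""
    basis = BasisSpec(4, 2)
    true_coef = np.array([1.5, -2.0, 2.0, -1.0])
    beta_true = basis.evaluate_beta(true_coef, GRID)
    cfg = FLRConfig(basis_dim=4, basis_degree=2, penalty=1e-6)
    wins = 0
    rng = np.random.default_rng(6)
    B = basis.design(GRID)
    for _ in range(20):
        # smooth functional covariates with variance along the basis
        values = rng.normal(scale=3.0, size=(200, 4)) @ B.T
        values += 0.1 * rng.normal(size=(200, GRID.size))
        Z = _functional_design(values, GRID, basis)
        eta = 0.3 + Z @ true_coef
        y = rng.random(200) < 1 / (1 + np.exp(-eta))
        curves = curves_from_matrix(values)
        groups = ["Healthy" if yi else "Sick" for yi in y]
        model = fit_flr(curves, groups, cfg)
        beta_hat = model.beta(GRID)
        rms_fit = np.sqrt(np.mean((beta_hat - beta_true) ** 2))
        rms_null = np.sqrt(np.mean(beta_true ** 2))
        wins += rms_fit < rms_null
    assert wins >= 19


def test_fit_flr_one_class_error():
    curves = curves_from_matrix(np.zeros((4, GRID.size)))
    with pytest.raises(OneClassError):
        fit_flr(curves, ["Healthy"] * 4)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def test_score_closed_form_at_zero_parameters():
    curves = curves_from_matrix(np.ones((6, GRID.size)))
    model = fit_flr(curves, ["Healthy"] * 3 + ["Sick"] * 3)
    model.intercept = 0.0
    model.beta_coefficients = np.zeros_like(model.beta_coefficients)
    assert score(model, curves[0]) == pytest.approx(0.5, abs=1e-12)


def test_score_monotone_in_beta_aligned_signal():
    rng = np.random.default_rng(7)
    values = rng.normal(size=(30, GRID.size))
    y = (values.mean(axis=1) > 0)
    curves = curves_from_matrix(values)
    model = fit_flr(curves, ["Healthy" if yi else "Sick" for yi in y])
    beta = model.beta(GRID)
    base = curves[0]
    s0 = score(model, base)
    boosted = IndicatorCurve(base.label, GRID, base.values + 0.5 * beta, "b")
    assert score(model, boosted) > s0


def test_score_grid_mismatch():
    curves = curves_from_matrix(np.ones((6, GRID.size)))
    model = fit_flr(curves, ["Healthy"] * 3 + ["Sick"] * 3)
    other = IndicatorCurve("smiling.symmetry", np.linspace(0, 1, 30),
                           np.ones(30))
    with pytest.raises(GridMismatchError):
        score(model, other)


def test_score_dataset_counts_and_determinism(pipeline120):
    table = pipeline120["score_table"]
    sets = pipeline120["indicator_sets"]
    assert len(table) == 14 * len(sets)
    finite = table["score"].dropna()
    assert ((finite >= 0) & (finite <= 1)).all()
    rerun = score_dataset(pipeline120["flr_models"], sets[:5])
    again = score_dataset(pipeline120["flr_models"], sets[:5])
    pd.testing.assert_frame_equal(rerun, again)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def brute_spearman(x, y):
    rx, ry = rankdata(x), rankdata(y)
    rx, ry = rx - rx.mean(), ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def test_spearman_perfectly_decreasing_is_minus_one():
    table = pd.DataFrame({
        "session_id": [f"s{i}" for i in range(4)],
        "label": ["lips.intensity"] * 4,
        "score": [0.9, 0.7, 0.5, 0.2],
    })
    grades = {f"s{i}": g for i, g in enumerate([1, 2, 3, 6])}
    out = spearman_vs_grade(table, grades)
    assert out.loc[0, "rho"] == pytest.approx(-1.0)


def test_spearman_matches_rank_oracle():
    scores = [0.1, 0.9, 0.4, 0.4, 0.7]
    grades = [3, 1, 2, 6, 1]
    table = pd.DataFrame({
        "session_id": [f"s{i}" for i in range(5)],
        "label": ["smiling.symmetry"] * 5,
        "score": scores,
    })
    out = spearman_vs_grade(table, {f"s{i}": g for i, g in enumerate(grades)})
    assert out.loc[0, "rho"] == pytest.approx(brute_spearman(scores, grades),
                                              abs=1e-12)


def test_spearman_null_scores_small_rho():
    rng = np.random.default_rng(8)
    table = pd.DataFrame({
        "session_id": [f"s{i}" for i in range(100)],
        "label": ["teeth.symmetry"] * 100,
        "score": rng.random(100),
    })
    grades = {f"s{i}": int(g) for i, g in
              enumerate(rng.choice([1, 2, 3, 6], size=100))}
    out = spearman_vs_grade(table, grades)
    assert abs(out.loc[0, "rho"]) < 0.3


def test_correlogram_symmetric_unit_diagonal(pipeline120):
    corr = score_correlogram(pipeline120["score_table"])
    assert corr.shape == (14, 14)
    assert np.allclose(corr.values, corr.values.T, equal_nan=True)
    assert np.allclose(np.diag(corr.values), 1.0)


def test_correlogram_duplicated_column_is_one():
    rng = np.random.default_rng(9)
    n = 20
    rows = []
    for i in range(n):
        v = rng.random()
        rows.append((f"s{i}", "smiling.symmetry", v))
        rows.append((f"s{i}", "teeth.symmetry", v))
    table = pd.DataFrame(rows, columns=["session_id", "label", "score"])
    corr = score_correlogram(table)
    assert corr.loc["smiling.symmetry", "teeth.symmetry"] == pytest.approx(1.0)


def test_correlogram_shared_driver_positive(pipeline120):
    """Smiling and baring share the attenuation driver, so their symmetry
    scores must correlate positively across the cohort."""
    corr = score_correlogram(pipeline120["score_table"])
    assert corr.loc["smiling.symmetry", "teeth.symmetry"] > 0.3


def test_correlogram_needs_three_sessions():
    table = pd.DataFrame({
        "session_id": ["a", "b"],
        "label": ["lips.speed"] * 2,
        "score": [0.1, 0.2],
    })
    with pytest.raises(FacekinError):
        score_correlogram(table)
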