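"""Stage 2 - health scores via scalar-on-function logistic regression.

Each indicator curve X(t) is reduced to a single *health score*: the
probability that the session belongs to the Healthy group, under

    p = 1 / (1 + exp(-alpha - integral X(t) beta(t) dt)),

with the functional coefficient beta(t) expanded in a B-spline basis and
the integral evaluated by trapezoid quadrature on the registered unit
grid.  The model is trained on the two extreme groups only - Healthy =
adjusted grade 1, Sick = adjusted grade 6 - and then scores *every*
session, giving intermediate grades intermediate scores.  A small ridge
penalty on the basis coefficients (intercept unpenalized) keeps the fit
finite when the extreme groups are linearly separable, which rich curves
with modest group sizes routinely are.

Speed indicators enter as warping-minus-identity residuals by default so
the deterministic diagonal trend of a warping function does not dominate
the basis expansion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline
from scipy.stats import spearmanr

from .core_io import FacekinError, adjust_grade
from .indicators import INDICATOR_LABELS, IndicatorCurve, IndicatorSet

__all__ = [
    "OneClassError",
    "GridMismatchError",
    "BasisSpec",
    "FLRConfig",
    "FLRModel",
    "fit_flr",
    "score",
    "fit_all_flr",
    "score_dataset",
    "spearman_vs_grade",
    "score_correlogram",
]


class OneClassError(FacekinError):
    """Training data contains only one of the two groups."""


class GridMismatchError(FacekinError):
    """Curve grid differs from the grid the model was fitted on."""


# ---------------------------------------------------------------------------
# Basis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BasisSpec:
    """B-spline basis for beta(t) on the registered domain."""

    dim: int = 8
    degree: int = 3
    domain: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise FacekinError("basis dimension must be >= 1")
        if self.degree < 0 or self.degree >= self.dim + 1:
            raise FacekinError("invalid basis degree")

    def knots(self) -> np.ndarray:
        lo, hi = self.domain
        n_interior = self.dim - self.degree - 1
        if n_interior < 0:
            raise FacekinError("dim must be >= degree + 1")
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
        return np.concatenate([
            np.full(self.degree + 1, lo), interior, np.full(self.degree + 1, hi)
        ])

    def design(self, t: np.ndarray) -> np.ndarray:
        """Basis evaluation matrix of shape (len(t), dim)."""
        t = np.clip(np.asarray(t, dtype=float), *self.domain)
        mat = BSpline.design_matrix(t, self.knots(), self.degree,
                                    extrapolate=False)
        return np.asarray(mat.todense())

    def evaluate_beta(self, coefs: np.ndarray, t: np.ndarray) -> np.ndarray:
        return self.design(t) @ np.asarray(coefs, dtype=float)


@dataclass
class FLRConfig:
    basis_dim: int = 8
    basis_degree: int = 3
    penalty: float = 1e-3
    speed_as_residual: bool = True
    max_iter: int = 500
    tol: float = 1e-10


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class FLRModel:
    """Fitted scalar-on-function logistic model for one indicator label."""

    indicator_label: str
    intercept: float
    beta_coefficients: np.ndarray
    basis: BasisSpec
    penalty: float
    grid: np.ndarray
    n_healthy: int
    n_sick: int
    converged: bool
    separation_suspected: bool = False

    def beta(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the functional coefficient beta(t)."""
        return self.basis.evaluate_beta(self.beta_coefficients, t)


def _trapezoid_weights(t: np.ndarray) -> np.ndarray:
    w = np.zeros_like(t)
    dt = np.diff(t)
    w[:-1] += dt / 2
    w[1:] += dt / 2
    return w


def _prepare_values(label: str, curve: IndicatorCurve,
                    speed_as_residual: bool = True) -> np.ndarray:
    """Covariate values entering the FLR (speed curves as residuals)."""
    if speed_as_residual and label.endswith(".speed"):
        return curve.values - curve.times
    return curve.values


def _functional_design(values: np.ndarray, t: np.ndarray,
                       basis: BasisSpec) -> np.ndarray:
    """Quadrature features z_j = integral X(t) B_j(t) dt, shape (n, dim)."""
    w = _trapezoid_weights(t)
    B = basis.design(t)
    return (values * w) @ B


def _penalized_logistic(Z: np.ndarray, y: np.ndarray, penalty: float,
                        max_iter: int = 500, tol: float = 1e-10
                        ) -> tuple[float, np.ndarray, bool]:
    """Penalized-ML logistic fit; intercept unpenalized. Returns (a, c, ok)."""
    n, d = Z.shape

    def nll_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        a, c = theta[0], theta[1:]
        eta = a + Z @ c
        # stable log(1 + exp(eta))
        nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
        nll += 0.5 * penalty * float(c @ c)
        p = 1.0 / (1.0 + np.exp(-eta))
        g = np.empty(d + 1)
        g[0] = np.sum(p - y)
        g[1:] = Z.T @ (p - y) + penalty * c
        return nll, g

    theta0 = np.zeros(d + 1)
    res = optimize.minimize(nll_grad, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": max_iter, "gtol": tol,
                                     "ftol": 1e-14})
    return float(res.x[0]), res.x[1:].copy(), bool(res.success)


def fit_flr(curves: list[IndicatorCurve], groups: list[str],
            config: FLRConfig | None = None) -> FLRModel:
    """Fit one FLR on Healthy/Sick-labelled indicator curves of one label.

    ``groups`` entries are ``"Healthy"`` or ``"Sick"`` (Healthy codes as 1).
    """
    config = config or FLRConfig()
    if len(curves) != len(groups) or not curves:
        raise FacekinError("need one group label per curve")
    labels = {c.label for c in curves}
    if len(labels) != 1:
        raise FacekinError("all curves must share one indicator label")
    label = labels.pop()
    y = np.array([1.0 if g == "Healthy" else 0.0 for g in groups])
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise OneClassError("both Healthy and Sick examples are required")
    if min(n1, n0) < 3:
        warnings.warn("fewer than 3 curves in one group; fit may be fragile",
                      stacklevel=2)
    grid = curves[0].times
    for c in curves[1:]:
        if c.times.shape != grid.shape or not np.allclose(c.times, grid):
            raise GridMismatchError("curves must share a common grid")
    basis = BasisSpec(config.basis_dim, config.basis_degree,
                      (float(grid[0]), float(grid[-1])))
    X = np.vstack([_prepare_values(label, c, config.speed_as_residual)
                   for c in curves])
    Z = _functional_design(X, grid, basis)
    alpha, coefs, ok = _penalized_logistic(Z, y, config.penalty,
                                           config.max_iter, config.tol)
    eta = alpha + Z @ coefs
    separated = bool(np.all((eta > 0) == (y > 0.5)) and np.min(np.abs(eta)) > 8.0)
    if separated and config.penalty == 0:
        warnings.warn(f"{label}: complete separation without penalty; "
                      "estimates unbounded", stacklevel=2)
    return FLRModel(label, alpha, coefs, basis, config.penalty, grid.copy(),
                    n1, n0, ok, separated)


def score(model: FLRModel, curve: IndicatorCurve,
          speed_as_residual: bool = True) -> float:
    """Health score of one curve under a fitted model (in (0, 1))."""
    if curve.times.shape != model.grid.shape or \
            not np.allclose(curve.times, model.grid):
        raise GridMismatchError(
            f"{curve.label}: curve grid differs from model grid")
    x = _prepare_values(model.indicator_label, curve, speed_as_residual)
    z = _functional_design(x[None, :], model.grid, model.basis)[0]
    eta = model.intercept + z @ model.beta_coefficients
    return float(1.0 / (1.0 + np.exp(-eta)))


# ---------------------------------------------------------------------------
# Cohort-level fitting and scoring
# ---------------------------------------------------------------------------

def fit_all_flr(indicator_sets: list[IndicatorSet],
                config: FLRConfig | None = None) -> dict[str, FLRModel]:
    """Fit one FLR per indicator label on the extreme-grade groups.

    Healthy = sessions with adjusted grade 1; Sick = adjusted grade 6
    (raw 5 and 6).  Sessions without a clinician grade are ignored for
    training.
    """
    models: dict[str, FLRModel] = {}
    for label in INDICATOR_LABELS:
        curves: list[IndicatorCurve] = []
        groups: list[str] = []
        for s in indicator_sets:
            if s.hb_clinician is None or label not in s.curves:
                continue
            adj = adjust_grade(s.hb_clinician).adjusted
            if adj == 1:
                groups.append("Healthy")
            elif adj == 6:
                groups.append("Sick")
            else:
                continue
            curves.append(s.curves[label])
        if not curves:
            continue
        try:
            models[label] = fit_flr(curves, groups, config)
        except FacekinError as err:
            warnings.warn(f"{label}: FLR fit failed ({err})", stacklevel=2)
    return models


def score_dataset(models: dict[str, FLRModel],
                  indicator_sets: list[IndicatorSet],
                  speed_as_residual: bool = True) -> pd.DataFrame:
    """Score every session under every per-label model.

    Returns a long table (session_id, label, score); absent indicators
    appear with a NaN score so the absence stays visible downstream.
    """
    rows = []
    for s in indicator_sets:
        for label in INDICATOR_LABELS:
            model = models.get(label)
            curve = s.curves.get(label)
            if model is None or curve is None:
                rows.append((s.session_id, label, np.nan))
                continue
            rows.append((s.session_id, label,
                         score(model, curve, speed_as_residual)))
    return pd.DataFrame(rows, columns=["session_id", "label", "score"])


def scores_wide(score_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long score table to one row per session."""
    return score_table.pivot(index="session_id", columns="label",
                             values="score")


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def spearman_vs_grade(score_table: pd.DataFrame,
                      grades: dict[str, int]) -> pd.DataFrame:
    """Spearman rank correlation of each label's scores with the HB grade.

    ``grades`` maps session_id to the adjusted grade. Mid-rank ties and a
    two-sided p-value via the t approximation (scipy's default). Labels
    with constant input are flagged with NaN rho. Sorted ascending by rho
    (strongest negative association first).
    """
    rows = []
    for label, sub in score_table.groupby("label"):
        pairs = [(r.score, grades[r.session_id]) for r in sub.itertuples()
                 if r.session_id in grades and np.isfinite(r.score)]
        if len(pairs) < 3:
            rows.append((label, np.nan, np.nan))
            continue
        s, g = zip(*pairs)
        if len(set(s)) == 1 or len(set(g)) == 1:
            rows.append((label, np.nan, np.nan))
            continue
        rho, p = spearmanr(s, g)
        rows.append((label, float(rho), float(p)))
    df = pd.DataFrame(rows, columns=["label", "rho", "p_value"])
    return df.sort_values("rho", na_position="last").reset_index(drop=True)


def score_correlogram(score_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of the per-label health scores.

    Pairwise-complete observations; degenerate (constant) columns yield
    NaN off-diagonals but keep a unit diagonal.
    """
    wide = scores_wide(score_table)
    if wide.shape[0] < 3:
        raise FacekinError("need at least 3 sessions for a correlogram")
    corr = wide.corr(method="pearson", min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    return corr
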