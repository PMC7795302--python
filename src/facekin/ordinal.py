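"""Stage 3 - ordinal House-Brackmann classification.

The per-session health scores feed a weighted cumulative-logit
(proportional-odds) model over the adjusted grades (1, 2, 3, 6):

    P(HB <= level_j) = 1 / (1 + exp(-(alpha_j + sum_i beta_i p_i)))

with strictly increasing thresholds alpha_j (one per non-top level) and
level-independent slopes beta_i.  Class probabilities are differences of
consecutive cumulative probabilities; the predicted grade is the argmax
(ties break toward the lower, healthier grade).  To offset the dominance
of grade 1 in the data, each session is weighted by the inverse frequency
of its class.  Predictors are chosen by bidirectional stepwise search
minimizing AIC from the empty model.

Threshold ordering is enforced by parametrizing the gaps on the log scale;
fitting is quasi-Newton (L-BFGS-B) on the negative weighted log-likelihood
with an analytic gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy import optimize

from .core_io import ADJUSTED_LEVELS, FacekinError

__all__ = [
    "OLRModel",
    "SingleClassError",
    "inverse_frequency_weights",
    "cumulative_logit_nll_grad",
    "fit_olr",
    "class_probabilities",
    "predict",
    "stepwise_select",
    "argmax_grade",
    "confusion_matrix",
    "accuracy_report",
    "AccuracyReport",
]

LEVELS = ADJUSTED_LEVELS  # (1, 2, 3, 6)


class SingleClassError(FacekinError):
    """Fewer than two grade levels present in the training data."""


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

def inverse_frequency_weights(grades: list[int] | np.ndarray) -> np.ndarray:
    """Per-session weight 1 / count(class of that session).

    Balances the per-class contribution to the fit; the total weight
    equals the number of classes present.
    """
    grades = np.asarray(grades)
    if grades.size == 0:
        raise FacekinError("no grades given")
    for g in np.unique(grades):
        if g not in LEVELS:
            raise FacekinError(f"grade {g} is not an adjusted level")
    counts = {g: int(np.sum(grades == g)) for g in np.unique(grades)}
    return np.array([1.0 / counts[g] for g in grades])


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def cumulative_logit_nll_grad(alphas: np.ndarray, betas: np.ndarray,
                              X: np.ndarray, y_idx: np.ndarray,
                              weights: np.ndarray
                              ) -> tuple[float, np.ndarray, np.ndarray]:
    """Weighted negative log-likelihood and its analytic gradient.

    Direct parametrization: ``alphas`` are the J-1 thresholds (need not be
    ordered for evaluation), ``betas`` the slopes; ``y_idx`` holds class
    indices 0..J-1.  Returns (nll, d_nll/d_alphas, d_nll/d_betas).
    """
    n, d = X.shape
    J = alphas.size + 1
    eta = alphas[None, :] + (X @ betas)[:, None]  # (n, J-1)
    F = _sigmoid(eta)
    Fext = np.hstack([np.zeros((n, 1)), F, np.ones((n, 1))])  # (n, J+1)
    prob = Fext[np.arange(n), y_idx + 1] - Fext[np.arange(n), y_idx]
    prob = np.clip(prob, 1e-300, None)
    nll = -float(np.sum(weights * np.log(prob)))
    # gradient
    fprime = F * (1.0 - F)  # sigma'(eta), (n, J-1)
    g_alpha = np.zeros(J - 1)
    g_x = np.zeros(n)  # d nll / d (x beta) per sample
    for j in range(J - 1):
        contrib = np.zeros(n)
        upper = y_idx == j        # eta_j is the upper cumulative of class j
        lower = y_idx == j + 1    # eta_j is the lower cumulative of class j+1
        contrib[upper] = fprime[upper, j] / prob[upper]
        contrib[lower] -= fprime[lower, j] / prob[lower]
        g_alpha[j] = -float(np.sum(weights * contrib))
        g_x -= weights * contrib
    g_beta = X.T @ g_x
    return nll, g_alpha, g_beta


def _pack(alphas: np.ndarray, betas: np.ndarray) -> np.ndarray:
    """Ordered thresholds -> unconstrained (a1, log-gaps, betas)."""
    gaps = np.diff(alphas)
    return np.concatenate([[alphas[0]], np.log(gaps), betas])


def _unpack(theta: np.ndarray, J: int) -> tuple[np.ndarray, np.ndarray]:
    a1 = theta[0]
    gaps = np.exp(theta[1:J - 1])
    alphas = a1 + np.concatenate([[0.0], np.cumsum(gaps)])
    return alphas, theta[J - 1:]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class OLRModel:
    """Fitted weighted proportional-odds model."""

    class_levels: tuple[int, ...]
    thresholds: np.ndarray  # strictly increasing, one per non-top level
    coefficients: np.ndarray  # one per selected label
    selected_labels: tuple[str, ...]
    weights_used: np.ndarray
    aic: float
    loglik: float
    n_obs: int
    converged: bool
    inclusion_order: tuple[str, ...] = ()
    standard_errors: np.ndarray | None = None

    @property
    def n_parameters(self) -> int:
        return self.thresholds.size + self.coefficients.size


def _as_matrix(scores: pd.DataFrame | np.ndarray,
               labels: list[str] | None) -> tuple[np.ndarray, list[str]]:
    if isinstance(scores, pd.DataFrame):
        if labels is None:
            labels = list(scores.columns)
        X = scores[labels].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(scores, dtype=float))
        if labels is None:
            labels = [f"x{i}" for i in range(X.shape[1])]
    if np.any(~np.isfinite(X)):
        raise FacekinError("missing scores among selected labels")
    return X, labels


def fit_olr(scores: pd.DataFrame | np.ndarray,
            grades: list[int] | np.ndarray,
            weights: np.ndarray | None = None,
            labels: list[str] | None = None,
            tol: float = 1e-8,
            max_iter: int = 500,
            compute_se: bool = False) -> OLRModel:
    """Weighted maximum-likelihood fit of the cumulative-logit model.

    ``scores`` is (n, d) (a DataFrame with label columns or an array; d may
    be 0 for the intercept-only model); ``grades`` holds adjusted levels.
    """
    grades = np.asarray(grades)
    present = [g for g in LEVELS if np.any(grades == g)]
    if len(present) < 2:
        raise SingleClassError("need at least two grade levels")
    levels = tuple(present)
    J = len(levels)
    level_idx = {g: i for i, g in enumerate(levels)}
    y_idx = np.array([level_idx[g] for g in grades])
    if labels is None:
        X, labels = _as_matrix(scores, None)
    elif labels:
        X, labels = _as_matrix(scores, list(labels))
    else:
        X = np.zeros((grades.size, 0))
        labels = []
    if weights is None:
        weights = np.ones(grades.size)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise FacekinError("weights must be positive")
    # canonicalize to mean 1: the ML fit is invariant to the overall weight
    # scale, and this keeps the log-likelihood (hence AIC) on the usual
    # per-observation scale whatever convention the caller's weights follow
    wnorm = weights * (grades.size / weights.sum())

    # start: thresholds at weighted empirical cumulative logits, betas at 0
    wsum = np.array([np.sum(wnorm[y_idx == j]) for j in range(J)])
    cum = np.cumsum(wsum)[:-1] / np.sum(wsum)
    cum = np.clip(cum, 1e-3, 1 - 1e-3)
    alphas0 = np.log(cum / (1 - cum))
    alphas0 = np.maximum.accumulate(alphas0 + 1e-6 * np.arange(J - 1))
    if np.any(np.diff(alphas0) <= 0):  # guard pathological starts
        alphas0 = np.linspace(-1, 1, J - 1)
    theta0 = _pack(alphas0, np.zeros(X.shape[1]))

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        alphas, betas = _unpack(theta, J)
        nll, ga, gb = cumulative_logit_nll_grad(alphas, betas, X, y_idx, wnorm)
        # chain rule to (a1, log-gaps, betas)
        g = np.empty_like(theta)
        g[0] = ga.sum()
        gaps = np.exp(theta[1:J - 1])
        for m in range(J - 2):
            g[1 + m] = gaps[m] * ga[m + 1:].sum()
        g[J - 1:] = gb
        return nll, g

    res = optimize.minimize(objective, theta0, jac=True, method="L-BFGS-B",
                            options={"maxiter": max_iter, "gtol": tol,
                                     "ftol": 1e-15})
    alphas, betas = _unpack(res.x, J)
    nll, _, _ = cumulative_logit_nll_grad(alphas, betas, X, y_idx, wnorm)
    n_params = (J - 1) + X.shape[1]
    aic = 2.0 * n_params + 2.0 * nll

    se = None
    if compute_se:
        se = _standard_errors(alphas, betas, X, y_idx, wnorm)

    return OLRModel(
        class_levels=levels,
        thresholds=alphas,
        coefficients=betas,
        selected_labels=tuple(labels),
        weights_used=weights,
        aic=float(aic),
        loglik=float(-nll),
        n_obs=grades.size,
        converged=bool(res.success),
        standard_errors=se,
    )


def _standard_errors(alphas: np.ndarray, betas: np.ndarray, X: np.ndarray,
                     y_idx: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """SEs for (alphas, betas) from a finite-difference observed information."""
    theta = np.concatenate([alphas, betas])
    J = alphas.size + 1

    def grad(th: np.ndarray) -> np.ndarray:
        _, ga, gb = cumulative_logit_nll_grad(th[:J - 1], th[J - 1:],
                                              X, y_idx, weights)
        return np.concatenate([ga, gb])

    d = theta.size
    H = np.empty((d, d))
    h = 1e-5
    for i in range(d):
        e = np.zeros(d)
        e[i] = h
        H[:, i] = (grad(theta + e) - grad(theta - e)) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(d, np.nan)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def class_probabilities(model: OLRModel,
                        scores: pd.Series | dict | np.ndarray) -> np.ndarray:
    """Per-level probability vector (differences of cumulative logits)."""
    if isinstance(scores, (pd.Series, dict)):
        try:
            x = np.array([float(scores[l]) for l in model.selected_labels])
        except KeyError as missing:
            raise FacekinError(f"missing selected score {missing}") from None
    else:
        x = np.asarray(scores, dtype=float)
        if x.size != len(model.selected_labels):
            raise FacekinError("score vector length mismatch")
    if np.any(~np.isfinite(x)):
        raise FacekinError("missing selected score (NaN)")
    eta = model.thresholds + float(x @ model.coefficients)
    F = np.concatenate([_sigmoid(eta), [1.0]])
    probs = np.diff(np.concatenate([[0.0], F]))
    return probs


def argmax_grade(probs: np.ndarray,
                 levels: tuple[int, ...] = LEVELS) -> int:
    """Most probable grade; exact ties resolve to the lower (healthier) one."""
    probs = np.asarray(probs, dtype=float)
    if probs.size != len(levels):
        raise FacekinError("probability vector length mismatch")
    return int(levels[int(np.argmax(probs))])


def predict(model: OLRModel,
            scores: pd.Series | dict | np.ndarray) -> int:
    """Argmax grade; exact ties resolve to the lower (healthier) grade."""
    return argmax_grade(class_probabilities(model, scores),
                        model.class_levels)


# ---------------------------------------------------------------------------
# Stepwise AIC selection
# ---------------------------------------------------------------------------

def stepwise_select(scores: pd.DataFrame,
                    grades: list[int] | np.ndarray,
                    weights: np.ndarray | None = None,
                    candidates: list[str] | None = None,
                    tol: float = 1e-8,
                    max_iter: int = 500) -> OLRModel:
    """Bidirectional greedy AIC search starting from the empty model.

    Each step applies the single add-or-drop move that most reduces
    AIC = 2 * #parameters - 2 * weighted log-likelihood, stopping when no
    move improves it.  Candidate fits that fail are skipped with a warning.
    """
    if candidates is None:
        candidates = list(scores.columns)
    if not candidates:
        raise FacekinError("no candidate labels")
    grades = np.asarray(grades)

    def try_fit(sel: list[str]) -> OLRModel | None:
        try:
            return fit_olr(scores, grades, weights, labels=sel,
                           tol=tol, max_iter=max_iter)
        except SingleClassError:
            raise
        except Exception as err:
            warnings.warn(f"candidate fit {sel} failed: {err}", stacklevel=2)
            return None

    selected: list[str] = []
    order: list[str] = []
    current = fit_olr(scores, grades, weights, labels=[], tol=tol,
                      max_iter=max_iter)
    while True:
        best_move: tuple[str, str] | None = None
        best_model = None
        best_aic = current.aic
        for lab in candidates:
            if lab in selected:
                continue
            cand = try_fit(selected + [lab])
            if cand is not None and cand.aic < best_aic - 1e-9:
                best_aic, best_model, best_move = cand.aic, cand, ("add", lab)
        for lab in selected:
            cand = try_fit([l for l in selected if l != lab])
            if cand is not None and cand.aic < best_aic - 1e-9:
                best_aic, best_model, best_move = cand.aic, cand, ("drop", lab)
        if best_move is None:
            break
        action, lab = best_move
        if action == "add":
            selected.append(lab)
            order.append(lab)
        else:
            selected.remove(lab)
        current = best_model
    current.inclusion_order = tuple(order)
    return current


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def confusion_matrix(true_grades: list[int] | np.ndarray,
                     predicted_grades: list[int] | np.ndarray) -> pd.DataFrame:
    """4x4 count matrix, rows = clinician grade, columns = model grade."""
    t = np.asarray(true_grades)
    p = np.asarray(predicted_grades)
    if t.size != p.size:
        raise FacekinError("true/predicted length mismatch")
    cm = pd.DataFrame(0, index=list(LEVELS), columns=list(LEVELS))
    for ti, pi in zip(t, p):
        if ti not in LEVELS or pi not in LEVELS:
            raise FacekinError(f"grade outside adjusted levels: {ti}, {pi}")
        cm.loc[ti, pi] += 1
    cm.index.name = "clinician"
    cm.columns.name = "model"
    return cm


@dataclass
class AccuracyReport:
    """Per-class and overall correct / approximate classification rates.

    *Correct* means model grade equals clinician grade; *approximate*
    means they differ by at most 1 on the numeric grade values, so 3 vs 6
    is NOT approximate.  Percentages are rounded to integers for display;
    exact fractions are retained.
    """

    per_class: pd.DataFrame  # index level, correct/approximate fractions+pct
    overall_correct: float
    overall_approximate: float

    @property
    def overall_correct_pct(self) -> int:
        return round(100.0 * self.overall_correct)

    @property
    def overall_approximate_pct(self) -> int:
        return round(100.0 * self.overall_approximate)

    @property
    def misclassified_pct(self) -> int:
        """Share of cases not even approximately classified."""
        return 100 - self.overall_approximate_pct


def accuracy_report(cm: pd.DataFrame) -> AccuracyReport:
    """Summarise a confusion matrix into classification rates."""
    total = int(cm.to_numpy().sum())
    if total == 0:
        raise FacekinError("empty confusion matrix")
    rows = []
    correct_sum = 0
    approx_sum = 0
    for level in cm.index:
        row_total = int(cm.loc[level].sum())
        correct = int(cm.loc[level, level]) if level in cm.columns else 0
        approx = sum(int(cm.loc[level, c]) for c in cm.columns
                     if abs(int(c) - int(level)) <= 1)
        correct_sum += correct
        approx_sum += approx
        if row_total == 0:
            rows.append((level, np.nan, np.nan, None, None))
        else:
            cf, af = correct / row_total, approx / row_total
            rows.append((level, cf, af, round(100 * cf), round(100 * af)))
    per_class = pd.DataFrame(
        rows, columns=["grade", "correct_fraction", "approximate_fraction",
                       "correct_pct", "approximate_pct"]
    ).set_index("grade")
    return AccuracyReport(per_class, correct_sum / total, approx_sum / total)
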