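"""Biomarker panels: binary logistic regression and ROC/AUC evaluation.

A panel is a fixed marker list fitted by maximum-likelihood logistic
regression (IRLS) on standardized marker values.  Complete or
quasi-complete separation (diverging coefficient norm) triggers a ridge
fallback with a tiny penalty and a flag.  ROC analysis computes the AUC as
the Mann-Whitney U statistic divided by n_pos * n_neg (ties count 0.5),
with the explicit threshold-sweep curve whose trapezoid integral equals
the U-based value.  Cross-syndrome application reuses the trained
coefficients AND the training standardization, so the evaluation on a new
cohort is well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PanelModel:
    markers: list
    coef: np.ndarray          # one per marker, on the standardized scale
    intercept: float
    means: np.ndarray         # training standardization
    sds: np.ndarray
    converged: bool
    separation: bool
    n_iter: int

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor for a features x samples matrix."""
        missing = [m for m in self.markers if m not in X.index]
        if missing:
            raise ValueError(f"markers absent from matrix: {missing}")
        Z = X.loc[self.markers].to_numpy(float).T
        sds = np.where(self.sds > 0, self.sds, 1.0)
        Z = (Z - self.means) / sds
        return Z @ self.coef + self.intercept


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def _irls(Z: np.ndarray, y: np.ndarray, ridge: float = 0.0, tol: float = 1e-8,
          max_iter: int = 100) -> tuple[np.ndarray, bool, bool, int]:
    """Newton/IRLS for logistic regression with optional ridge penalty.

    Returns (beta incl. intercept, converged, diverged, iterations).
    Divergence (separation) is flagged when the coefficient norm explodes.
    """
    n, p = Z.shape
    A = np.column_stack([np.ones(n), Z])
    beta = np.zeros(p + 1)
    pen = ridge * np.eye(p + 1)
    pen[0, 0] = 0.0  # never penalize the intercept
    for it in range(1, max_iter + 1):
        eta = np.clip(A @ beta, -35.0, 35.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = A.T @ (y - mu) - pen @ beta
        hess = (A * w[:, None]).T @ A + pen
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, False, True, it
        beta = beta + step
        if np.linalg.norm(beta) > 1e4:
            return beta, False, True, it
        if np.max(np.abs(step)) < tol:
            return beta, True, False, it
    # non-convergence with huge standardized coefficients is (quasi-)separation
    diverged = np.linalg.norm(beta) > 30.0
    return beta, False, diverged, max_iter


def fit_panel(X: pd.DataFrame, y, markers: list, ridge_fallback: float = 1e-6) -> PanelModel:
    """Fit a logistic biomarker panel.

    ``X`` is features x samples; ``y`` a binary label per sample (case=1).
    Markers are standardized with training mean/sd; a constant marker gets
    coefficient 0 (it carries no information and is effectively dropped
    from the score).
    """
    y = np.asarray(y, float)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    missing = [m for m in markers if m not in X.index]
    if missing:
        raise ValueError(f"markers absent from matrix: {missing}")
    Z = X.loc[markers].to_numpy(float).T
    means = Z.mean(axis=0)
    sds = Z.std(axis=0, ddof=1)
    constant = sds == 0
    if constant.any():
        logger.warning("constant markers carry no information: %s",
                       [m for m, c in zip(markers, constant) if c])
    Zs = (Z - means) / np.where(constant, 1.0, sds)
    Zs[:, constant] = 0.0

    beta, converged, diverged, n_iter = _irls(Zs, y)
    separation = diverged
    if diverged:
        logger.warning("separation detected; refitting with ridge %.1e", ridge_fallback)
        beta, converged, _, n_iter = _irls(Zs, y, ridge=ridge_fallback)
    coef = beta[1:]
    coef[constant] = 0.0
    return PanelModel(list(markers), coef, float(beta[0]), means, sds,
                      converged, separation, n_iter)


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC for continuous scores against binary labels.

    AUC = U / (n_pos * n_neg) with tied score pairs counted 0.5.  The curve
    sweeps all distinct score thresholds (ties collapse to one point), so
    its trapezoid integral equals the U-statistic AUC.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2.0
    auc = float(u / (len(pos) * len(neg)))

    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    sorted_pos = (labels[order] == 1).astype(float)
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], len(scores) - 1]
    tps = np.cumsum(sorted_pos)[distinct]
    fps = (distinct + 1) - tps
    tpr = np.r_[0.0, tps / len(pos)]
    fpr = np.r_[0.0, fps / len(neg)]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return RocResult(auc, fpr, tpr, thresholds)


def cross_apply(panel: PanelModel, X_other: pd.DataFrame, y_other) -> RocResult:
    """Evaluate a trained panel on another cohort (frozen standardization)."""
    scores = panel.decision_scores(X_other)
    return roc_auc(scores, np.asarray(y_other))
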