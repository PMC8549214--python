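"""Metabolomics discriminant modelling and differential-metabolite calling.

Implements the PLS family used throughout untargeted/targeted metabolomics:

* NIPALS PLS-DA on a binary class vector,
* O-PLS-DA in the Trygg-Wold formulation (orthogonal signal correction
  rounds followed by a single predictive component),
* VIP (variable importance in projection) over the predictive component,
  normalised so that mean(VIP^2) = 1,
* tenfold stratified cross-validated Q^2 = 1 - PRESS/SS,
* univariate Mann-Whitney U tests with Benjamini-Hochberg FDR.

Differential metabolites (DMs) combine the multivariate and univariate
evidence: VIP > 1 with q < 0.05 for untargeted data, VIP > 1 with raw
p < 0.05 for targeted data (strict inequalities throughout).

All model fitting centers X and, by default, scales each feature to unit
variance (auto scaling), the metabolomics convention that makes VIP
comparable across features; Pareto scaling is available via ``scale=``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from zhengomics.tables import OmicsTable

logger = logging.getLogger(__name__)

_SCALES = {"uv", "pareto", "none"}


def _preprocess(X: np.ndarray, scale: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center and scale columns; returns (Xs, mean, divisor)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scale == "uv":
        div = np.where(sd > 0, sd, 1.0)
    elif scale == "pareto":
        div = np.where(sd > 0, np.sqrt(sd), 1.0)
    else:
        div = np.ones_like(sd)
    return (X - mean) / div, mean, div


def _check_binary(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"class vector must be binary, got {classes.size} classes")
    return np.where(y == classes[1], 1.0, 0.0)


# ---------------------------------------------------------------------------
# PLS-DA (NIPALS, univariate y)
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    scores: np.ndarray      # n x A
    loadings: np.ndarray    # J x A
    weights: np.ndarray     # J x A
    y_loadings: np.ndarray  # A
    x_mean: np.ndarray
    x_div: np.ndarray
    y_mean: float


def fit_plsda(X: np.ndarray, y, n_comp: int = 2, scale: str = "uv") -> PlsModel:
    """NIPALS PLS with a single binary response.

    With a univariate y each component has weight w = X'y/||X'y||, score
    t = Xw, loading p = X't/(t't), y-loading q = y't/(t't); X and y are
    deflated between components, which makes successive scores mutually
    orthogonal.
    """
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {_SCALES}")
    X = np.asarray(X, float)
    yb = _check_binary(np.asarray(y))
    if n_comp < 1:
        raise ValueError("n_comp >= 1 required")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        logger.warning("dropping %d zero-variance features", int((sd == 0).sum()))
    Xs, mean, div = _preprocess(X, scale)
    Xs[:, sd == 0] = 0.0
    yc = yb - yb.mean()

    n, J = Xs.shape
    T = np.zeros((n, n_comp))
    P = np.zeros((J, n_comp))
    W = np.zeros((J, n_comp))
    Q = np.zeros(n_comp)
    Xd, yd = Xs.copy(), yc.copy()
    for a in range(n_comp):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm == 0:
            logger.warning("no covariance left at component %d; truncating", a + 1)
            T, P, W, Q = T[:, :a], P[:, :a], W[:, :a], Q[:a]
            break
        w /= norm
        t = Xd @ w
        tt = t @ t
        p = Xd.T @ t / tt
        q = yd @ t / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - q * t
        T[:, a], P[:, a], W[:, a], Q[a] = t, p, w, q
    return PlsModel(T, P, W, Q, mean, div, float(yb.mean()))


# ---------------------------------------------------------------------------
# O-PLS-DA (Trygg-Wold)
# ---------------------------------------------------------------------------

@dataclass
class OplsModel:
    """Fitted O-PLS-DA model with one predictive component.

    ``w``, ``t``, ``p`` are the predictive weight/score/loading vectors;
    ``w_ortho``/``t_ortho``/``p_ortho`` stack one row/column per orthogonal
    round.  ``r2y`` is the in-sample fraction of class variance explained
    by the predictive component; ``q2`` is filled by
    :func:`cross_validate_q2`.
    """

    w: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: float
    w_ortho: np.ndarray   # n_ortho x J
    t_ortho: np.ndarray   # n x n_ortho
    p_ortho: np.ndarray   # n_ortho x J
    x_mean: np.ndarray
    x_div: np.ndarray
    y_mean: float
    r2y: float
    n_ortho: int
    scale: str = "uv"
    q2: float | None = field(default=None)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        """Class-score prediction for new samples (continuous, around 0/1)."""
        Xs = (np.asarray(X_new, float) - self.x_mean) / self.x_div
        for k in range(self.n_ortho):
            t_o = Xs @ self.w_ortho[k]
            Xs = Xs - np.outer(t_o, self.p_ortho[k])
        t = Xs @ self.w
        return t * self.q + self.y_mean


def fit_oplsda(X: np.ndarray, y, n_ortho: int = 1, scale: str = "uv") -> OplsModel:
    """Orthogonal PLS-DA: strip y-orthogonal variation, then fit one
    predictive PLS component on the deflated matrix.

    Each orthogonal round computes w = X'y (normalised), t = Xw,
    p = X't/(t't), then the orthogonal weight w_o = p - (w'p)w
    (normalised), score t_o = X w_o and loading p_o, and deflates X by
    t_o p_o'.  With ``n_ortho=0`` the model reduces exactly to PLS-DA
    component 1.
    """
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {_SCALES}")
    if n_ortho < 0:
        raise ValueError("n_ortho >= 0 required")
    X = np.asarray(X, float)
    yb = _check_binary(np.asarray(y))
    sd = X.std(axis=0, ddof=1)
    Xs, mean, div = _preprocess(X, scale)
    Xs[:, sd == 0] = 0.0
    yc = yb - yb.mean()

    n, J = Xs.shape
    W_o = np.zeros((n_ortho, J))
    T_o = np.zeros((n, n_ortho))
    P_o = np.zeros((n_ortho, J))
    Xd = Xs.copy()
    for k in range(n_ortho):
        w = Xd.T @ yc
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm == 0:
            logger.warning("no orthogonal variation at round %d; stopping", k + 1)
            W_o, T_o, P_o = W_o[:k], T_o[:, :k], P_o[:k]
            n_ortho = k
            break
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o[k], T_o[:, k], P_o[k] = w_o, t_o, p_o

    w = Xd.T @ yc
    w /= np.linalg.norm(w)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = float(yc @ t / (t @ t))
    resid = yc - q * t
    r2y = 1.0 - float(resid @ resid) / float(yc @ yc)
    return OplsModel(w, t, p, q, W_o, T_o, P_o, mean, div, float(yb.mean()), r2y, n_ortho, scale)


def vip(model: OplsModel, include_orthogonal: bool = False) -> np.ndarray:
    """VIP scores over the predictive component(s).

    VIP_j = sqrt(J * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a); with a
    single predictive component this is sqrt(J)*|w_j| for the unit-norm
    weight vector, so mean(VIP^2) = 1 holds identically.  Setting
    ``include_orthogonal`` adds the orthogonal rounds to the sum (off by
    default: the O-PLS convention scores predictive relevance only).
    """
    J = model.w.size
    comps = [(model.w, model.t, model.q)]
    if include_orthogonal:
        for k in range(model.n_ortho):
            t_o = model.t_ortho[:, k]
            # orthogonal components explain no y-variance by construction;
            # weight them by their X-variance share instead
            comps.append((model.w_ortho[k], t_o, 0.0))
    ssy = np.array([ (q * t) @ (q * t) if q != 0 else (t @ t) for _, t, q in comps ])
    if ssy.sum() == 0:
        return np.ones(J)
    num = np.zeros(J)
    for (w, _, _), s in zip(comps, ssy):
        wn = w / np.linalg.norm(w)
        num += s * wn**2
    return np.sqrt(J * num / ssy.sum())


def cross_validate_q2(
    X: np.ndarray, y, folds: int = 10, seed: int = 0, n_ortho: int = 1, scale: str = "uv"
) -> float:
    """Stratified k-fold cross-validated Q^2 = 1 - PRESS/SS.

    SS is the total sum of squares of the centered class vector; each fold
    refits the full model (centering/scaling included) on the training
    portion.  Fold assignment is seeded and stratified by class; when the
    smaller class has fewer members than ``folds`` the fold count is
    reduced with a warning.
    """
    X = np.asarray(X, float)
    yb = _check_binary(np.asarray(y))
    n = yb.size
    if n < 4:
        raise ValueError("need at least 4 samples for cross-validation")
    min_class = int(min((yb == 0).sum(), (yb == 1).sum()))
    if min_class < folds:
        logger.warning("reducing folds from %d to %d (smallest class)", folds, min_class)
        folds = max(2, min_class)

    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    for cls in (0.0, 1.0):
        idx = np.where(yb == cls)[0]      # sample-id (position) order
        perm = rng.permutation(idx)
        assignment[perm] = np.arange(perm.size) % folds

    press = 0.0
    for f in range(folds):
        test = assignment == f
        model = fit_oplsda(X[~test], yb[~test], n_ortho=n_ortho, scale=scale)
        y_hat = model.predict(X[test])
        press += float(((yb[test] - y_hat) ** 2).sum())
    ss = float(((yb - yb.mean()) ** 2).sum())
    return 1.0 - press / ss


# ---------------------------------------------------------------------------
# univariate tests and DM calling
# ---------------------------------------------------------------------------

def univariate_mwu_fdr(X: np.ndarray, groups) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Mann-Whitney U per feature with BH-adjusted q-values.

    ``X`` is samples x features; ``groups`` a binary indicator per sample.
    Exact null distribution for small tie-free samples, tie-corrected
    normal approximation otherwise (scipy's automatic policy).
    """
    X = np.asarray(X, float)
    g = np.asarray(groups)
    classes = np.unique(g)
    if classes.size != 2:
        raise ValueError("exactly two groups required")
    a, b = X[g == classes[0]], X[g == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided", method="auto")
    p = np.atleast_1d(res.pvalue)
    q = multipletests(p, method="fdr_bh")[1]
    return p, q


def call_dms(
    feature_ids,
    vip_scores: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    mode: str,
    categories=None,
    vip_thresh: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential-metabolite table combining VIP and univariate evidence.

    mode ``untargeted``: significant iff VIP > 1 and q < 0.05;
    mode ``targeted``:   significant iff VIP > 1 and p < 0.05.
    Thresholds are strict.
    """
    if mode not in {"untargeted", "targeted"}:
        raise ValueError("mode must be 'untargeted' or 'targeted'")
    feature_ids = list(feature_ids)
    if not (len(feature_ids) == len(vip_scores) == len(p) == len(q)):
        raise ValueError("feature ids, VIP and p/q vectors are misaligned")
    uni = q if mode == "untargeted" else p
    out = pd.DataFrame(
        {
            "metabolite": feature_ids,
            "category": (list(categories) if categories is not None else [""] * len(feature_ids)),
            "vip": np.asarray(vip_scores, float),
            "p": np.asarray(p, float),
            "q": np.asarray(q, float),
        }
    )
    out["significant"] = (out["vip"] > vip_thresh) & (np.asarray(uni, float) < alpha)
    return out.sort_values(["p", "metabolite"], kind="mergesort").reset_index(drop=True)


def category_proportions(dm_table: pd.DataFrame) -> pd.Series:
    """Share of each chemical category among significant DMs."""
    sig = dm_table[dm_table["significant"]]
    if len(sig) == 0:
        return pd.Series(dtype=float)
    return sig["category"].value_counts(normalize=True).sort_index()


def differential_metabolites(
    table: OmicsTable,
    case: str,
    control: str,
    mode: str,
    n_ortho: int = 1,
    seed: int = 0,
    scale: str = "uv",
) -> tuple[pd.DataFrame, OplsModel]:
    """End-to-end DM calling for one syndrome-vs-control contrast.

    Fits the tenfold cross-validated O-PLS-DA on log2 data, computes VIP,
    runs the Mann-Whitney/BH univariate screen and applies the
    mode-specific significance rule.
    """
    sub = table.subset_groups([case, control])
    X = np.log2(sub.values.to_numpy(float)).T     # samples x features
    y = (sub.groups == case).astype(int).to_numpy()
    model = fit_oplsda(X, y, n_ortho=n_ortho, scale=scale)
    model.q2 = cross_validate_q2(X, y, folds=10, seed=seed, n_ortho=n_ortho, scale=scale)
    v = vip(model)
    p, q = univariate_mwu_fdr(X, y)
    cats = None
    if table.feature_meta is not None and "category" in table.feature_meta.columns:
        cats = table.feature_meta.loc[sub.feature_ids, "category"]
    return call_dms(sub.feature_ids, v, p, q, mode, categories=cats), model
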