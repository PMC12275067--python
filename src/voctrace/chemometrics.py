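"""Latent-variable models for discrimination: PCA, PLS-DA, OPLS-DA.

PLS components are extracted by NIPALS with deflation of both blocks.
OPLS-DA follows the orthogonal-filtering scheme: variation in X that is
orthogonal to the class response is removed component by component before
the predictive PLS part is fitted, concentrating class-discriminating
variance in the predictive scores.  Model quality is summarized by

* R2X — cumulative fraction of X variance captured (predictive + orthogonal),
* R2Y — fraction of class-coding variance fitted,
* Q2  — cross-validated predicted Y variance (7-fold venetian blinds),

and model validity is assessed with a label-permutation test: the observed
Q2 must beat (almost) every permuted Q2 and the regression of permuted Q2 on
label correlation must intercept below 0.05.

Variable importance in projection (VIP) scores follow the standard
normalization in which the mean squared VIP over variables equals 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 1000


# ---------------------------------------------------------------------------
# encoding and scaling helpers
# ---------------------------------------------------------------------------

def one_hot(y) -> tuple[np.ndarray, np.ndarray]:
    """Class labels -> (n x k 0/1 matrix, sorted class array)."""
    y = np.asarray(y)
    classes = np.unique(y)
    Y = (y[:, None] == classes[None, :]).astype(float)
    return Y, classes


def _scale_fit(X: np.ndarray, scale: str):
    mean = X.mean(axis=0)
    if scale == "uv":
        sd = X.std(axis=0, ddof=1)
    elif scale == "center":
        sd = np.ones(X.shape[1])
    else:
        raise ValueError("scale must be 'center' or 'uv'")
    keep = sd > 0 if scale == "uv" else X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {np.count_nonzero(~keep)} constant column(s)")
    return mean, np.where(sd > 0, sd, 1.0), keep


# ---------------------------------------------------------------------------
# NIPALS PLS2 with block deflation
# ---------------------------------------------------------------------------

def _nipals_component(X: np.ndarray, Y: np.ndarray):
    """One PLS component: unit weight w, scores t, loadings p, q."""
    u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
    if not u.any():
        u = Y[:, 0] + 1e-12
    w = np.zeros(X.shape[1])
    for _ in range(_NIPALS_MAX_ITER):
        w_new = X.T @ u
        norm = np.linalg.norm(w_new)
        if norm == 0:
            break
        w_new /= norm
        t = X @ w_new
        tt = t @ t
        if tt == 0:
            w = w_new
            break
        q = Y.T @ t / tt
        qq = q @ q
        u_new = Y @ q / qq if qq > 0 else u
        if np.linalg.norm(w_new - w) < _NIPALS_TOL:
            w = w_new
            u = u_new
            break
        w, u = w_new, u_new
    t = X @ w
    tt = t @ t
    p = X.T @ t / tt if tt > 0 else np.zeros(X.shape[1])
    q = Y.T @ t / tt if tt > 0 else np.zeros(Y.shape[1])
    return w, t, p, q


def _nipals_pls(X: np.ndarray, Y: np.ndarray, A: int):
    """A-component NIPALS PLS2 on centered blocks; X and Y are deflated."""
    Xd, Yd = X.copy(), Y.copy()
    W, T, P, Q = [], [], [], []
    for _ in range(A):
        if np.abs(Xd).max() < 1e-12:
            break
        w, t, p, q = _nipals_component(Xd, Yd)
        if t @ t < 1e-14:
            break
        Xd -= np.outer(t, p)
        Yd -= np.outer(t, q)
        W.append(w)
        T.append(t)
        P.append(p)
        Q.append(q)
    to = lambda L: np.array(L).T if L else np.zeros((X.shape[1], 0))
    Tm = np.array(T).T if T else np.zeros((X.shape[0], 0))
    Qm = np.array(Q).T if Q else np.zeros((Y.shape[1], 0))
    return to(W), Tm, to(P), Qm


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class LatentModel:
    """Fitted PLS-DA / OPLS-DA model (predictive + orthogonal blocks)."""

    classes: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    keep: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray  # predictive weights (p x A)
    P: np.ndarray
    Q: np.ndarray  # Y-loadings (k x A)
    T: np.ndarray  # training scores (n x A)
    W_o: np.ndarray  # orthogonal weights (p x n_ortho)
    P_o: np.ndarray
    T_o: np.ndarray
    r2x: float = np.nan
    r2x_pred: float = np.nan
    r2x_ortho: float = np.nan
    r2y: float = np.nan
    scale: str = "center"
    meta: dict = field(default_factory=dict)

    @property
    def A(self) -> int:
        return self.W.shape[1]

    @property
    def n_ortho(self) -> int:
        return self.W_o.shape[1]

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.keep]
        Xc = (X - self.x_mean) / self.x_scale
        for a in range(self.n_ortho):
            t_o = Xc @ self.W_o[:, a]
            Xc = Xc - np.outer(t_o, self.P_o[:, a])
        return Xc

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Predictive scores of new samples."""
        Xc = self._prepare(X)
        T = np.zeros((Xc.shape[0], self.A))
        for a in range(self.A):
            T[:, a] = Xc @ self.W[:, a]
            Xc = Xc - np.outer(T[:, a], self.P[:, a])
        return T

    def predict_continuous(self, X: np.ndarray) -> np.ndarray:
        return self.transform(X) @ self.Q.T + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        yc = self.predict_continuous(X)
        return self.classes[np.argmax(yc, axis=1)]


@dataclass
class FitMetrics:
    """Goodness-of-fit and cross-validated predictivity of a latent model."""

    r2x: float
    r2y: float
    q2: float
    rmse_cv: float
    n_ortho: int = 0
    A: int = 1


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit_core(
    X: np.ndarray, y, A: int, n_ortho: int, scale: str
) -> LatentModel:
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    Y, classes = one_hot(y)
    x_mean_full, x_scale_full, keep = _scale_fit(X, scale)
    Xc = (X[:, keep] - x_mean_full[keep]) / x_scale_full[keep]
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    ssx0 = float((Xc**2).sum())
    ssy0 = float((Yc**2).sum())

    W_o, T_o, P_o = [], [], []
    Xf = Xc.copy()
    for _ in range(n_ortho):
        w, t, p, _q = _nipals_component(Xf, Yc)
        w_o = p - (w @ p) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            raise ValueError("no orthogonal variation left to remove")
        w_o /= nrm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)

    W, T, P, Q = _nipals_pls(Xf, Yc, A)

    ssx_pred = float(sum((np.outer(T[:, a], P[:, a]) ** 2).sum() for a in range(T.shape[1])))
    ssx_orth = float(sum((np.outer(t, p) ** 2).sum() for t, p in zip(T_o, P_o)))
    resid_y = Yc - T @ Q.T
    model = LatentModel(
        classes=classes,
        x_mean=x_mean_full[keep],
        x_scale=x_scale_full[keep],
        keep=keep,
        y_mean=y_mean,
        W=W,
        P=P,
        Q=Q,
        T=T,
        W_o=np.array(W_o).T if W_o else np.zeros((Xc.shape[1], 0)),
        P_o=np.array(P_o).T if P_o else np.zeros((Xc.shape[1], 0)),
        T_o=np.array(T_o).T if T_o else np.zeros((Xc.shape[0], 0)),
        r2x=(ssx_pred + ssx_orth) / ssx0 if ssx0 > 0 else 0.0,
        r2x_pred=ssx_pred / ssx0 if ssx0 > 0 else 0.0,
        r2x_ortho=ssx_orth / ssx0 if ssx0 > 0 else 0.0,
        r2y=1.0 - float((resid_y**2).sum()) / ssy0 if ssy0 > 0 else 0.0,
        scale=scale,
        meta={"feature_names": feature_names},
    )
    return model


def plsda(X: np.ndarray, y, A: int, scale: str = "center") -> LatentModel:
    """PLS2 discriminant analysis on centered one-hot class coding."""
    if len(np.unique(np.asarray(y))) < 2:
        raise ValueError("need >= 2 classes")
    return _fit_core(X, y, A=A, n_ortho=0, scale=scale)


def venetian_folds(n: int, k: int = 7) -> list[np.ndarray]:
    """Deterministic venetian-blind folds: fold j = samples j, j+k, ..."""
    return [np.arange(j, n, k) for j in range(min(k, n))]


def cross_val_q2(
    X: np.ndarray, y, A: int, n_ortho: int = 0, scale: str = "center", k: int = 7
) -> tuple[float, float]:
    """(Q2, RMSE_CV) of the class coding under k-fold venetian blinds."""
    X = np.asarray(X, dtype=float)
    Y, _ = one_hot(y)
    n = X.shape[0]
    press = 0.0
    for test in venetian_folds(n, k):
        train = np.setdiff1d(np.arange(n), test)
        m = _fit_core(X[train], np.asarray(y)[train], A=A, n_ortho=n_ortho, scale=scale)
        # classes seen in the fold may be a subset; map predictions back
        yc = m.transform(X[test]) @ m.Q.T + m.y_mean
        Y_fold = (np.asarray(y)[test][:, None] == m.classes[None, :]).astype(float)
        press += float(((Y_fold - yc) ** 2).sum())
    tss = float(((Y - Y.mean(axis=0)) ** 2).sum())
    q2 = 1.0 - press / tss if tss > 0 else np.nan
    rmse_cv = float(np.sqrt(press / Y.size))
    return q2, rmse_cv


def oplsda(
    X: np.ndarray,
    y,
    n_ortho: int | None = None,
    A: int | None = None,
    scale: str = "center",
    max_ortho: int = 5,
) -> tuple[LatentModel, FitMetrics]:
    """Orthogonally filtered PLS-DA with cross-validated metrics.

    ``n_ortho=None`` selects the number of orthogonal components in
    0..max_ortho by maximizing cross-validated Q2 (first maximum wins).
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if A is None:
        A = max(1, len(classes) - 1)
    if n_ortho is None:
        best, best_q2 = 0, -np.inf
        for n_o in range(max_ortho + 1):
            try:
                q2, _ = cross_val_q2(X, y, A=A, n_ortho=n_o, scale=scale)
            except ValueError:
                break
            if q2 > best_q2 + 1e-12:
                best, best_q2 = n_o, q2
        n_ortho = best
    model = _fit_core(X, y, A=A, n_ortho=n_ortho, scale=scale)
    q2, rmse_cv = cross_val_q2(X, y, A=A, n_ortho=n_ortho, scale=scale)
    metrics = FitMetrics(
        r2x=model.r2x, r2y=model.r2y, q2=q2, rmse_cv=rmse_cv, n_ortho=n_ortho, A=model.A
    )
    return model, metrics


# ---------------------------------------------------------------------------
# VIP, permutation test, PCA, classification metrics
# ---------------------------------------------------------------------------

def vip(model: LatentModel) -> pd.Series | np.ndarray:
    """Variable importance in projection of the predictive components.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ); the mean
    of squared VIPs over variables is 1 by construction.
    """
    if model.A < 1:
        raise ValueError("model has no predictive components")
    W, T, Q = model.W, model.T, model.Q
    ssy = np.array([(T[:, a] @ T[:, a]) * (Q[:, a] @ Q[:, a]) for a in range(model.A)])
    if ssy.sum() <= 0:
        raise ValueError("zero explained Y variance; VIP undefined")
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    p = W.shape[0]
    scores_kept = np.sqrt(p * (wn**2 @ ssy) / ssy.sum())
    scores = np.zeros(model.keep.size)
    scores[model.keep] = scores_kept
    names = model.meta.get("feature_names")
    if names is not None:
        return pd.Series(scores, index=names, name="vip")
    return scores


@dataclass
class PermutationRecord:
    """Outcome of a label-permutation validation."""

    r2y_perm: np.ndarray
    q2_perm: np.ndarray
    correlation: np.ndarray
    r2y: float
    q2: float
    r2_intercept: float
    q2_intercept: float
    valid: bool


def permutation_test(
    X: np.ndarray,
    y,
    A: int | None = None,
    n_ortho: int = 0,
    scale: str = "center",
    n_perm: int = 200,
    seed: int = 0,
) -> PermutationRecord:
    """Label-permutation validation of a (O)PLS-DA model.

    Refits the model spec under ``n_perm`` random label permutations and
    regresses permuted R2Y/Q2 on the correlation between permuted and true
    class coding.  The model is 'valid' iff the Q2-regression intercept is
    below 0.05 and the original Q2 exceeds all but at most 5 % of the
    permuted Q2 values.
    """
    if n_perm < 20:
        raise ValueError("need n_perm >= 20")
    y = np.asarray(y)
    if A is None:
        A = max(1, len(np.unique(y)) - 1)
    rng = np.random.default_rng(seed)
    Y, _ = one_hot(y)
    Yc = Y - Y.mean(axis=0)
    ss = float((Yc**2).sum())

    model = _fit_core(X, y, A=A, n_ortho=n_ortho, scale=scale)
    q2_0, _ = cross_val_q2(X, y, A=A, n_ortho=n_ortho, scale=scale)

    r2s, q2s, cors = [], [], []
    for _ in range(n_perm):
        perm = rng.permutation(y.size)
        yp = y[perm]
        cors.append(float(np.abs((Yc * Yc[perm]).sum()) / ss))
        m = _fit_core(X, yp, A=A, n_ortho=n_ortho, scale=scale)
        r2s.append(m.r2y)
        q2p, _ = cross_val_q2(X, yp, A=A, n_ortho=n_ortho, scale=scale)
        q2s.append(q2p)
    r2s, q2s, cors = map(np.array, (r2s, q2s, cors))

    def intercept(vals: np.ndarray) -> float:
        xs = np.concatenate([cors, [1.0]])
        ys = np.concatenate([vals, [model.r2y if vals is r2s else q2_0]])
        coef = np.polyfit(xs, ys, 1)
        return float(coef[1])

    q2_int = intercept(q2s)
    r2_int = intercept(r2s)
    valid = q2_int < 0.05 and float((q2s >= q2_0).mean()) <= 0.05
    return PermutationRecord(
        r2y_perm=r2s,
        q2_perm=q2s,
        correlation=cors,
        r2y=model.r2y,
        q2=q2_0,
        r2_intercept=r2_int,
        q2_intercept=q2_int,
        valid=valid,
    )


def pca(X: np.ndarray, n_components: int) -> tuple[_SkPCA, np.ndarray]:
    """Mean-centered PCA; returns the fitted model and explained-variance
    fractions (truncated with a warning when n_components exceeds rank)."""
    X = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncating")
        n_components = rank
    model = _SkPCA(n_components=n_components, svd_solver="full").fit(X)
    return model, model.explained_variance_ratio_


@dataclass
class ClassMetrics:
    """Confusion matrix with accuracy and macro-averaged P/R/F1."""

    confusion: pd.DataFrame
    accuracy: float
    precision: float
    recall: float
    f1: float


def class_metrics(y_true, y_pred) -> ClassMetrics:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError("length mismatch")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    if not set(np.unique(y_pred)) <= set(np.unique(y_true)):
        warnings.warn("predictions contain labels unseen in y_true")
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # absent classes yield 0-division P/R
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average="macro", zero_division=0
        )
    return ClassMetrics(
        confusion=pd.DataFrame(cm, index=labels, columns=labels),
        accuracy=float(cm.trace() / cm.sum()),
        precision=float(p),
        recall=float(r),
        f1=float(f1),
    )
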