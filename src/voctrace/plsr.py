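"""PLS regression linking preprocessed spectra to marker concentrations.

One PLS1 model per target compound: NIPALS components on centered data, the
number of latent variables (LVs) chosen by 7-fold venetian-blind
cross-validation with the one-standard-error parsimony rule, and optional
refitting on the VIP > 1 variable subset.  Models are scored by R^2, RMSE
and the residual prediction deviation RPD = SD(reference) / RMSE on both the
calibration and the prediction set; RPD > 2 with R^2_P > 0.8 is the
conventional bar for a model fit for practical use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemometrics import _nipals_pls, venetian_folds
from .containers import SpectrumSet, VocTable
from .prep import average_replicates, preprocess
from .splitters import split as ks_split


@dataclass
class PlsrModel:
    """Fitted single-target PLS regression."""

    A: int
    coef: np.ndarray  # on centered retained variables
    x_mean: np.ndarray
    y_mean: float
    mask: np.ndarray  # retained-variable mask over the full input space
    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    q: np.ndarray  # (A,)
    cv_rmse: np.ndarray = field(default_factory=lambda: np.array([]))
    meta: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.mask]
        return (X - self.x_mean) @ self.coef + self.y_mean


@dataclass
class QuantMetrics:
    """R^2 / RMSE / RPD on one evaluation set."""

    set_name: str
    r2: float
    rmse: float
    rpd: float
    n: int


def _pls1(Xc: np.ndarray, yc: np.ndarray, A: int):
    W, T, P, Q = _nipals_pls(Xc, yc[:, None], A)
    return W, T, P, Q.ravel()


def _coef(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def _cv_rmse_by_A(X: np.ndarray, y: np.ndarray, A_max: int, k: int = 7) -> np.ndarray:
    """Fold x A matrix of CV RMSE for 1..A_max components."""
    n = X.shape[0]
    folds = venetian_folds(n, k)
    out = np.full((len(folds), A_max), np.nan)
    for f, test in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test)
        xm, ym = X[train].mean(axis=0), y[train].mean()
        Xc, yc = X[train] - xm, y[train] - ym
        W, T, P, q = _pls1(Xc, yc, A_max)
        for a in range(1, W.shape[1] + 1):
            b = _coef(W[:, :a], P[:, :a], q[:a])
            pred = (X[test] - xm) @ b + ym
            out[f, a - 1] = np.sqrt(np.mean((y[test] - pred) ** 2))
    return out


def fit_plsr(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    A_max: int = 10,
    cv_folds: int = 7,
    A: int | None = None,
) -> PlsrModel:
    """Fit PLS1 on centered calibration data.

    When ``A`` is not given, the LV count minimizes 7-fold CV RMSE under the
    one-SE rule: the smallest A whose mean CV RMSE is within one standard
    error of the minimum.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    n, p = X_cal.shape
    A_cap = min(A_max, p, n - 1)
    cv = np.empty((0, A_cap))
    if A is None:
        cv = _cv_rmse_by_A(X_cal, y_cal, A_cap, cv_folds)
        valid = np.isfinite(cv).any(axis=0)
        mean = np.full(A_cap, np.inf)
        mean[valid] = np.nanmean(cv[:, valid], axis=0)
        best = int(np.nanargmin(mean))
        se = np.nanstd(cv[:, best], ddof=1) / np.sqrt(np.sum(np.isfinite(cv[:, best])))
        A = int(np.argmax(mean <= mean[best] + se)) + 1  # first A within one SE
    A = min(A, A_cap)

    xm, ym = X_cal.mean(axis=0), float(y_cal.mean())
    W, T, P, q = _pls1(X_cal - xm, y_cal - ym, A)
    return PlsrModel(
        A=W.shape[1],
        coef=_coef(W, P, q),
        x_mean=xm,
        y_mean=ym,
        mask=np.ones(p, dtype=bool),
        W=W,
        T=T,
        P=P,
        q=q,
        cv_rmse=cv,
    )


def evaluate(model: PlsrModel, X: np.ndarray, y: np.ndarray, set_name: str) -> QuantMetrics:
    """R^2 = 1 - SSE/SST, RMSE = sqrt(SSE/n), RPD = SD_(n-1)(y) / RMSE."""
    y = np.asarray(y, dtype=float)
    if y.std(ddof=1) == 0:
        raise ValueError("zero-variance reference values; RPD undefined")
    pred = model.predict(X)
    sse = float(((y - pred) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    rmse = np.sqrt(sse / y.size)
    rpd = np.inf if rmse == 0 else float(y.std(ddof=1) / rmse)
    return QuantMetrics(set_name=set_name, r2=1.0 - sse / sst, rmse=float(rmse), rpd=rpd, n=y.size)


def vip_plsr(model: PlsrModel) -> np.ndarray:
    """VIP scores of a PLS1 model over its retained variables."""
    W, T, q = model.W, model.T, model.q
    A = W.shape[1]
    ssy = np.array([(T[:, a] @ T[:, a]) * q[a] ** 2 for a in range(A)])
    if ssy.sum() <= 0:
        raise ValueError("zero explained variance; VIP undefined")
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    return np.sqrt(W.shape[0] * (wn**2 @ ssy) / ssy.sum())


def vip_refit(
    model: PlsrModel,
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    threshold: float = 1.0,
    A_max: int = 10,
) -> PlsrModel:
    """Retain VIP > threshold variables and refit with reselected LVs."""
    scores = vip_plsr(model)
    keep_local = scores > threshold
    if keep_local.sum() < 2:
        raise ValueError("VIP filter retains < 2 variables")
    mask = model.mask.copy()
    mask[np.flatnonzero(model.mask)] = keep_local
    X_cal = np.asarray(X_cal, dtype=float)
    refit = fit_plsr(X_cal[:, mask], np.asarray(y_cal, float), A_max=A_max)
    refit.mask = mask
    refit.meta = {**model.meta, "vip_threshold": threshold}
    return refit


def quant_pipeline(
    spectra: SpectrumSet,
    conc: VocTable,
    targets: list[str],
    methods: tuple[str, ...] = ("raw", "SG", "1stDer", "2ndDer", "SNV", "MSC"),
    ratios: tuple[float, float] = (2, 1),
    vip_filter: bool = False,
    conc_column: str = "conc",
    A_max: int = 10,
) -> pd.DataFrame:
    """Targets x preprocessing grid of calibration/prediction metrics.

    Spectra are replicate-averaged, preprocessed, split 2:1 by Kennard-Stone
    on the preprocessed features, and modeled per target.  Rows flag models
    meeting the practical-use bar R^2_P > 0.8 and RPD_P > 2.
    """
    avg = average_replicates(spectra) if max(spectra.replicates) > 1 else spectra
    conc_wide = conc.pivot(conc_column)
    conc_wide = conc_wide.loc[avg.samples]

    rows = []
    for method in methods:
        sp = preprocess(avg, method)
        X = sp.absorbance
        sp_split = ks_split(X, ratios)
        cal, pred = sp_split.subsets[0], sp_split.subsets[1]
        for target in targets:
            if target not in conc_wide.columns:
                import warnings

                warnings.warn(f"target {target} missing from concentration table; skipped")
                continue
            y = conc_wide[target].to_numpy()
            model = fit_plsr(X[cal], y[cal], A_max=A_max)
            if vip_filter:
                model = vip_refit(model, X[cal], y[cal], A_max=A_max)
            mc = evaluate(model, X[cal], y[cal], "calibration")
            mp = evaluate(model, X[pred], y[pred], "prediction")
            rows.append(
                {
                    "target": target,
                    "preprocessing": method,
                    "variable_filter": "VIP>1" if vip_filter else "all",
                    "A": model.A,
                    "n_variables": int(model.mask.sum()),
                    "R2_C": mc.r2,
                    "RMSE_C": mc.rmse,
                    "RPD_C": mc.rpd,
                    "R2_P": mp.r2,
                    "RMSE_P": mp.rmse,
                    "RPD_P": mp.rpd,
                    "passes_bar": (mp.r2 > 0.8) and (mp.rpd > 2.0),
                }
            )
    return pd.DataFrame(rows)
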