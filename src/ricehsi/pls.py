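"""Orthogonal-scores partial least squares regression (univariate response).

The classical NIPALS deflation: predictors and response are mean-centered
(not scaled); each component extracts a weight vector proportional to
X'y, a score t = Xw, an X-loading p = X't/t't and a y-loading q = y't/t't,
then deflates X by t p'.  Scores are mutually orthogonal; with as many
components as the rank of centered X, the fit coincides with ordinary
least squares.  Model selection uses leave-one-out RMSEP over component
counts, with the 0-component model (the calibration mean) as the null --
a 0-component optimum signals that no model should be built for the trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PLSRModel",
    "Metrics",
    "fit_plsr",
    "coefficient_path",
    "select_components_loo",
    "loo_predictions",
    "jackknife_predict",
    "evaluate",
]

_EPS = 1e-12


@dataclass
class PLSRModel:
    """A fitted orthogonal-scores PLSR model."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray        # (p, A)
    x_loadings: np.ndarray     # (p, A)
    y_loadings: np.ndarray     # (A,)
    scores: np.ndarray         # (n, A)
    coef_: np.ndarray          # (p,), maps raw predictors to response
    intercept_: float
    selected_wavelengths: np.ndarray | None = None
    jackknife_coefs: np.ndarray | None = None   # (n_cal, p) when computed

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.coef_ + self.intercept_


@dataclass
class Metrics:
    """Prediction-quality summary: R^2, RMSEP and range-normalized %RMSEP."""

    r2: float
    rmsep: float
    pct_rmsep: float
    n: int
    context: str = "validation"


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """Core deflation on pre-centered data.

    Returns W, P, q, T, R (may stop early if the residual predictor
    information is exhausted).  R maps raw centered predictors to scores,
    t_h = Xc r_h, built by the exact recursion
    r_h = w_h - sum_{j<h} (p_j' w_h) r_j, so coefficients for any component
    count a are B_a = sum_{h<=a} q_h r_h.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    R = np.zeros((p, n_components))
    X = Xc.copy()
    y = yc.copy()
    scale = max(np.abs(Xc).max(), 1.0)
    a = 0
    for h in range(n_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= _EPS * scale:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt <= _EPS:
            break
        ph = X.T @ t / tt
        qh = (y @ t) / tt
        r = w - R[:, :h] @ (P[:, :h].T @ w)
        X -= np.outer(t, ph)
        y = y - qh * t
        W[:, h], P[:, h], q[h], T[:, h], R[:, h] = w, ph, qh, t, r
        a = h + 1
    return W[:, :a], P[:, :a], q[:a], T[:, :a], R[:, :a]


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int,
             selected_wavelengths: np.ndarray | None = None) -> PLSRModel:
    """Fit an orthogonal-scores PLSR with ``n_components`` latent variables."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1 (0 components is NotFittable)")
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds min(rows-1, cols)={min(n - 1, p)}")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    xm = X.mean(axis=0)
    ym = y.mean()
    W, P, q, T, R = _nipals(X - xm, y - ym, n_components)
    if W.shape[1] == 0:
        raise ValueError("predictors have no variance; cannot fit")
    coef = R @ q
    return PLSRModel(
        n_components=W.shape[1],
        x_mean=xm,
        y_mean=ym,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        scores=T,
        coef_=coef,
        intercept_=ym - xm @ coef,
        selected_wavelengths=selected_wavelengths,
    )


def coefficient_path(X: np.ndarray, y: np.ndarray, max_components: int):
    """Coefficients and intercepts for every component count 1..A in one
    NIPALS pass.  Returns (coefs (p, A'), intercepts (A',)) where A' <= A
    if the rank is exhausted early."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = X.mean(axis=0)
    ym = y.mean()
    W, P, q, _, R = _nipals(X - xm, y - ym, max_components)
    a = W.shape[1]
    if a == 0:
        return np.zeros((X.shape[1], 0)), np.zeros(0)
    coefs = np.cumsum(R * q, axis=1)          # B_a = sum_{h<=a} r_h q_h
    intercepts = ym - xm @ coefs
    return coefs, intercepts


def loo_predictions(X: np.ndarray, y: np.ndarray, max_components: int) -> np.ndarray:
    """Leave-one-out predictions for component counts 0..max_components.

    Returns an (n, max_components+1) array; column 0 is the mean of the
    retained calibration samples (the null model).  Counts a left-out fit
    cannot reach (rank exhaustion) reuse its largest attainable model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    preds = np.empty((n, max_components + 1))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        preds[i, 0] = y[keep].mean()
        coefs, intercepts = coefficient_path(X[keep], y[keep], max_components)
        a = coefs.shape[1]
        if a:
            vals = X[i] @ coefs + intercepts
            preds[i, 1:a + 1] = vals
            preds[i, a + 1:] = vals[-1]
        else:
            preds[i, 1:] = preds[i, 0]
    return preds


def select_components_loo(X: np.ndarray, y: np.ndarray,
                          max_components: int | None = None) -> int:
    """Component count minimizing leave-one-out RMSEP.

    Candidates are 0..min(20, n-1, p); ties resolve to the smallest count.
    A return of 0 is the NotFittable signal: the calibration mean predicts
    no worse than any latent-variable model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 calibration rows")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    cap = min(20, n - 1, p)
    if max_components is not None:
        cap = min(cap, max_components)
    preds = loo_predictions(X, y, cap)
    rmsep = np.sqrt(((y[:, None] - preds) ** 2).mean(axis=0))
    # numerical ties (e.g. noiseless data) resolve to the smallest count
    tol = 1e-9 * max(np.ptp(y), 1e-30)
    return int(np.flatnonzero(rmsep <= rmsep.min() + tol)[0])


def jackknife_predict(X_cal: np.ndarray, y_cal: np.ndarray, n_components: int,
                      X_val: np.ndarray, level: float = 0.95):
    """Point predictions with jackknife confidence bounds.

    Each calibration sample is left out and the model refit, giving n_cal
    coefficient vectors and hence n_cal predictions per validation sample;
    the interval is point +/- z(level) x jackknife SE, where the jackknife
    variance carries the (n-1)/n factor.  Returns (pred, lower, upper).
    """
    X_cal = np.asarray(X_cal, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    n = len(y_cal)
    if n < 3:
        raise ValueError("need at least 3 calibration rows for a jackknife")
    full = fit_plsr(X_cal, y_cal, n_components)
    point = full.predict(X_val)
    reps = np.empty((n, len(X_val)))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        a = min(n_components, len(y_cal) - 2)
        m = fit_plsr(X_cal[keep], y_cal[keep], max(a, 1))
        reps[i] = m.predict(X_val)
    se = np.sqrt((n - 1) / n * ((reps - reps.mean(axis=0)) ** 2).sum(axis=0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return point, point - z * se, point + z * se


def evaluate(y: np.ndarray, y_hat: np.ndarray, context: str = "validation") -> Metrics:
    """RMSEP, R^2 and range-normalized %RMSEP.

    RMSEP = sqrt(mean squared error); R^2 = 1 - SSE/SST about the mean of
    the measured values; %RMSEP = 100 x RMSEP / range(y).  A constant
    response leaves R^2 and %RMSEP undefined (NaN, flagged via context).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) == 0 or len(y) != len(y_hat):
        raise ValueError("y and y_hat must be equal-length and nonempty")
    sse = float(((y - y_hat) ** 2).sum())
    rmsep = float(np.sqrt(sse / len(y)))
    sst = float(((y - y.mean()) ** 2).sum())
    span = float(np.ptp(y))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    pct = 100.0 * rmsep / span if span > 0 else np.nan
    return Metrics(r2=r2, rmsep=rmsep, pct_rmsep=pct, n=len(y), context=context)
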