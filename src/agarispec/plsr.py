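"""Partial least squares regression (PLS1) for spectra-to-property models.

Factors are extracted by the standard PLS1 deflation: each weight vector is
the covariance direction between the current X residual and the response
residual, scores deflate both blocks, and the collapsed per-band coefficient
vector is B = W (PᵀW)⁻¹ c. Data are mean-centered only (``x_scale`` is kept
as ones — the chemometric convention for reflectance spectra). Predictions
through the sequential factor path and through the collapsed coefficients
agree to numerical precision, and the factor count k is chosen by minimum
cross-validated RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

__all__ = ["PlsrModel", "plsr_fit", "plsr_predict", "plsr_select_k"]


@dataclass
class PlsrModel:
    n_factors: int
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    coefficients: np.ndarray       # collapsed per-band regression vector
    x_weights: np.ndarray          # W, (bands, k)
    x_loadings: np.ndarray         # P, (bands, k)
    y_loadings: np.ndarray         # c, (k,)


def _k_bound(X: np.ndarray) -> int:
    return min(X.shape[0] - 1, X.shape[1])


def plsr_fit(X: np.ndarray, y: np.ndarray, k: int) -> PlsrModel:
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if np.std(y) == 0:
        raise ValueError("zero-variance response: PLSR undefined")
    if not (1 <= k <= _k_bound(X)):
        raise ValueError(f"k must lie in [1, {_k_bound(X)}]")
    x_center = X.mean(axis=0)
    y_center = float(y.mean())
    E = X - x_center
    f = y - y_center
    scale = float(np.sqrt(np.mean(E ** 2))) or 1.0

    W, P, c = [], [], []
    for _ in range(k):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw <= 1e-14 * scale * np.linalg.norm(f):
            break                  # response residual exhausted
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt <= (1e-14 * scale) ** 2:
            break                  # X residual rank exhausted
        p = E.T @ t / tt
        ci = float(t @ f) / tt
        E = E - np.outer(t, p)
        f = f - ci * t
        W.append(w)
        P.append(p)
        c.append(ci)
    W = np.column_stack(W)
    P = np.column_stack(P)
    c = np.asarray(c)
    R = W @ np.linalg.inv(P.T @ W)   # rotation: scores T = Xc @ R
    return PlsrModel(
        n_factors=W.shape[1],
        x_center=x_center,
        x_scale=np.ones(X.shape[1]),
        y_center=y_center,
        coefficients=R @ c,
        x_weights=W,
        x_loadings=P,
        y_loadings=c,
    )


def plsr_predict(model: PlsrModel, X: np.ndarray, *,
                 via_factors: bool = False) -> np.ndarray:
    """Predict through the collapsed coefficients (default) or by explicitly
    deflating the new spectra factor by factor."""
    X = np.atleast_2d(np.asarray(X, float))
    if not via_factors:
        return (X - model.x_center) @ model.coefficients + model.y_center
    E = X - model.x_center
    pred = np.full(X.shape[0], model.y_center)
    for a in range(model.n_factors):
        t = E @ model.x_weights[:, a]
        pred = pred + model.y_loadings[a] * t
        E = E - np.outer(t, model.x_loadings[:, a])
    return pred


def plsr_select_k(X: np.ndarray, y: np.ndarray, k_max: int | None = None,
                  n_folds: int = 5, seed: int = 0) -> tuple[int, np.ndarray]:
    """Factor count with minimum CV RMSE (first minimum on ties)."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    k_max = min(k_max or _k_bound(X), _k_bound(X))
    kf = KFold(n_splits=min(n_folds, X.shape[0]), shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    curve = np.empty(k_max)
    for k in range(1, k_max + 1):
        sq, n = 0.0, 0
        for tr, te in folds:
            m = plsr_fit(X[tr], y[tr], min(k, _k_bound(X[tr])))
            pred = plsr_predict(m, X[te])
            sq += float(np.sum((y[te] - pred) ** 2))
            n += te.size
        curve[k - 1] = np.sqrt(sq / n)
    return int(np.argmin(curve)) + 1, curve
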