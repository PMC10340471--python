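"""Wavelength reduction: successive projections algorithm (SPA) and PCA.

SPA is a forward selection that fights collinearity geometrically: starting
from one band, it repeatedly projects all remaining band-columns onto the
orthogonal complement of the span of the already-selected bands and adds the
band with the largest residual norm. Candidate chains are grown from every
possible starting band (or one fixed band), every chain prefix is scored by
cross-validated multiple-linear-regression RMSE against the response, and
the (start, size) pair with the smallest RMSE wins.

PCA follows chemometric convention for reflectance spectra: mean-centered,
unscaled; components are retained up to a cumulative explained-variance
threshold (default 95%).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import KFold

from .spectra import WavelengthGrid

__all__ = ["SpaResult", "PcaResult", "spa_select", "pca_fit", "pca_select",
           "pca_transform"]


@dataclass
class SpaResult:
    selected_indices: np.ndarray      # sorted ascending, for reporting
    chain: list[int]                  # in selection order
    rmse_curve: np.ndarray            # best CV RMSE per candidate subset size
    chosen_size: int                  # argmin of the curve (first on ties)
    start_index: int                  # starting band of the winning chain
    selected_wavelengths: np.ndarray | None = None


@dataclass
class PcaResult:
    mean: np.ndarray
    loadings: np.ndarray              # (components, bands), orthonormal rows
    scores: np.ndarray                # (samples, components)
    contribution: np.ndarray          # per-component variance share
    cumulative_contribution: np.ndarray
    n_selected: int | None = None


def _projection_chain(Xc: np.ndarray, start: int, max_size: int) -> list[int]:
    """Grow a chain by successive orthogonal projections from one start band."""
    R = Xc.copy()
    chain = [start]
    norms0 = np.einsum("ij,ij->j", Xc, Xc)
    floor = 1e-12 * norms0.max()
    for _ in range(max_size - 1):
        v = R[:, chain[-1]]
        nv = float(v @ v)
        if nv <= floor:
            break
        R = R - np.outer(v, (v @ R) / nv)
        norms = np.einsum("ij,ij->j", R, R)
        norms[chain] = -np.inf
        best = int(np.argmax(norms))
        # tie-break on equal projection norms: lowest band index
        ties = np.nonzero(norms >= norms[best] - 1e-12 * max(norms[best], 1.0))[0]
        best = int(ties[0])
        if norms[best] <= floor:
            break
        chain.append(best)
    return chain


def _cv_mlr_rmse(X: np.ndarray, y: np.ndarray, folds: list) -> float:
    """K-fold RMSE of an intercepted multiple linear regression."""
    sq, n = 0.0, 0
    for tr, te in folds:
        A = np.column_stack([np.ones(tr.size), X[tr]])
        coef, *_ = np.linalg.lstsq(A, y[tr], rcond=None)
        pred = np.column_stack([np.ones(te.size), X[te]]) @ coef
        sq += float(np.sum((y[te] - pred) ** 2))
        n += te.size
    return float(np.sqrt(sq / n))


def spa_select(X: np.ndarray, y: np.ndarray, max_size: int,
               first_band: int | str = "scan_all", *,
               grid: WavelengthGrid | None = None, n_folds: int = 5,
               seed: int = 0) -> SpaResult:
    """Select characteristic wavelengths by SPA scored with CV-MLR RMSE."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not (1 <= max_size <= p):
        raise ValueError("max_size must be between 1 and the number of bands")
    if n < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=0)
    col_norms = np.einsum("ij,ij->j", Xc, Xc)
    if np.any(col_norms <= 1e-300):
        raise ValueError("degenerate design: a band column has zero variance")
    starts = range(p) if first_band == "scan_all" else [int(first_band)]
    kf = KFold(n_splits=min(n_folds, n), shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in kf.split(X)]

    best_curve = np.full(max_size, np.inf)
    best_prefix: list[list[int] | None] = [None] * max_size
    for s in starts:
        chain = _projection_chain(Xc, s, max_size)
        for size in range(1, len(chain) + 1):
            r = _cv_mlr_rmse(X[:, chain[:size]], y, folds)
            if r < best_curve[size - 1]:
                best_curve[size - 1] = r
                best_prefix[size - 1] = chain[:size]
    chosen_size = int(np.argmin(best_curve)) + 1  # first minimum on ties
    winner = best_prefix[chosen_size - 1]
    idx = np.sort(np.array(winner))
    return SpaResult(
        selected_indices=idx,
        chain=list(winner),
        rmse_curve=best_curve,
        chosen_size=chosen_size,
        start_index=winner[0],
        selected_wavelengths=grid.wavelengths[idx] if grid else None,
    )


def pca_fit(X: np.ndarray) -> PcaResult:
    """Full PCA on mean-centered, unscaled data."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    model = PCA(n_components=min(X.shape[0] - 1, X.shape[1]))
    scores = model.fit_transform(X)
    contrib = model.explained_variance_ratio_
    return PcaResult(
        mean=model.mean_,
        loadings=model.components_,
        scores=scores,
        contribution=contrib,
        cumulative_contribution=np.cumsum(contrib),
    )


def pca_select(result: PcaResult, threshold: float = 0.95) -> PcaResult:
    """Retain the smallest leading set of components reaching the threshold."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    cum = result.cumulative_contribution
    reach = np.nonzero(cum >= threshold - 1e-12)[0]
    k = int(reach[0]) + 1 if reach.size else len(cum)
    return replace(result, n_selected=k)


def pca_transform(result: PcaResult, X: np.ndarray,
                  n_components: int | None = None) -> np.ndarray:
    """Project new spectra with the stored center and loadings."""
    k = n_components or result.n_selected or result.loadings.shape[0]
    return (np.asarray(X, float) - result.mean) @ result.loadings[:k].T
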