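"""NIPALS principal component analysis with Wold cross-validated Q2.

R2X(cum) is the fraction of total (centered, scaled) X variance captured by
the first A components.  Q2 is estimated by element-wise deletion
cross-validation: entries of X are struck out in diagonal stripes, each
component is refitted on the incomplete matrix, and the deleted entries are
predicted; Q2(cum) = 1 - prod_a PRESS_a / SS_a.  This is the classical
chemometrics recipe behind the "predictive ability" quoted for PCA models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAModel", "fit_pca", "q2_pca"]

_NIPALS_TOL = 1e-10
_NIPALS_MAXITER = 500


@dataclass
class PCAModel:
    n_components: int
    scores: np.ndarray       # n x A
    loadings: np.ndarray     # p x A, orthonormal columns
    r2x_per_component: np.ndarray
    r2x_cumulative: np.ndarray
    q2_cumulative: float | None = None


def _check_centered(X: np.ndarray, tol: float = 1e-8) -> None:
    if np.abs(X.mean(axis=0)).max() > tol:
        raise ValueError("X must be column-centered before PCA (see scale_columns)")


def _nipals_component(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One NIPALS component of a complete matrix: (scores t, loading p)."""
    start = int(np.argmax(X.var(axis=0)))
    t = X[:, start].copy()
    if np.allclose(t, 0):
        t = X[:, int(np.argmax(np.abs(X).sum(axis=0)))].copy()
    for _ in range(_NIPALS_MAXITER):
        p = X.T @ t / (t @ t)
        p /= np.linalg.norm(p)
        t_new = X @ p
        if np.linalg.norm(t_new - t) <= _NIPALS_TOL * max(np.linalg.norm(t_new), 1e-300):
            t = t_new
            break
        t = t_new
    # sign convention: largest-magnitude loading entry positive
    j = int(np.argmax(np.abs(p)))
    if p[j] < 0:
        p = -p
        t = -t
    return t, p


def _nipals_component_missing(X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One NIPALS component when mask==False marks deleted entries."""
    Xw = np.where(mask, X, 0.0)
    start = int(np.argmax(np.nanvar(np.where(mask, X, np.nan), axis=0)))
    t = Xw[:, start].copy()
    if np.allclose(t, 0):
        t = np.ones(X.shape[0])
    for _ in range(_NIPALS_MAXITER):
        denom_p = mask.T.astype(float) @ (t * t)
        p = (Xw.T @ t) / np.where(denom_p > 0, denom_p, 1.0)
        nrm = np.linalg.norm(p)
        if nrm == 0:
            break
        p /= nrm
        denom_t = mask.astype(float) @ (p * p)
        t_new = (Xw @ p) / np.where(denom_t > 0, denom_t, 1.0)
        if np.linalg.norm(t_new - t) <= _NIPALS_TOL * max(np.linalg.norm(t_new), 1e-300):
            t = t_new
            break
        t = t_new
    j = int(np.argmax(np.abs(p)))
    if p[j] < 0:
        p, t = -p, -t
    return t, p


def fit_pca(X: np.ndarray, max_components: int, stop_rule: float | None = None,
            folds: int = 7, seed: int = 0) -> PCAModel:
    """Extract up to ``max_components`` NIPALS components in decreasing
    variance order.

    If ``stop_rule`` is a float, extraction stops before the first component
    whose Wold cross-validated per-component Q2 falls below it (the SIMCA
    "component significance" idea); the model then also carries Q2(cum) for
    the retained components.
    """
    X = np.asarray(X, dtype=float)
    _check_centered(X)
    n, p = X.shape
    max_components = int(max_components)
    if max_components < 1 or max_components > min(n - 1, p):
        raise ValueError(f"max_components must lie in [1, min(n-1, p)] = [1, {min(n - 1, p)}]")
    ss0 = float((X**2).sum())
    if ss0 == 0:
        raise ValueError("X has no variance")
    q2_comp = None
    if stop_rule is not None:
        q2_comp, _ = _wold_q2(X, max_components, folds, seed)
    E = X.copy()
    scores, loadings, r2x = [], [], []
    kept = 0
    for a in range(max_components):
        if stop_rule is not None and q2_comp[a] < stop_rule:
            break
        t, pvec = _nipals_component(E)
        scores.append(t)
        loadings.append(pvec)
        r2x.append((t @ t) / ss0)
        E = E - np.outer(t, pvec)
        kept += 1
        if (E**2).sum() / ss0 < 1e-12:
            break
    if kept == 0:  # stop rule fired immediately: keep nothing, report it
        return PCAModel(
            n_components=0,
            scores=np.zeros((n, 0)),
            loadings=np.zeros((p, 0)),
            r2x_per_component=np.zeros(0),
            r2x_cumulative=np.zeros(0),
            q2_cumulative=None,
        )
    r2x = np.asarray(r2x)
    q2cum = None
    if stop_rule is not None:
        _, q2cum_all = _wold_q2(X, kept, folds, seed)
        q2cum = float(q2cum_all[kept - 1])
    return PCAModel(
        n_components=kept,
        scores=np.column_stack(scores),
        loadings=np.column_stack(loadings),
        r2x_per_component=r2x,
        r2x_cumulative=np.cumsum(r2x),
        q2_cumulative=q2cum,
    )


def _wold_q2(X: np.ndarray, n_components: int, folds: int, seed: int
             ) -> tuple[np.ndarray, np.ndarray]:
    """Per-component and cumulative Q2 by diagonal-striping deletion.

    Deletion group g removes entries (i, j) with (i + j + offset) % folds == g,
    a pattern that spreads deletions over every row and column.  ``seed``
    only rotates the stripe offset, keeping the procedure deterministic.
    """
    n, p = X.shape
    if folds < 2:
        raise ValueError("folds must be >= 2")
    offset = int(np.random.default_rng(seed).integers(0, folds))
    ii, jj = np.meshgrid(np.arange(n), np.arange(p), indexing="ij")
    group = (ii + jj + offset) % folds
    E = X.copy()
    press_ratio = []
    for _ in range(n_components):
        ss = float((E**2).sum())
        if ss == 0:
            press_ratio.append(1.0)
            continue
        press = 0.0
        for g in range(folds):
            mask = group != g
            t, pvec = _nipals_component_missing(E, mask)
            pred = np.outer(t, pvec)
            press += float(((E - pred)[~mask] ** 2).sum())
        press_ratio.append(press / ss)
        t, pvec = _nipals_component(E)
        E = E - np.outer(t, pvec)
    ratios = np.asarray(press_ratio)
    q2_per = 1.0 - ratios
    q2_cum = 1.0 - np.cumprod(ratios)
    return q2_per, q2_cum


def q2_pca(X: np.ndarray, n_components: int, folds: int = 7, seed: int = 0) -> float:
    """Cumulative Q2 of an A-component PCA model (Wold element-wise CV)."""
    X = np.asarray(X, dtype=float)
    _check_centered(X)
    n, p = X.shape
    if folds > n * p:
        raise ValueError("more deletion groups than matrix entries")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError("n_components out of range")
    _, q2_cum = _wold_q2(X, n_components, folds, seed)
    return float(q2_cum[n_components - 1])
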