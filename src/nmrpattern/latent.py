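"""PLS-DA and OPLS-DA with VIP, S-line, cross-validation and permutation
testing.

PLS-DA regresses the (scaled) bucket matrix X on one-hot class indicators Y
via NIPALS PLS2 with X- and Y-deflation.  OPLS-DA first strips X-variation
orthogonal to the Y space into separate components, then fits the
predictive component(s) on the filtered matrix; with zero orthogonal
components it degenerates exactly to PLS-DA.  Q2 = 1 - PRESS/SSY comes from
stratified k-fold cross-validation (7 groups by default); the permutation
test refits under shuffled labels and reports the intercepts of the R2Y and
Q2 regression lines against label correlation — negative Q2 intercepts are
the conventional "not over-fitting" diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DummyY",
    "PLSModel",
    "OPLSModel",
    "VIPResult",
    "SLine",
    "PermutationResult",
    "fit_plsda",
    "vip_scores",
    "fit_oplsda",
    "s_line",
    "cross_validate",
    "permutation_test",
    "predict",
    "predict_class",
]

_TOL = 1e-10
_MAXITER = 500


@dataclass
class DummyY:
    """One-hot class indicator matrix with a fixed class order."""

    indicators: np.ndarray
    class_order: list[str]

    @classmethod
    def from_labels(cls, labels) -> "DummyY":
        labels = list(labels)
        order = list(dict.fromkeys(labels))
        mat = np.zeros((len(labels), len(order)))
        pos = {c: j for j, c in enumerate(order)}
        for i, lab in enumerate(labels):
            mat[i, pos[lab]] = 1.0
        return cls(indicators=mat, class_order=order)

    def __post_init__(self) -> None:
        mat = np.asarray(self.indicators, dtype=float)
        if mat.ndim != 2 or not np.allclose(mat.sum(axis=1), 1.0):
            raise ValueError("each indicator row must sum to 1")
        self.indicators = mat


@dataclass
class PLSModel:
    n_components: int
    weights: np.ndarray        # p x A (unit columns)
    x_loadings: np.ndarray     # p x A
    x_scores: np.ndarray       # n x A (training scores, mutually orthogonal)
    y_loadings: np.ndarray     # q x A
    coef: np.ndarray           # p x q regression coefficients
    y_mean: np.ndarray
    r2x_per_component: np.ndarray
    r2y_per_component: np.ndarray
    ssy_explained: np.ndarray  # absolute Y sum of squares per component
    class_order: list[str] | None = None
    q2_cumulative: float | None = None

    @property
    def r2x_cumulative(self) -> float:
        return float(self.r2x_per_component.sum())

    @property
    def r2y_cumulative(self) -> float:
        return float(self.r2y_per_component.sum())


@dataclass
class OPLSModel:
    predictive: PLSModel               # fitted on the filtered matrix
    orthogonal_weights: np.ndarray     # p x A_o
    orthogonal_loadings: np.ndarray    # p x A_o
    orthogonal_scores: np.ndarray      # n x A_o
    n_orthogonal: int
    r2x_predictive: float
    r2x_orthogonal: float
    class_order: list[str] | None = None
    q2_cumulative: float | None = None

    @property
    def predictive_scores(self) -> np.ndarray:
        return self.predictive.x_scores

    @property
    def r2y_cumulative(self) -> float:
        return self.predictive.r2y_cumulative


@dataclass
class VIPResult:
    vip: np.ndarray
    threshold: float = 1.0

    def selected(self) -> np.ndarray:
        """Indices with VIP strictly greater than the threshold."""
        return np.flatnonzero(self.vip > self.threshold)


@dataclass
class SLine:
    covariance: np.ndarray   # p(cov): cov(t_p, x_j)
    correlation: np.ndarray  # p(corr): corr(t_p, x_j)


@dataclass
class PermutationResult:
    n_permutations: int
    correlations: np.ndarray  # first entry = 1 (unpermuted reference)
    r2y_values: np.ndarray
    q2_values: np.ndarray
    r2_intercept: float
    q2_intercept: float


def model_to_json(model: PLSModel | OPLSModel, path) -> None:
    """Serialize a fitted PLS or OPLS model (weights/loadings as arrays)."""
    import json

    def _pls(m: PLSModel) -> dict:
        return {
            "n_components": m.n_components,
            "weights": m.weights.tolist(),
            "x_loadings": m.x_loadings.tolist(),
            "x_scores": m.x_scores.tolist(),
            "y_loadings": m.y_loadings.tolist(),
            "coef": m.coef.tolist(),
            "y_mean": m.y_mean.tolist(),
            "r2x_per_component": m.r2x_per_component.tolist(),
            "r2y_per_component": m.r2y_per_component.tolist(),
            "ssy_explained": m.ssy_explained.tolist(),
            "class_order": m.class_order,
        }

    if isinstance(model, OPLSModel):
        payload = {
            "kind": "opls",
            "predictive": _pls(model.predictive),
            "orthogonal_weights": model.orthogonal_weights.tolist(),
            "orthogonal_loadings": model.orthogonal_loadings.tolist(),
            "orthogonal_scores": model.orthogonal_scores.tolist(),
            "n_orthogonal": model.n_orthogonal,
            "r2x_predictive": model.r2x_predictive,
            "r2x_orthogonal": model.r2x_orthogonal,
            "class_order": model.class_order,
        }
    else:
        payload = {"kind": "pls", **_pls(model)}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def model_from_json(path) -> "PLSModel | OPLSModel":
    import json

    with open(path) as fh:
        d = json.load(fh)

    def _pls(p: dict) -> PLSModel:
        return PLSModel(
            n_components=int(p["n_components"]),
            weights=np.asarray(p["weights"]),
            x_loadings=np.asarray(p["x_loadings"]),
            x_scores=np.asarray(p["x_scores"]),
            y_loadings=np.asarray(p["y_loadings"]),
            coef=np.asarray(p["coef"]),
            y_mean=np.asarray(p["y_mean"]),
            r2x_per_component=np.asarray(p["r2x_per_component"]),
            r2y_per_component=np.asarray(p["r2y_per_component"]),
            ssy_explained=np.asarray(p["ssy_explained"]),
            class_order=p["class_order"],
        )

    if d["kind"] == "pls":
        return _pls(d)
    return OPLSModel(
        predictive=_pls(d["predictive"]),
        orthogonal_weights=np.asarray(d["orthogonal_weights"]),
        orthogonal_loadings=np.asarray(d["orthogonal_loadings"]),
        orthogonal_scores=np.asarray(d["orthogonal_scores"]),
        n_orthogonal=int(d["n_orthogonal"]),
        r2x_predictive=float(d["r2x_predictive"]),
        r2x_orthogonal=float(d["r2x_orthogonal"]),
        class_order=d["class_order"],
    )


def _as_y(Y) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(Y, DummyY):
        return np.asarray(Y.indicators, dtype=float), list(Y.class_order)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y, None


def fit_plsda(X: np.ndarray, Y, n_components: int) -> PLSModel:
    """NIPALS PLS2 with per-component deflation of both X and Y.

    X is expected centered (and usually scaled) upstream; Y is centered
    internally.  Weight iteration starts from the Y column of largest
    variance, making fits fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    Ymat, class_order = _as_y(Y)
    n, p = X.shape
    if Ymat.shape[0] != n:
        raise ValueError("X and Y row counts differ")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(f"n_components must lie in [1, {min(n - 1, p)}]")
    y_mean = Ymat.mean(axis=0)
    Yc = Ymat - y_mean
    if class_order is not None and np.allclose(Yc, 0):
        raise ValueError("single-class Y: the indicator matrix has no variance")
    ssx0 = float((X**2).sum())
    ssy0 = float((Yc**2).sum())
    if ssy0 == 0:
        raise ValueError("Y has no variance")
    E, F = X.copy(), Yc.copy()
    W, P, T, C = [], [], [], []
    r2x, r2y, ssy_exp = [], [], []
    for _ in range(n_components):
        u = F[:, int(np.argmax(F.var(axis=0)))].copy()
        if np.allclose(u, 0):
            break
        t = np.zeros(n)
        for _ in range(_MAXITER):
            w = E.T @ u
            nw = np.linalg.norm(w)
            if nw == 0:
                break
            w /= nw
            t_new = E @ w
            c = F.T @ t_new / (t_new @ t_new)
            u = F @ c / (c @ c)
            if np.linalg.norm(t_new - t) <= _TOL * max(np.linalg.norm(t_new), 1e-300):
                t = t_new
                break
            t = t_new
        tt = float(t @ t)
        if tt <= 1e-300:
            break
        pvec = E.T @ t / tt
        c = F.T @ t / tt
        E = E - np.outer(t, pvec)
        F = F - np.outer(t, c)
        W.append(w)
        P.append(pvec)
        T.append(t)
        C.append(c)
        r2x.append(tt * float(pvec @ pvec) / ssx0 if ssx0 > 0 else 0.0)
        explained = tt * float(c @ c)
        ssy_exp.append(explained)
        r2y.append(explained / ssy0)
    if not W:
        raise ValueError("no PLS component could be extracted")
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    Tm = np.column_stack(T)
    Cm = np.column_stack(C)  # q x A
    coef = Wm @ np.linalg.solve(Pm.T @ Wm, Cm.T)
    return PLSModel(
        n_components=Wm.shape[1],
        weights=Wm,
        x_loadings=Pm,
        x_scores=Tm,
        y_loadings=Cm,
        coef=coef,
        y_mean=y_mean,
        r2x_per_component=np.asarray(r2x),
        r2y_per_component=np.asarray(r2y),
        ssy_explained=np.asarray(ssy_exp),
        class_order=class_order,
    )


def vip_scores(model: PLSModel, threshold: float = 1.0) -> VIPResult:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_aj/||w_a||)^2 / sum_a SSY_a ) where
    SSY_a is the Y sum of squares explained by component a.  The mean
    square of VIP is 1, so VIP > 1 flags above-average contributors.
    """
    W = model.weights
    p = W.shape[0]
    ssy = model.ssy_explained
    if ssy.sum() <= 0:
        raise ValueError("model explains no Y variance; VIP undefined")
    wnorm2 = (W**2) / (W**2).sum(axis=0)
    vip = np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())
    return VIPResult(vip=vip, threshold=threshold)


def _y_weight_basis(X: np.ndarray, Yc: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the X'Y weight space (the dummy-Y projection)."""
    Wy = X.T @ Yc
    q, r = np.linalg.qr(Wy)
    keep = np.abs(np.diag(r)) > 1e-12 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def fit_oplsda(X: np.ndarray, Y, n_predictive: int | None = None,
               n_orthogonal: int = 1) -> OPLSModel:
    """Orthogonal-projection PLS-DA.

    Orthogonal components are extracted by taking each candidate X-loading
    and removing its projection onto the Y-weight space (for multi-class Y,
    the span of X'Y), leaving purely class-orthogonal variation that is
    deflated out of X.  The predictive part is then a plain PLS2 fit on the
    filtered matrix, with (classes - 1) components by default.
    """
    X = np.asarray(X, dtype=float)
    Ymat, class_order = _as_y(Y)
    n, p = X.shape
    q = Ymat.shape[1]
    if n_predictive is None:
        n_predictive = max(1, q - 1)
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    if n_orthogonal + n_predictive > min(n - 1, p):
        raise ValueError("n_orthogonal + n_predictive exceeds the rank bound min(n-1, p)")
    Yc = Ymat - Ymat.mean(axis=0)
    ssx0 = float((X**2).sum())
    basis = _y_weight_basis(X, Yc)
    E = X.copy()
    Wo, Po, To = [], [], []
    for _ in range(n_orthogonal):
        # candidate loading from the current leading PLS component
        u = Yc[:, int(np.argmax(Yc.var(axis=0)))]
        w = E.T @ u
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        for _ in range(_MAXITER):
            t = E @ w
            c = Yc.T @ t / (t @ t)
            u2 = Yc @ c / (c @ c)
            w_new = E.T @ u2
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) <= _TOL:
                w = w_new
                break
            w = w_new
        t = E @ w
        pvec = E.T @ t / (t @ t)
        w_o = pvec - basis @ (basis.T @ pvec)
        n_wo = np.linalg.norm(w_o)
        if n_wo <= 1e-12 * max(np.linalg.norm(pvec), 1e-300):
            break  # no orthogonal variation left
        w_o /= n_wo
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        Wo.append(w_o)
        Po.append(p_o)
        To.append(t_o)
    n_orth = len(Wo)
    inner = fit_plsda(E, Y, n_components=n_predictive)
    r2x_orth = sum(float(t @ t) * float(pv @ pv) for t, pv in zip(To, Po)) / ssx0 if ssx0 > 0 else 0.0
    # predictive R2X measured against the ORIGINAL X variance
    r2x_pred = float(sum(
        (inner.x_scores[:, a] @ inner.x_scores[:, a]) * (inner.x_loadings[:, a] @ inner.x_loadings[:, a])
        for a in range(inner.n_components)
    )) / ssx0 if ssx0 > 0 else 0.0
    return OPLSModel(
        predictive=inner,
        orthogonal_weights=np.column_stack(Wo) if Wo else np.zeros((p, 0)),
        orthogonal_loadings=np.column_stack(Po) if Po else np.zeros((p, 0)),
        orthogonal_scores=np.column_stack(To) if To else np.zeros((n, 0)),
        n_orthogonal=n_orth,
        r2x_predictive=r2x_pred,
        r2x_orthogonal=r2x_orth,
        class_order=class_order if class_order is not None else inner.class_order,
    )


def _filter_orthogonal(model: OPLSModel, X: np.ndarray) -> np.ndarray:
    E = np.asarray(X, dtype=float).copy()
    for a in range(model.n_orthogonal):
        t_o = E @ model.orthogonal_weights[:, a]
        E = E - np.outer(t_o, model.orthogonal_loadings[:, a])
    return E


def predict(model: PLSModel | OPLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted Y (dummy scale) for rows scaled like the training matrix."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if isinstance(model, OPLSModel):
        if X_new.shape[1] != model.orthogonal_weights.shape[0] and model.n_orthogonal:
            raise ValueError("column count mismatch with the fitted model")
        X_new = _filter_orthogonal(model, X_new)
        model = model.predictive
    if X_new.shape[1] != model.coef.shape[0]:
        raise ValueError("column count mismatch with the fitted model")
    return X_new @ model.coef + model.y_mean


def predict_class(model: PLSModel | OPLSModel, X_new: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Class labels by argmax over predicted dummy-Y columns.

    Ties resolve to the lowest class index (logged as a warning).
    """
    yhat = predict(model, X_new)
    if yhat.shape[1] < 2:
        raise ValueError("class prediction needs a model fitted on >= 2 indicator columns")
    order = model.class_order or [f"class{j}" for j in range(yhat.shape[1])]
    idx = np.argmax(yhat, axis=1)
    ties = (yhat == yhat.max(axis=1, keepdims=True)).sum(axis=1) > 1
    if np.any(ties):
        warnings.warn(f"{int(ties.sum())} tied prediction(s) resolved to the lowest class index",
                      stacklevel=2)
    return [order[i] for i in idx], yhat


def s_line(model: OPLSModel, X: np.ndarray) -> SLine:
    """S-line/S-plot statistics of a two-class OPLS-DA model.

    p(cov)_j = cov(t_p, x_j) and p(corr)_j = corr(t_p, x_j) against the
    predictive score.  Compute on centered (not variance-scaled) data to
    retain the magnitude axis.  Zero-variance columns get correlation 0.
    """
    if model.class_order is not None and len(model.class_order) > 2:
        raise ValueError("S-line is defined for two-class models")
    X = np.asarray(X, dtype=float)
    t = model.predictive_scores[:, 0]
    if X.shape[0] != t.shape[0]:
        raise ValueError("X rows must match the training scores")
    n = X.shape[0]
    tc = t - t.mean()
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ tc / (n - 1)
    sx = Xc.std(axis=0, ddof=1)
    st = tc.std(ddof=1)
    zero = sx <= 1e-300
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero-variance column(s): correlation set to 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(zero, 0.0, cov / (np.where(zero, 1.0, sx) * st))
    corr = np.clip(corr, -1.0, 1.0)
    return SLine(covariance=cov, correlation=corr)


def _stratified_folds(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Fold assignment per row, stratified by class; deterministic in seed."""
    rng = np.random.default_rng(seed)
    assign = np.full(len(labels), -1, dtype=int)
    start = 0
    for lab in dict.fromkeys(labels.tolist()):
        idx = np.flatnonzero(labels == lab)
        perm = rng.permutation(idx)
        for k, i in enumerate(perm):
            assign[i] = (start + k) % folds
        start += len(idx)  # rotate the starting fold between classes
    # a fold's TRAINING side must keep every class
    for lab in dict.fromkeys(labels.tolist()):
        idx = np.flatnonzero(labels == lab)
        for g in range(folds):
            if np.all(assign[idx] == g):
                if len(idx) < 2:
                    raise ValueError(f"class {lab!r} has a single sample; cannot stratify")
                moved = idx[: len(idx) // 2]
                assign[moved] = (g + 1) % folds
                warnings.warn(f"fold {g} contained all of class {lab!r}; reassigned", stacklevel=2)
    return assign


def cross_validate(X: np.ndarray, Y, n_components: int, folds: int = 7, seed: int = 0,
                   model_kind: str = "pls", n_orthogonal: int = 1) -> tuple[float, float]:
    """(R2Y(cum), Q2(cum)) of a PLS-DA or OPLS-DA model.

    Q2 = 1 - PRESS/SSY with PRESS accumulated over held-out rows of a
    stratified k-fold split; each fold recenters X and Y by its training
    means.  SSY is the total centered Y sum of squares pooled over dummy
    columns.
    """
    X = np.asarray(X, dtype=float)
    Ymat, class_order = _as_y(Y)
    n = X.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError("more folds than samples")
    if model_kind not in ("pls", "opls"):
        raise ValueError(f"unknown model_kind {model_kind!r}")
    strat = np.asarray(
        [class_order[j] for j in np.argmax(Ymat, axis=1)] if class_order is not None
        else np.argmax(Ymat, axis=1).astype(str)
    )
    assign = _stratified_folds(strat, folds, seed)
    ssy = float(((Ymat - Ymat.mean(axis=0)) ** 2).sum())
    press = 0.0
    for g in range(folds):
        test = assign == g
        train = ~test
        if not np.any(test):
            continue
        x_mean = X[train].mean(axis=0)
        Xtr = X[train] - x_mean
        Xte = X[test] - x_mean
        Ytr = Ymat[train]
        if model_kind == "pls":
            m = fit_plsda(Xtr, Ytr, n_components=n_components)
        else:
            m = fit_oplsda(Xtr, Ytr, n_predictive=n_components, n_orthogonal=n_orthogonal)
        yhat = predict(m, Xte)
        press += float(((Ymat[test] - yhat) ** 2).sum())
    if model_kind == "pls":
        full = fit_plsda(X, Ymat if class_order is None else DummyY(Ymat, class_order), n_components)
        r2y = full.r2y_cumulative
    else:
        full = fit_oplsda(X, Ymat if class_order is None else DummyY(Ymat, class_order),
                          n_predictive=n_components, n_orthogonal=n_orthogonal)
        r2y = full.r2y_cumulative
    return float(r2y), float(1.0 - press / ssy)


def permutation_test(X: np.ndarray, Y, n_permutations: int = 200, n_components: int = 2,
                     folds: int = 7, seed: int = 0, model_kind: str = "pls",
                     n_orthogonal: int = 1) -> PermutationResult:
    """Label-permutation validation at fixed model size.

    Entry 0 is the unpermuted reference (correlation 1); each permutation
    shuffles the rows of Y, refits, and records (corr(Y_perm, Y), R2Y, Q2).
    Intercepts come from least-squares lines of R2Y and Q2 against the
    correlation, reference point included.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    Ymat, class_order = _as_y(Y)
    Yc = Ymat - Ymat.mean(axis=0)
    if float((Yc**2).sum()) == 0:
        raise ValueError("Y holds a single class; permutation correlation is undefined")
    Yobj = DummyY(Ymat, class_order) if class_order is not None else Ymat

    def _cv(Yarg):
        return cross_validate(X, Yarg, n_components=n_components, folds=folds, seed=seed,
                              model_kind=model_kind, n_orthogonal=n_orthogonal)

    corrs = [1.0]
    r2s, q2s = [], []
    r2_ref, q2_ref = _cv(Yobj)
    r2s.append(r2_ref)
    q2s.append(q2_ref)
    rng = np.random.default_rng(seed)
    denom = float((Yc**2).sum())
    for _ in range(n_permutations):
        perm = rng.permutation(Ymat.shape[0])
        Yp = Ymat[perm]
        Ypc = Yp - Yp.mean(axis=0)
        corr = float((Ypc * Yc).sum() / denom)  # equal column scales: denom = ||Yc||^2
        Yparg = DummyY(Yp, class_order) if class_order is not None else Yp
        r2, q2 = _cv(Yparg)
        corrs.append(corr)
        r2s.append(r2)
        q2s.append(q2)
    corrs_a = np.asarray(corrs)
    A = np.column_stack([np.ones_like(corrs_a), corrs_a])
    r2_line, *_ = np.linalg.lstsq(A, np.asarray(r2s), rcond=None)
    q2_line, *_ = np.linalg.lstsq(A, np.asarray(q2s), rcond=None)
    return PermutationResult(
        n_permutations=n_permutations,
        correlations=corrs_a,
        r2y_values=np.asarray(r2s),
        q2_values=np.asarray(q2s),
        r2_intercept=float(r2_line[0]),
        q2_intercept=float(q2_line[0]),
    )
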