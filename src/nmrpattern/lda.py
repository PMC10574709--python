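"""Stepwise linear discriminant analysis with Fisher classification
functions.

Variables enter greedily by minimizing Wilks' lambda (the ratio of within-
to total-scatter determinants), gated by probability-of-F thresholds
(enter at p <= 0.05, remove at p >= 0.10 by default).  The fitted model
carries one linear classification function per class,

    g_k(x) = mu_k' S^-1 x - 1/2 mu_k' S^-1 mu_k + log pi_k,

with S the pooled within-class covariance; argmax over classes is the
assignment rule, equivalent to the shared-covariance Gaussian Bayes rule.
Canonical axes for score plots come from the between/within generalized
eigenproblem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy import stats

__all__ = [
    "LDAModel",
    "StepwiseRecord",
    "StepwiseEvent",
    "stepwise_select",
    "fit_lda",
    "classify",
    "predict_labels",
    "loocv",
    "canonical_scores",
    "model_from_functions",
]


@dataclass(frozen=True)
class StepwiseEvent:
    action: str           # "enter" or "remove"
    variable: int         # original column index
    wilks_lambda: float
    f_statistic: float
    p_value: float


@dataclass
class StepwiseRecord:
    events: list[StepwiseEvent] = field(default_factory=list)

    @property
    def entered(self) -> list[int]:
        current: list[int] = []
        for ev in self.events:
            if ev.action == "enter":
                current.append(ev.variable)
            else:
                current.remove(ev.variable)
        return current


@dataclass
class LDAModel:
    selected_variables: list[int]          # original column indices
    class_order: list[str]
    coefficients: np.ndarray               # classes x |selected|
    intercepts: np.ndarray                 # classes
    class_means: np.ndarray | None = None  # classes x |selected|
    pooled_covariance: np.ndarray | None = None
    priors: np.ndarray | None = None
    canonical_axes: np.ndarray | None = None  # |selected| x (classes-1)
    grand_mean: np.ndarray | None = None


def _scatters(X: np.ndarray, labels: np.ndarray, classes: list) -> tuple[np.ndarray, np.ndarray]:
    """Within-class and total scatter (cross-product) matrices."""
    mu = X.mean(axis=0)
    T = (X - mu).T @ (X - mu)
    W = np.zeros_like(T)
    for c in classes:
        Xi = X[labels == c]
        d = Xi - Xi.mean(axis=0)
        W += d.T @ d
    return W, T


def _wilks(W: np.ndarray, T: np.ndarray, idx: list[int]) -> float | None:
    """Wilks' lambda on a variable subset; None when the subset is singular."""
    if not idx:
        return 1.0
    sub = np.ix_(idx, idx)
    sW, ldW = np.linalg.slogdet(W[sub])
    sT, ldT = np.linalg.slogdet(T[sub])
    if sW <= 0 or sT <= 0:
        return None
    return float(np.exp(ldW - ldT))


def stepwise_select(X: np.ndarray, labels, p_enter: float = 0.05, p_remove: float = 0.10,
                    max_steps: int = 200) -> tuple[list[int], StepwiseRecord]:
    """Greedy Wilks'-lambda stepwise variable selection.

    At each step the candidate with the smallest partial-F p-value enters if
    p <= p_enter; afterwards any entered variable with p >= p_remove leaves.
    Candidates whose within-class scatter turns singular are skipped with a
    warning.  Raises when nothing can enter at all.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))
    g = len(classes)
    n, p = X.shape
    if g < 2:
        raise ValueError("stepwise_select needs >= 2 classes")
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    if not (0 <= p_enter < p_remove):
        raise ValueError("need 0 <= p_enter < p_remove")
    W, T = _scatters(X, labels, classes)
    selected: list[int] = []
    record = StepwiseRecord()
    lam_cur = 1.0
    for _ in range(max_steps):
        changed = False
        m = len(selected)
        df2 = n - g - m
        if df2 >= 1:
            best = None  # (p_value, F, lambda_new, j)
            for j in range(p):
                if j in selected:
                    continue
                lam_new = _wilks(W, T, selected + [j])
                if lam_new is None or lam_new <= 0:
                    warnings.warn(f"variable {j} skipped: singular scatter", stacklevel=2)
                    continue
                F = (df2 / (g - 1)) * (lam_cur / lam_new - 1.0)
                F = max(F, 0.0)
                pval = float(stats.f.sf(F, g - 1, df2))
                if best is None or (pval, -F) < (best[0], -best[1]):
                    best = (pval, F, lam_new, j)
            if best is not None and best[0] <= p_enter:
                pval, F, lam_new, j = best
                selected.append(j)
                lam_cur = lam_new
                record.events.append(StepwiseEvent("enter", j, lam_cur, F, pval))
                changed = True
        # removal pass
        if len(selected) > 1:
            m = len(selected)
            df2r = n - g - (m - 1)
            worst = None
            for j in selected[:-1] if changed else selected:
                lam_red = _wilks(W, T, [k for k in selected if k != j])
                if lam_red is None:
                    continue
                F = (df2r / (g - 1)) * (lam_red / lam_cur - 1.0)
                F = max(F, 0.0)
                pval = float(stats.f.sf(F, g - 1, df2r))
                if worst is None or pval > worst[0]:
                    worst = (pval, F, j, lam_red)
            if worst is not None and worst[0] >= p_remove:
                pval, F, j, lam_red = worst
                selected.remove(j)
                lam_cur = lam_red if lam_red is not None else lam_cur
                record.events.append(StepwiseEvent("remove", j, lam_cur, F, pval))
                changed = True
        if not changed:
            break
    if not selected:
        raise ValueError(f"no variable met the entry criterion p <= {p_enter}")
    return selected, record


def fit_lda(X_sel: np.ndarray, labels, priors: str | np.ndarray = "equal",
            selected_variables: list[int] | None = None,
            allow_singleton: bool = False) -> LDAModel:
    """Fisher LDA on an already-reduced matrix.

    ``priors`` is 'equal' (default), 'proportional', or an explicit vector in
    class order.  A singular pooled covariance is ridged once by
    1e-8 * trace/p on the diagonal (with a warning).  A class with a single
    sample is an error unless ``allow_singleton`` (used by LOOCV refits,
    where held-out rows can deplete a small class).
    """
    X = np.asarray(X_sel, dtype=float)
    labels = np.asarray(labels)
    classes = list(dict.fromkeys(labels.tolist()))
    g = len(classes)
    n, p = X.shape
    if g < 2:
        raise ValueError("need >= 2 classes")
    counts = np.array([np.sum(labels == c) for c in classes])
    if np.any(counts < 2) and not allow_singleton:
        bad = classes[int(np.argmin(counts))]
        raise ValueError(f"class {bad!r} has a single sample; covariance undefined")
    means = np.vstack([X[labels == c].mean(axis=0) for c in classes])
    Sw = np.zeros((p, p))
    for c, mu in zip(classes, means):
        d = X[labels == c] - mu
        Sw += d.T @ d
    Sw /= max(n - g, 1)
    if isinstance(priors, str):
        if priors == "equal":
            pri = np.full(g, 1.0 / g)
        elif priors == "proportional":
            pri = counts / counts.sum()
        else:
            raise ValueError(f"unknown priors {priors!r}")
    else:
        pri = np.asarray(priors, dtype=float)
        pri = pri / pri.sum()
    sign, _ = np.linalg.slogdet(Sw)
    if sign <= 0 or np.linalg.cond(Sw) > 1e12:
        eps = max(1e-8 * np.trace(Sw) / p, 1e-12)
        Sw = Sw + eps * np.eye(p)
        warnings.warn(f"pooled covariance ridged by {eps:.3g} on the diagonal", stacklevel=2)
    Sinv_mu = np.linalg.solve(Sw, means.T).T       # classes x p
    coefficients = Sinv_mu
    intercepts = -0.5 * np.einsum("ij,ij->i", Sinv_mu, means) + np.log(pri)
    # canonical axes: between-class vs pooled within-class metric
    grand = X.mean(axis=0)
    Sb = np.zeros((p, p))
    for cnt, mu in zip(counts, means):
        d = (mu - grand)[:, None]
        Sb += cnt * (d @ d.T)
    Sb /= max(n - g, 1)
    evals, evecs = sla.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][: g - 1]
    axes = evecs[:, order]
    for k in range(axes.shape[1]):  # sign convention: largest entry positive
        j = int(np.argmax(np.abs(axes[:, k])))
        if axes[j, k] < 0:
            axes[:, k] = -axes[:, k]
    return LDAModel(
        selected_variables=list(selected_variables) if selected_variables is not None else list(range(p)),
        class_order=[str(c) for c in classes],
        coefficients=coefficients,
        intercepts=intercepts,
        class_means=means,
        pooled_covariance=Sw,
        priors=pri,
        canonical_axes=axes,
        grand_mean=grand,
    )


def classify(model: LDAModel, x: np.ndarray) -> tuple[str, np.ndarray]:
    """(label, per-class classification-function scores) for one sample.

    Ties resolve to the lowest class index.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.coefficients.shape[1]:
        raise ValueError(
            f"expected {model.coefficients.shape[1]} selected-variable values, got {x.shape[0]}"
        )
    scores = model.coefficients @ x + model.intercepts
    return model.class_order[int(np.argmax(scores))], scores


def predict_labels(model: LDAModel, X: np.ndarray) -> list[str]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    scores = X @ model.coefficients.T + model.intercepts
    return [model.class_order[int(i)] for i in np.argmax(scores, axis=1)]


def loocv(X_sel: np.ndarray, labels, priors: str | np.ndarray = "equal"
          ) -> tuple[float, list[str]]:
    """Leave-one-out accuracy: refit with each sample held out in turn."""
    X = np.asarray(X_sel, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    classes = list(dict.fromkeys(labels.tolist()))
    if n < len(classes) + 1:
        raise ValueError("need at least classes + 1 samples for LOOCV")
    preds: list[str] = []
    correct = 0
    for i in range(n):
        keep = np.arange(n) != i
        remaining = set(labels[keep].tolist())
        if len(remaining) == 1:
            # the held-out sample was its class's only member
            lab = next(iter(remaining))
        else:
            model = fit_lda(X[keep], labels[keep], priors=priors, allow_singleton=True)
            lab = predict_labels(model, X[i])[0]
        preds.append(lab)
        if lab == str(labels[i]):
            correct += 1
    return correct / n, preds


def canonical_scores(model: LDAModel, X: np.ndarray) -> np.ndarray:
    """Projections onto the canonical discriminant axes (axis 1 first)."""
    if model.canonical_axes is None or model.grand_mean is None:
        raise ValueError("model carries no canonical axes (imported coefficient table?)")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return (X - model.grand_mean) @ model.canonical_axes


def model_to_json(model: LDAModel, path) -> None:
    """Serialize a model (fitted or imported coefficient table) to JSON."""
    import json

    def _arr(a):
        return None if a is None else np.asarray(a).tolist()

    with open(path, "w") as fh:
        json.dump({
            "selected_variables": list(model.selected_variables),
            "class_order": list(model.class_order),
            "coefficients": _arr(model.coefficients),
            "intercepts": _arr(model.intercepts),
            "class_means": _arr(model.class_means),
            "pooled_covariance": _arr(model.pooled_covariance),
            "priors": _arr(model.priors),
            "canonical_axes": _arr(model.canonical_axes),
            "grand_mean": _arr(model.grand_mean),
        }, fh)


def model_from_json(path) -> LDAModel:
    import json

    with open(path) as fh:
        d = json.load(fh)

    def _arr(key):
        return None if d.get(key) is None else np.asarray(d[key], dtype=float)

    return LDAModel(
        selected_variables=[int(i) for i in d["selected_variables"]],
        class_order=[str(c) for c in d["class_order"]],
        coefficients=np.asarray(d["coefficients"], dtype=float),
        intercepts=np.asarray(d["intercepts"], dtype=float),
        class_means=_arr("class_means"),
        pooled_covariance=_arr("pooled_covariance"),
        priors=_arr("priors"),
        canonical_axes=_arr("canonical_axes"),
        grand_mean=_arr("grand_mean"),
    )


def model_from_functions(coefficients: np.ndarray, intercepts: np.ndarray,
                         class_order: list[str],
                         selected_variables: list[int] | None = None) -> LDAModel:
    """Build an LDAModel directly from a table of classification functions
    (classes x coefficients plus an intercept per class), e.g. published
    discriminant functions.  Such a model classifies but has no canonical
    axes or covariance."""
    coefficients = np.asarray(coefficients, dtype=float)
    intercepts = np.asarray(intercepts, dtype=float).ravel()
    if coefficients.ndim != 2 or coefficients.shape[0] != len(class_order) \
            or intercepts.shape[0] != len(class_order):
        raise ValueError("need one coefficient row and one intercept per class")
    return LDAModel(
        selected_variables=list(selected_variables)
        if selected_variables is not None else list(range(coefficients.shape[1])),
        class_order=list(class_order),
        coefficients=coefficients,
        intercepts=intercepts,
    )
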