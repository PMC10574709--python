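"""Two-stage VIP screening with PLS-DA/OPLS-DA intersection.

Stage 1 fits a PLS-DA on the full matrix and keeps variables with VIP > 1.
Stage 2 refits both a PLS-DA and an OPLS-DA on the reduced matrix and
screens each by VIP again.  The characteristic variables are the
intersection of the two stage-2 sets, tracked by their original variable
identities so reduction cannot introduce index drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .latent import DummyY, cross_validate, fit_oplsda, fit_plsda, vip_scores

__all__ = ["SelectionTrace", "select_by_vip", "intersect_cascade", "choose_components"]


@dataclass
class SelectionTrace:
    """Audit record of the variable-reduction cascade (original indices)."""

    stage1_selected: np.ndarray
    stage2_pls: np.ndarray
    stage2_opls: np.ndarray
    characteristic: np.ndarray
    threshold: float
    components: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage1_selected": [int(i) for i in self.stage1_selected],
            "stage2_pls": [int(i) for i in self.stage2_pls],
            "stage2_opls": [int(i) for i in self.stage2_opls],
            "characteristic": [int(i) for i in self.characteristic],
            "threshold": float(self.threshold),
            "components": dict(self.components),
        }

    def __post_init__(self) -> None:
        s1 = set(self.stage1_selected.tolist())
        s2p = set(self.stage2_pls.tolist())
        s2o = set(self.stage2_opls.tolist())
        ch = set(self.characteristic.tolist())
        if not (ch <= s2p and ch <= s2o and s2p <= s1 and s2o <= s1):
            raise ValueError("selection trace violates the nesting invariant")


def choose_components(X: np.ndarray, Y, max_components: int = 6, folds: int = 7,
                      seed: int = 0, min_gain: float = 0.01,
                      model_kind: str = "pls", n_orthogonal: int = 1) -> int:
    """Smallest A at which cumulative Q2 stops improving by > ``min_gain``.

    The cross-validated stop rule used wherever a component count is not
    fixed a priori; deterministic given the seed.
    """
    n, p = np.asarray(X).shape
    cap = min(max_components, n - 1 - (n_orthogonal if model_kind == "opls" else 0), p)
    best_a, best_q2 = 1, -np.inf
    for a in range(1, max(cap, 1) + 1):
        _, q2 = cross_validate(X, Y, n_components=a, folds=folds, seed=seed,
                               model_kind=model_kind, n_orthogonal=n_orthogonal)
        if q2 > best_q2 + min_gain:
            best_a, best_q2 = a, q2
        else:
            break
    return best_a


def select_by_vip(X: np.ndarray, Y, threshold: float = 1.0,
                  n_components: int | None = None, folds: int = 7, seed: int = 0,
                  model_kind: str = "pls", n_orthogonal: int = 1) -> np.ndarray:
    """Indices (ascending) whose VIP is strictly greater than ``threshold``.

    Fits a PLS-DA (or OPLS-DA) first; when ``n_components`` is None the
    cross-validated stop rule picks it.  An empty selection raises — the
    caller decides how to proceed.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    X = np.asarray(X, dtype=float)
    if n_components is None:
        n_components = choose_components(X, Y, folds=folds, seed=seed,
                                         model_kind=model_kind, n_orthogonal=n_orthogonal)
    if model_kind == "pls":
        model = fit_plsda(X, Y, n_components=n_components)
        vip = vip_scores(model, threshold=threshold)
    else:
        omodel = fit_oplsda(X, Y, n_predictive=n_components, n_orthogonal=n_orthogonal)
        vip = vip_scores(omodel.predictive, threshold=threshold)
    sel = vip.selected()
    if sel.size == 0:
        raise ValueError(f"VIP > {threshold} selects no variables")
    return np.sort(sel)


def intersect_cascade(X_train: np.ndarray, Y_train, threshold: float = 1.0,
                      folds: int = 7, seed: int = 0,
                      n_orthogonal: int = 1) -> SelectionTrace:
    """The full two-stage cascade; all index sets refer to the input matrix."""
    X_train = np.asarray(X_train, dtype=float)
    Ymat = Y_train.indicators if isinstance(Y_train, DummyY) else np.asarray(Y_train, dtype=float)
    if Ymat.ndim != 2 or Ymat.shape[1] < 2 or np.allclose(Ymat - Ymat.mean(axis=0), 0):
        raise ValueError("intersect_cascade needs >= 2 classes in Y_train")
    components: dict[str, int] = {}

    def _stage(Xs, kind, stage_name, n_orth):
        try:
            a = choose_components(Xs, Y_train, folds=folds, seed=seed,
                                  model_kind=kind, n_orthogonal=n_orth)
            components[stage_name] = a
            return select_by_vip(Xs, Y_train, threshold=threshold, n_components=a,
                                 folds=folds, seed=seed, model_kind=kind, n_orthogonal=n_orth)
        except ValueError as exc:
            raise ValueError(f"cascade stage {stage_name!r} failed: {exc}") from exc

    stage1 = _stage(X_train, "pls", "stage1_pls", 0)
    X_red = X_train[:, stage1]
    s2p_local = _stage(X_red, "pls", "stage2_pls", 0)
    s2o_local = _stage(X_red, "opls", "stage2_opls", n_orthogonal)
    stage2_pls = stage1[s2p_local]
    stage2_opls = stage1[s2o_local]
    characteristic = np.intersect1d(stage2_pls, stage2_opls)
    if characteristic.size == 0:
        raise ValueError("cascade stage 'intersection' failed: empty characteristic set")
    return SelectionTrace(
        stage1_selected=stage1,
        stage2_pls=np.sort(stage2_pls),
        stage2_opls=np.sort(stage2_opls),
        characteristic=characteristic,
        threshold=threshold,
        components=components,
    )
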