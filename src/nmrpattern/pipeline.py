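"""End-to-end orchestration of the two study designs.

``run_species_analysis`` executes the full three-class workflow:
bucket -> TMS-normalize -> stratified split -> PCA overview -> VIP
intersection cascade -> stepwise LDA (with LOOCV and test-set scoring) ->
verification PLS-DA/OPLS-DA on the stepwise variables with cross-validated
R2Y/Q2 and label-permutation intercepts, plus an S-line on the binary
LF-vs-LJF contrast.  ``run_processing_analysis`` runs the binary variant
(OPLS-DA + permutation, then VIP > 1 -> stepwise LDA).

Every stage draws its randomness from a child seed derived by hashing the
stage name together with the single pipeline seed, so toggling one stage
never shifts another's stream.  Reports are JSON; tables are CSV.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import read_labels_csv, read_spectrum_csv, write_bucket_table, write_partition
from .latent import (DummyY, cross_validate, fit_oplsda, fit_plsda,
                     permutation_test, predict_class, s_line, vip_scores)
from .lda import canonical_scores, fit_lda, loocv, predict_labels, stepwise_select
from .pca import fit_pca, q2_pca
from .preprocess import (BucketConfig, assemble_table, apply_scaling,
                         scale_columns, split_train_test)
from .select import choose_components, intersect_cascade, select_by_vip
from .synthetic import (CohortDesign, default_processing_design,
                        default_species_design, simulate_cohort)

__all__ = ["PipelineConfig", "run_species_analysis", "run_processing_analysis", "child_seed"]


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived by hashing."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything a run needs; ``seed`` is mandatory and fans out per stage."""

    seed: int
    output_dir: str = "nmrpattern_out"
    spectra_dir: str | None = None       # directory of per-sample CSVs + labels.csv
    design: str = "species"              # 'species' | 'processing' when simulating
    bucket_low: float = -0.025
    bucket_high: float = 9.975
    bucket_width: float = 0.05
    scaling: str = "uv"
    cv_folds: int = 7
    vip_threshold: float = 1.0
    n_permutations: int = 200
    p_enter: float = 0.05
    p_remove: float = 0.10
    train_counts: dict[str, int] = field(default_factory=dict)
    max_pca_components: int = 15
    max_components: int = 6

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 < self.bucket_width <= self.bucket_high - self.bucket_low):
            raise ValueError("bucket width out of bounds")
        if self.scaling not in ("center", "uv", "pareto"):
            raise ValueError(f"unknown scaling {self.scaling!r}")
        if self.cv_folds < 2 or self.n_permutations < 1 or self.vip_threshold < 0:
            raise ValueError("cv_folds >= 2, n_permutations >= 1, vip_threshold >= 0 required")
        if not (0 <= self.p_enter < self.p_remove):
            raise ValueError("need 0 <= p_enter < p_remove")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _load_or_simulate(config: PipelineConfig, kind: str):
    if config.spectra_dir is not None:
        d = Path(config.spectra_dir)
        labels = read_labels_csv(d / "labels.csv")
        return [read_spectrum_csv(d / f"{sid}.csv", sample_id=sid, label=lab)
                for sid, lab in labels.items()]
    seed = child_seed(config.seed, "simulate")
    if kind == "species":
        design = default_species_design(seed=seed)
    else:
        design = default_processing_design(seed=seed)
    return simulate_cohort(design)


def _default_train_counts(labels: list[str]) -> dict[str, int]:
    # hold out ~40% per class, at least one test sample per class
    counts: dict[str, int] = {}
    for lab in dict.fromkeys(labels):
        n = labels.count(lab)
        counts[lab] = max(1, min(n - 1, int(round(n * 0.61))))
    return counts


_SPECIES_TRAIN_COUNTS = {"cLJF": 47, "wLJF": 6, "LF": 8}
_PROCESSING_TRAIN_COUNTS = {"hot_air": 26, "sun": 28}


def run_species_analysis(config: PipelineConfig) -> dict:
    """Run the three-class analysis; returns (and writes) the report dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "analysis": "species",
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seeds": {},
    }
    spectra = _load_or_simulate(config, "species")
    bucket_cfg = BucketConfig(config.bucket_low, config.bucket_high, config.bucket_width)
    table = assemble_table(spectra, bucket_cfg)
    write_bucket_table(table, out / "bucket_table.csv")
    labels = list(table.labels)

    split_seed = child_seed(config.seed, "split")
    report["seeds"]["split"] = split_seed
    counts = dict(config.train_counts) if config.train_counts else (
        _SPECIES_TRAIN_COUNTS if set(_SPECIES_TRAIN_COUNTS) == set(labels)
        else _default_train_counts(labels)
    )
    part = split_train_test(table, counts, seed=split_seed)
    write_partition(part, out / "partition.json")
    train = table.subset_rows(part.train_indices)
    test = table.subset_rows(part.test_indices)
    report["n_train"] = int(train.n_samples)
    report["n_test"] = int(test.n_samples)
    report["n_buckets"] = int(table.n_buckets)
    report["train_matrix_shape"] = [int(train.n_samples), int(train.n_buckets)]

    # --- PCA overview on the full cohort -------------------------------
    pca_seed = child_seed(config.seed, "pca")
    report["seeds"]["pca"] = pca_seed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X_all, _ = scale_columns(table.values, config.scaling)
    max_a = min(config.max_pca_components, table.n_samples - 1, table.n_buckets)
    pca = fit_pca(X_all, max_components=max_a, stop_rule=0.0,
                  folds=config.cv_folds, seed=pca_seed)
    if pca.n_components == 0:  # stop rule fired immediately: keep one PC anyway
        pca = fit_pca(X_all, max_components=1)
        pca.q2_cumulative = q2_pca(X_all, 1, folds=config.cv_folds, seed=pca_seed)
    report["pca"] = {
        "n_components": int(pca.n_components),
        "r2x_cum": float(pca.r2x_cumulative[-1]),
        "q2_cum": float(pca.q2_cumulative),
    }
    pd.DataFrame(pca.scores, index=table.sample_ids).to_csv(out / "pca_scores.csv")

    # --- VIP intersection cascade on the training matrix ----------------
    cascade_seed = child_seed(config.seed, "cascade")
    report["seeds"]["cascade"] = cascade_seed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X_train, scale_rec = scale_columns(train.values, config.scaling)
    Y_train = DummyY.from_labels(train.labels)
    trace = intersect_cascade(X_train, Y_train, threshold=config.vip_threshold,
                              folds=config.cv_folds, seed=cascade_seed)
    report["selection"] = {
        "stage1": int(trace.stage1_selected.size),
        "stage2_pls": int(trace.stage2_pls.size),
        "stage2_opls": int(trace.stage2_opls.size),
        "characteristic": int(trace.characteristic.size),
        "components": trace.components,
    }
    with open(out / "selection_trace.json", "w") as fh:
        json.dump(trace.to_dict(), fh, indent=2)
    char_names = [train.variable_names[i] for i in trace.characteristic]
    pd.DataFrame({
        "variable": char_names,
        "ppm_low": [train.bucket_edges[i][0] for i in trace.characteristic],
        "ppm_high": [train.bucket_edges[i][1] for i in trace.characteristic],
    }).to_csv(out / "characteristic_variables.csv", index=False)

    # --- stepwise LDA on the characteristic variables -------------------
    X_char_train = train.values[:, trace.characteristic]
    X_char_test = test.values[:, trace.characteristic]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel_local, record = stepwise_select(X_char_train, train.labels,
                                            p_enter=config.p_enter, p_remove=config.p_remove)
    lda_vars = [int(trace.characteristic[j]) for j in sel_local]
    lda_model = fit_lda(X_char_train[:, sel_local], train.labels,
                        selected_variables=lda_vars)
    train_pred = predict_labels(lda_model, X_char_train[:, sel_local])
    test_pred = predict_labels(lda_model, X_char_test[:, sel_local])
    acc_train = float(np.mean([a == b for a, b in zip(train_pred, train.labels)]))
    acc_test = float(np.mean([a == b for a, b in zip(test_pred, test.labels)]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acc_loo, _ = loocv(X_char_train[:, sel_local], train.labels)
    report["lda"] = {
        "selected_variables": [train.variable_names[i] for i in lda_vars],
        "n_selected": len(lda_vars),
        "train_accuracy": acc_train,
        "test_accuracy": acc_test,
        "loocv_accuracy": float(acc_loo),
    }
    scores = canonical_scores(lda_model, np.vstack([X_char_train[:, sel_local],
                                                    X_char_test[:, sel_local]]))
    pd.DataFrame(scores, index=train.sample_ids + test.sample_ids).to_csv(out / "lda_scores.csv")

    # --- verification PLS-DA / OPLS-DA on the stepwise variables --------
    verify_seed = child_seed(config.seed, "verify")
    report["seeds"]["verify"] = verify_seed
    X_sel_all_raw = table.values[:, lda_vars]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X_sel_all, _ = scale_columns(X_sel_all_raw, config.scaling)
    Y_all = DummyY.from_labels(table.labels)
    a_ver = choose_components(X_sel_all, Y_all, max_components=min(config.max_components,
                                                                   len(lda_vars)),
                              folds=config.cv_folds, seed=verify_seed)
    report["verification"] = {}
    for kind in ("pls", "opls"):
        n_orth = 1 if kind == "opls" else 0
        r2y, q2 = cross_validate(X_sel_all, Y_all, n_components=a_ver, folds=config.cv_folds,
                                 seed=verify_seed, model_kind=kind, n_orthogonal=n_orth)
        if kind == "pls":
            m = fit_plsda(X_sel_all, Y_all, n_components=a_ver)
            r2x = m.r2x_cumulative
        else:
            m = fit_oplsda(X_sel_all, Y_all, n_predictive=a_ver, n_orthogonal=1)
            r2x = m.r2x_predictive + m.r2x_orthogonal
        pred_labels, _ = predict_class(m, X_sel_all)
        acc_all = float(np.mean([a == b for a, b in zip(pred_labels, table.labels)]))
        test_mask = np.zeros(table.n_samples, dtype=bool)
        test_mask[part.test_indices] = True
        acc_te = float(np.mean([pred_labels[i] == table.labels[i]
                                for i in range(table.n_samples) if test_mask[i]]))
        perm = permutation_test(X_sel_all, Y_all, n_permutations=config.n_permutations,
                                n_components=a_ver, folds=config.cv_folds, seed=verify_seed,
                                model_kind=kind, n_orthogonal=n_orth)
        report["verification"][kind] = {
            "n_components": int(a_ver),
            "r2x_cum": float(r2x),
            "r2y_cum": float(r2y),
            "q2_cum": float(q2),
            "accuracy_all": acc_all,
            "accuracy_test": acc_te,
            "perm_r2_intercept": perm.r2_intercept,
            "perm_q2_intercept": perm.q2_intercept,
        }

    # --- S-line for the LF vs (c+w)LJF contrast on centered data --------
    binary_labels = ["LF" if lab == "LF" else "LJF" for lab in table.labels]
    if len(set(binary_labels)) == 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            X_ctr, _ = scale_columns(table.values, "center")
            om = fit_oplsda(X_ctr, DummyY.from_labels(binary_labels),
                            n_predictive=1, n_orthogonal=1)
            sl = s_line(om, X_ctr)
        order = np.argsort(-np.abs(sl.covariance))
        pd.DataFrame({
            "variable": table.variable_names,
            "ppm_low": [e[0] for e in table.bucket_edges],
            "ppm_high": [e[1] for e in table.bucket_edges],
            "p_cov": sl.covariance,
            "p_corr": sl.correlation,
        }).to_csv(out / "s_line_LF_vs_LJF.csv", index=False)
        report["s_line_top_variables"] = [table.variable_names[i] for i in order[:5]]

    with open(out / "species_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def run_processing_analysis(config: PipelineConfig) -> dict:
    """Binary processing-method analysis: OPLS-DA + permutation, then
    VIP > 1 -> stepwise LDA, mirroring the species machinery."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "analysis": "processing",
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seeds": {},
    }
    spectra = _load_or_simulate(config, "processing")
    bucket_cfg = BucketConfig(config.bucket_low, config.bucket_high, config.bucket_width)
    table = assemble_table(spectra, bucket_cfg)
    labels = list(table.labels)
    if len(set(labels)) != 2:
        raise ValueError("processing analysis expects exactly two class labels")
    write_bucket_table(table, out / "bucket_table.csv")

    split_seed = child_seed(config.seed, "split")
    report["seeds"]["split"] = split_seed
    counts = dict(config.train_counts) if config.train_counts else (
        _PROCESSING_TRAIN_COUNTS if set(_PROCESSING_TRAIN_COUNTS) == set(labels)
        else _default_train_counts(labels)
    )
    part = split_train_test(table, counts, seed=split_seed)
    train = table.subset_rows(part.train_indices)
    test = table.subset_rows(part.test_indices)
    report["n_train"] = int(train.n_samples)
    report["n_test"] = int(test.n_samples)

    opls_seed = child_seed(config.seed, "opls")
    report["seeds"]["opls"] = opls_seed
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X_train, scale_rec = scale_columns(train.values, config.scaling)
        X_test = apply_scaling(test.values, scale_rec)
    Y_train = DummyY.from_labels(train.labels)
    om = fit_oplsda(X_train, Y_train, n_predictive=1, n_orthogonal=1)
    r2y, q2 = cross_validate(X_train, Y_train, n_components=1, folds=config.cv_folds,
                             seed=opls_seed, model_kind="opls", n_orthogonal=1)
    tr_pred, _ = predict_class(om, X_train)
    te_pred, _ = predict_class(om, X_test)
    acc_tr = float(np.mean([a == b for a, b in zip(tr_pred, train.labels)]))
    acc_te = float(np.mean([a == b for a, b in zip(te_pred, test.labels)]))
    perm = permutation_test(X_train, Y_train, n_permutations=config.n_permutations,
                            n_components=1, folds=config.cv_folds, seed=opls_seed,
                            model_kind="opls", n_orthogonal=1)
    report["opls"] = {
        "r2x_cum": float(om.r2x_predictive + om.r2x_orthogonal),
        "r2y_cum": float(r2y),
        "q2_cum": float(q2),
        "train_accuracy": acc_tr,
        "test_accuracy": acc_te,
        "perm_r2_intercept": perm.r2_intercept,
        "perm_q2_intercept": perm.q2_intercept,
    }

    # VIP > 1 under the OPLS-DA, then stepwise LDA on those buckets
    vip = vip_scores(om.predictive, threshold=config.vip_threshold)
    vip_idx = vip.selected()
    if vip_idx.size == 0:
        raise ValueError("processing stage 'vip' failed: no variable above threshold")
    report["n_vip_selected"] = int(vip_idx.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel_local, _ = stepwise_select(train.values[:, vip_idx], train.labels,
                                       p_enter=config.p_enter, p_remove=config.p_remove)
    lda_vars = [int(vip_idx[j]) for j in sel_local]
    model = fit_lda(train.values[:, lda_vars], train.labels, selected_variables=lda_vars)
    tr_pred = predict_labels(model, train.values[:, lda_vars])
    te_pred = predict_labels(model, test.values[:, lda_vars])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acc_loo, _ = loocv(train.values[:, lda_vars], train.labels)
    report["lda"] = {
        "selected_variables": [table.variable_names[i] for i in lda_vars],
        "train_accuracy": float(np.mean([a == b for a, b in zip(tr_pred, train.labels)])),
        "test_accuracy": float(np.mean([a == b for a, b in zip(te_pred, test.labels)])),
        "loocv_accuracy": float(acc_loo),
    }
    with open(out / "processing_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
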