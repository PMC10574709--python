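"""Spectral bucketing and the normalized bucket matrix.

The modelling matrix is built by integrating each spectrum over fixed-width
chemical-shift windows ("buckets").  With the default range
[-0.025, 9.975] ppm and 0.05 ppm width this yields 200 variables per
sample.  Variables are numbered V1..Vn from the HIGH-ppm end downwards, so
V186 spans [0.675, 0.725] ppm (saponin methyl region) and V200 contains the
TMS reference at 0.0 ppm.  Every row is normalized so its TMS bucket equals
exactly 1.0, removing dilution/receiver-gain scale differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import Spectrum

__all__ = [
    "BucketConfig",
    "BucketTable",
    "Partition",
    "ScalingRecord",
    "bucket_edges",
    "bucket_spectrum",
    "normalize_to_tms",
    "assemble_table",
    "scale_columns",
    "apply_scaling",
    "split_train_test",
]

DEFAULT_RANGE_LOW = -0.025
DEFAULT_RANGE_HIGH = 9.975
DEFAULT_WIDTH = 0.05


@dataclass(frozen=True)
class BucketConfig:
    """Bucketing configuration; defaults give the canonical 200 variables."""

    range_low: float = DEFAULT_RANGE_LOW
    range_high: float = DEFAULT_RANGE_HIGH
    width: float = DEFAULT_WIDTH
    normalize: bool = True
    exclude_windows: tuple[tuple[float, float], ...] = ()


@dataclass
class BucketTable:
    """Samples x buckets matrix of (normalized) integrals.

    ``bucket_edges[i]`` is the (low, high) ppm window of ``variable_names[i]``;
    variables run V1..Vn descending in ppm.
    """

    values: np.ndarray
    bucket_edges: list[tuple[float, float]]
    variable_names: list[str]
    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.bucket_edges) != p or len(self.variable_names) != p:
            raise ValueError("bucket_edges/variable_names must match column count")
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ValueError("sample_ids/labels must match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_buckets(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.variable_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def ppm_window(self, variable: str) -> tuple[float, float]:
        return self.bucket_edges[self.variable_names.index(variable)]

    def subset_rows(self, indices: Sequence[int]) -> "BucketTable":
        idx = np.asarray(indices, dtype=int)
        return BucketTable(
            values=self.values[idx],
            bucket_edges=list(self.bucket_edges),
            variable_names=list(self.variable_names),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=[self.labels[i] for i in idx],
        )


@dataclass
class Partition:
    """Stratified train/test split over the rows of a BucketTable."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    stratum_counts: dict[str, tuple[int, int]]
    seed: int


@dataclass(frozen=True)
class ScalingRecord:
    """Column centering/scaling fitted on training data, reusable on new rows."""

    method: str
    center: np.ndarray
    scale: np.ndarray


def bucket_edges(range_low: float = DEFAULT_RANGE_LOW,
                 range_high: float = DEFAULT_RANGE_HIGH,
                 width: float = DEFAULT_WIDTH) -> list[tuple[float, float]]:
    """Edges in variable order: V1 at the high-ppm end, descending.

    Bucket i (1-based) spans [range_high - i*width, range_high - (i-1)*width].
    """
    span = range_high - range_low
    n = span / width
    n_round = round(n)
    if abs(n - n_round) > 1e-9 * max(1.0, n_round) or n_round < 1:
        raise ValueError(f"width {width} does not tile [{range_low}, {range_high}]")
    return [(range_high - (i + 1) * width, range_high - i * width) for i in range(n_round)]


def _cumulative_integral_at(ppm: np.ndarray, intensity: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Exact integral of the piecewise-linear trace from ppm[0] to each x."""
    # prefix trapezoid integrals at the grid points
    seg = 0.5 * (intensity[1:] + intensity[:-1]) * np.diff(ppm)
    prefix = np.concatenate([[0.0], np.cumsum(seg)])
    k = np.clip(np.searchsorted(ppm, x, side="right") - 1, 0, len(ppm) - 2)
    x0 = ppm[k]
    y0 = intensity[k]
    slope = (intensity[k + 1] - y0) / (ppm[k + 1] - x0)
    dx = x - x0
    yx = y0 + slope * dx
    return prefix[k] + 0.5 * (y0 + yx) * dx


def bucket_spectrum(spectrum: Spectrum,
                    range_low: float = DEFAULT_RANGE_LOW,
                    range_high: float = DEFAULT_RANGE_HIGH,
                    width: float = DEFAULT_WIDTH) -> np.ndarray:
    """Trapezoidal integral of the spectrum over each bucket, in V order.

    The trace is treated as piecewise linear between grid points, so bucket
    integrals are exact for that interpolant and exactly additive across
    adjacent buckets.
    """
    ppm = spectrum.ppm
    intensity = spectrum.intensity
    if ppm[0] > ppm[-1]:  # accept descending grids
        ppm = ppm[::-1]
        intensity = intensity[::-1]
    if ppm[0] > range_low + 1e-12 or ppm[-1] < range_high - 1e-12:
        raise ValueError(
            f"spectrum grid [{ppm[0]:.4g}, {ppm[-1]:.4g}] does not cover "
            f"[{range_low}, {range_high}] ppm"
        )
    edges = bucket_edges(range_low, range_high, width)
    los = np.array([lo for lo, _ in edges])
    his = np.array([hi for _, hi in edges])
    F_lo = _cumulative_integral_at(ppm, intensity, los)
    F_hi = _cumulative_integral_at(ppm, intensity, his)
    return F_hi - F_lo


def _tms_bucket_index(edges: Sequence[tuple[float, float]], anchor: float = 0.0) -> int:
    for i, (lo, hi) in enumerate(edges):
        if lo <= anchor < hi:
            return i
    raise ValueError(f"no bucket contains the reference anchor {anchor} ppm")


def normalize_to_tms(raw: np.ndarray, edges: Sequence[tuple[float, float]],
                     anchor: float = 0.0) -> np.ndarray:
    """Divide a raw bucket vector by its TMS-anchor bucket (the one holding
    0.0 ppm), which becomes exactly 1.0.  Raises if that bucket is <= 0."""
    raw = np.asarray(raw, dtype=float)
    idx = _tms_bucket_index(edges, anchor)
    ref = raw[idx]
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("reference peak missing: TMS bucket integral is not positive")
    out = raw / ref
    out[idx] = 1.0  # exact, not merely up to rounding
    return out


def assemble_table(spectra: Sequence[Spectrum], config: BucketConfig | None = None) -> BucketTable:
    """Bucket (and optionally TMS-normalize) a list of spectra into a table.

    Rows keep the input order; columns are V1..Vn descending in ppm.
    ``exclude_windows`` drops any bucket overlapping a listed ppm window
    (e.g. residual-solvent regions) after normalization.
    """
    if config is None:
        config = BucketConfig()
    if len(spectra) < 2:
        raise ValueError("assemble_table needs at least two spectra")
    edges = bucket_edges(config.range_low, config.range_high, config.width)
    rows = []
    for sp in spectra:
        raw = bucket_spectrum(sp, config.range_low, config.range_high, config.width)
        rows.append(normalize_to_tms(raw, edges) if config.normalize else raw)
    values = np.vstack(rows)
    names = [f"V{i + 1}" for i in range(len(edges))]
    if config.exclude_windows:
        keep = [
            i for i, (lo, hi) in enumerate(edges)
            if not any(lo < w_hi and hi > w_lo for w_lo, w_hi in config.exclude_windows)
        ]
        values = values[:, keep]
        edges = [edges[i] for i in keep]
        names = [names[i] for i in keep]
    return BucketTable(
        values=values,
        bucket_edges=list(edges),
        variable_names=names,
        sample_ids=[sp.sample_id for sp in spectra],
        labels=[sp.label for sp in spectra],
    )


def scale_columns(X: np.ndarray | BucketTable, method: str = "uv") -> tuple[np.ndarray, ScalingRecord]:
    """Column scaling: 'center', 'uv' (unit variance) or 'pareto'.

    Zero-variance columns are centered but left unscaled, with a warning —
    the TMS anchor bucket is constant 1.0 by construction.
    """
    if isinstance(X, BucketTable):
        X = X.values
    X = np.asarray(X, dtype=float)
    if method not in ("center", "uv", "pareto"):
        raise ValueError(f"unknown scaling method {method!r}")
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    zero = sd <= 1e-300
    if method == "center":
        scale = np.ones_like(sd)
    else:
        scale = np.where(zero, 1.0, sd if method == "uv" else np.sqrt(np.where(zero, 1.0, sd)))
        if np.any(zero):
            warnings.warn(
                f"{int(zero.sum())} zero-variance column(s) passed through centered only",
                stacklevel=2,
            )
    record = ScalingRecord(method=method, center=center, scale=scale)
    return (X - center) / scale, record


def apply_scaling(X: np.ndarray, record: ScalingRecord) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != record.center.shape[0]:
        raise ValueError("column count does not match the scaling record")
    return (X - record.center) / record.scale


def split_train_test(table: BucketTable, stratum_counts: Mapping[str, int], seed: int,
                     allow_empty_test: bool = False) -> Partition:
    """Stratified random split drawing the requested per-label training counts.

    Deterministic given ``seed``.  An empty test set is refused unless
    ``allow_empty_test`` is set.
    """
    labels = np.asarray(table.labels)
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    strata: dict[str, tuple[int, int]] = {}
    requested = dict(stratum_counts)
    present = list(dict.fromkeys(table.labels))
    unknown = set(requested) - set(present)
    if unknown:
        raise ValueError(f"stratum labels not present in table: {sorted(unknown)}")
    for lab in present:
        idx = np.flatnonzero(labels == lab)
        k = int(requested.get(lab, 0))
        if k > len(idx):
            raise ValueError(f"class {lab!r}: requested {k} training samples, have {len(idx)}")
        perm = rng.permutation(idx)
        train.extend(perm[:k].tolist())
        test.extend(perm[k:].tolist())
        strata[lab] = (k, len(idx) - k)
    if not test and not allow_empty_test:
        raise ValueError("split leaves an empty test set (pass allow_empty_test=True to permit)")
    return Partition(
        train_indices=np.asarray(sorted(train), dtype=int),
        test_indices=np.asarray(sorted(test), dtype=int),
        stratum_counts=strata,
        seed=int(seed),
    )
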