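"""Synthetic 1H-NMR cohort generator.

Produces cohorts of one-dimensional proton spectra whose class structure
mimics an authentication study of Lonicerae japonicae flos (LJF, cultivated
``cLJF`` / wild ``wLJF``) versus its adulterant Lonicerae flos (``LF``):

* triterpenoid saponins (macranthoidin A/B, dipsacoside B) resonate in the
  methyl region 0.65-1.80 ppm and are abundant in LF, intermediate in wLJF
  and near-trace in cLJF;
* secoiridoids (secoxyloganin, secologanoside) resonate around
  2.65-2.95, 4.60-4.70 and 5.20-5.30 ppm and are elevated in wLJF;
* sweroside contributes a signal at 5.50-5.55 ppm;
* every spectrum carries a TMS reference peak at 0.0 ppm used downstream
  for normalisation.

Peaks are Lorentzian (Cauchy) lines, the natural NMR line shape; compound
abundances are drawn log-normally so they are positive and right-skewed.
All randomness flows from a single cohort seed; the stream for one spectrum
is derived deterministically from ``(seed, label, sample_index)``.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "CompoundSignature",
    "CohortDesign",
    "Spectrum",
    "default_compound_library",
    "default_species_design",
    "default_processing_design",
    "null_design",
    "simulate_spectrum",
    "simulate_cohort",
    "planted_marker_buckets",
    "write_cohort",
    "PPM_MIN",
    "PPM_MAX",
    "N_GRID",
]

# Simulation grid: evenly spaced, slightly wider than the 200-bucket
# integration range [-0.025, 9.975] so edge buckets never touch grid ends.
PPM_MIN = -0.525
PPM_MAX = 10.475
N_GRID = 16384


@dataclass(frozen=True)
class CompoundSignature:
    """One compound's line list: ``(center ppm, half-width ppm, height)``."""

    name: str
    peaks: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"{self.name}: a signature needs at least one peak")
        for c, w, h in self.peaks:
            if not (-0.025 <= c <= 9.975):
                raise ValueError(f"{self.name}: peak center {c} outside [-0.025, 9.975] ppm")
            if w <= 0:
                raise ValueError(f"{self.name}: non-positive width {w}")
            if h < 0:
                raise ValueError(f"{self.name}: negative height {h}")


@dataclass(frozen=True)
class Spectrum:
    """A processed 1D spectrum: strictly monotone ppm grid plus intensities."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str
    label: str

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if ppm.shape != intensity.shape or ppm.ndim != 1:
            raise ValueError("ppm and intensity must be equal-length 1-D arrays")
        d = np.diff(ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm grid must be strictly monotone")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", intensity)


@dataclass(frozen=True)
class CohortDesign:
    """Cohort recipe: class sizes, per-(class, compound) mean abundances,
    abundance coefficient of variation, baseline, noise and TMS height.

    ``concentration_means`` maps class label -> {compound name -> mean};
    a missing entry means the compound is absent from that class.
    """

    class_sizes: Mapping[str, int]
    concentration_means: Mapping[str, Mapping[str, float]]
    concentration_cv: float = 0.2
    baseline_level: float = 0.01
    noise_sd: float = 0.005
    tms_height: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_sizes:
            raise ValueError("class_sizes must name at least one class")
        for lab, n in self.class_sizes.items():
            if n < 1:
                raise ValueError(f"class {lab!r}: count must be >= 1")
        for lab, comps in self.concentration_means.items():
            for name, m in comps.items():
                if m < 0:
                    raise ValueError(f"negative mean for ({lab}, {name})")
        if self.concentration_cv < 0:
            raise ValueError("concentration_cv must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tms_height <= 0:
            raise ValueError("tms_height must be > 0")

    def to_dict(self) -> dict:
        return {
            "class_sizes": dict(self.class_sizes),
            "concentration_means": {k: dict(v) for k, v in self.concentration_means.items()},
            "concentration_cv": self.concentration_cv,
            "baseline_level": self.baseline_level,
            "noise_sd": self.noise_sd,
            "tms_height": self.tms_height,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortDesign":
        return cls(
            class_sizes={str(k): int(v) for k, v in d["class_sizes"].items()},
            concentration_means={
                str(k): {str(c): float(m) for c, m in v.items()}
                for k, v in d["concentration_means"].items()
            },
            concentration_cv=float(d.get("concentration_cv", 0.2)),
            baseline_level=float(d.get("baseline_level", 0.01)),
            noise_sd=float(d.get("noise_sd", 0.005)),
            tms_height=float(d.get("tms_height", 5.0)),
            seed=int(d.get("seed", 0)),
        )


def default_compound_library() -> list[CompoundSignature]:
    """The six marker compounds of the authentication problem.

    The saponins place their methyl/methylene signals inside 0.65-1.80 ppm;
    the secoiridoids cover 2.65-2.95, 4.60-4.70 and 5.20-5.30 ppm; sweroside
    contributes its olefinic signal at 5.50-5.55 ppm.  Exact centers, widths
    and relative heights within those windows are package constants (the
    windows, not the line lists, are what the markers are identified by).
    """
    w = 0.004  # half-width at half-maximum, ~2 Hz at 500 MHz
    return [
        CompoundSignature(
            "macranthoidin A",
            ((0.85, w, 1.00), (1.10, w, 0.80), (1.35, w, 0.60)),
        ),
        CompoundSignature(
            "macranthoidin B",
            ((0.95, w, 1.00), (1.25, w, 0.70), (1.70, w, 0.50)),
        ),
        CompoundSignature(
            "dipsacoside B",
            ((0.80, w, 0.90), (1.05, w, 0.90), (1.55, w, 0.50)),
        ),
        # the two secoiridoids resonate in the same three windows; their
        # lines are close enough to share buckets at 0.05 ppm resolution
        CompoundSignature(
            "secoxyloganin",
            ((2.72, w, 0.90), (4.63, w, 0.70), (5.23, w, 0.80)),
        ),
        CompoundSignature(
            "secologanoside",
            ((2.73, w, 0.90), (4.64, w, 0.70), (5.24, w, 0.80)),
        ),
        CompoundSignature(
            "sweroside",
            ((5.52, w, 0.90),),
        ),
    ]


_SAPONINS = ("macranthoidin A", "macranthoidin B", "dipsacoside B")
_SECOIRIDOIDS = ("secoxyloganin", "secologanoside")


def default_species_design(seed: int = 0) -> CohortDesign:
    """Three-class 77/10/13 cohort (cLJF/wLJF/LF).

    Saponins: trace in cLJF, intermediate in wLJF, high in LF.
    Secoiridoids: elevated in wLJF; sweroside mildly elevated in wLJF.
    """
    means = {
        "cLJF": {**{s: 0.05 for s in _SAPONINS}, **{s: 0.3 for s in _SECOIRIDOIDS}, "sweroside": 0.3},
        "wLJF": {**{s: 0.50 for s in _SAPONINS}, **{s: 1.0 for s in _SECOIRIDOIDS}, "sweroside": 0.8},
        "LF": {**{s: 1.00 for s in _SAPONINS}, **{s: 0.3 for s in _SECOIRIDOIDS}, "sweroside": 0.4},
    }
    return CohortDesign(
        class_sizes={"cLJF": 77, "wLJF": 10, "LF": 13},
        concentration_means=means,
        seed=seed,
    )


def default_processing_design(seed: int = 0) -> CohortDesign:
    """Binary hot-air vs sun drying cohort of cultivated LJF (39/38).

    Drying mode shifts the heat-labile secoiridoids only modestly, and
    batch-to-batch abundance variation is wider than in the species design,
    so the two classes overlap substantially — a deliberately weak-signal
    regime in which supervised models fit well but predict poorly.
    """
    base = {**{s: 0.05 for s in _SAPONINS}}
    means = {
        "hot_air": {**base, "secoxyloganin": 0.26, "secologanoside": 0.26, "sweroside": 0.26},
        "sun": {**base, "secoxyloganin": 0.38, "secologanoside": 0.38, "sweroside": 0.38},
    }
    return CohortDesign(
        class_sizes={"hot_air": 39, "sun": 38},
        concentration_means=means,
        concentration_cv=0.30,
        seed=seed,
    )


def null_design(class_sizes: Mapping[str, int] | None = None, seed: int = 0) -> CohortDesign:
    """All classes share one concentration profile: no real class signal."""
    sizes = dict(class_sizes) if class_sizes else {"A": 20, "B": 20, "C": 20}
    profile = {**{s: 0.4 for s in _SAPONINS}, **{s: 0.4 for s in _SECOIRIDOIDS}, "sweroside": 0.4}
    return CohortDesign(
        class_sizes=sizes,
        concentration_means={lab: dict(profile) for lab in sizes},
        seed=seed,
    )


def _grid() -> np.ndarray:
    return np.linspace(PPM_MIN, PPM_MAX, N_GRID)


def _lorentzian(ppm: np.ndarray, center: float, width: float, height: float) -> np.ndarray:
    # height is the amplitude at the line center; width is the half-width
    # at half-maximum, so the line integrates to pi * height * width.
    return height * width**2 / ((ppm - center) ** 2 + width**2)


def _spectrum_rng(design: CohortDesign, label: str, sample_index: int) -> np.random.Generator:
    # independent, reproducible stream per (cohort seed, label, index)
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(design.seed), key, int(sample_index)]))


def _draw_concentration(rng: np.random.Generator, mean: float, cv: float) -> float:
    if mean == 0.0:
        return 0.0
    if cv == 0.0:
        return mean
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mean=mu, sigma=np.sqrt(sigma2)))


def simulate_spectrum(
    design: CohortDesign,
    label: str,
    sample_index: int,
    library: Sequence[CompoundSignature] | None = None,
) -> Spectrum:
    """Simulate one spectrum of class ``label``.

    intensity = baseline + sum over compounds of abundance x Lorentzian lines
    + TMS line at 0.0 ppm + iid Gaussian noise.
    """
    if label not in design.class_sizes:
        raise KeyError(f"unknown class label {label!r}")
    library = list(library) if library is not None else default_compound_library()
    rng = _spectrum_rng(design, label, sample_index)
    ppm = _grid()
    intensity = np.full_like(ppm, design.baseline_level)
    class_means = design.concentration_means.get(label, {})
    # concentrations drawn in fixed library order to keep the stream stable
    for compound in library:
        conc = _draw_concentration(rng, float(class_means.get(compound.name, 0.0)), design.concentration_cv)
        if conc == 0.0:
            continue
        for center, width, height in compound.peaks:
            intensity += conc * _lorentzian(ppm, center, width, height)
    intensity += _lorentzian(ppm, 0.0, 0.004, design.tms_height)
    if design.noise_sd > 0:
        intensity += rng.normal(0.0, design.noise_sd, size=ppm.shape)
    return Spectrum(ppm=ppm, intensity=intensity, sample_id=f"{label}-{sample_index:03d}", label=label)


def simulate_cohort(
    design: CohortDesign,
    library: Sequence[CompoundSignature] | None = None,
) -> list[Spectrum]:
    """Simulate the whole cohort, ordered stably by (label, index)."""
    out: list[Spectrum] = []
    for label in design.class_sizes:  # dict order is insertion order: stable
        for i in range(design.class_sizes[label]):
            out.append(simulate_spectrum(design, label, i, library=library))
    return out


def planted_marker_buckets(
    design: CohortDesign,
    bucket_edges: Sequence[tuple[float, float]],
    library: Sequence[CompoundSignature] | None = None,
    min_gap: float = 1e-9,
) -> list[int]:
    """0-based bucket indices holding a peak of any compound whose mean
    abundance differs between classes — the planted discriminative buckets.
    """
    library = list(library) if library is not None else default_compound_library()
    discriminative = set()
    for compound in library:
        means = [float(design.concentration_means.get(lab, {}).get(compound.name, 0.0))
                 for lab in design.class_sizes]
        if max(means) - min(means) > min_gap:
            discriminative.add(compound.name)
    hits: set[int] = set()
    for compound in library:
        if compound.name not in discriminative:
            continue
        for center, _, _ in compound.peaks:
            for j, (lo, hi) in enumerate(bucket_edges):
                if lo <= center < hi:
                    hits.add(j)
                    break
    return sorted(hits)


def write_cohort(spectra: Iterable[Spectrum], design: CohortDesign, outdir: str | Path) -> None:
    """Write per-sample two-column CSVs, a labels CSV and the design JSON."""
    from .io import write_spectrum_csv  # local import: io depends on types here

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sp in spectra:
        write_spectrum_csv(sp, outdir / f"{sp.sample_id}.csv")
        rows.append((sp.sample_id, sp.label))
    with open(outdir / "labels.csv", "w") as fh:
        fh.write("sample_id,label\n")
        for sid, lab in rows:
            fh.write(f"{sid},{lab}\n")
    with open(outdir / "design.json", "w") as fh:
        json.dump(design.to_dict(), fh, indent=2)
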