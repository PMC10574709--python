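# Methods

This note documents the models implemented in `nmrpattern`, the choices
made where the design was genuinely open, and what the synthetic cohorts
do and do not show about real spectra.

## Spectral preprocessing

A processed 1D ¹H spectrum is a piecewise-linear trace on a strictly
monotone ppm grid. Bucketing integrates the trace over fixed-width windows
with the trapezoid rule, which is exact for the piecewise-linear
interpolant and makes bucket integrals exactly additive. The default
configuration — δ −0.025 to 9.975 ppm in 0.05 ppm steps — yields 200
variables. Variables are numbered from the **high**-ppm end down (V1 =
[9.925, 9.975]): under this convention V186 spans [0.675, 0.725] ppm and
V184 [0.775, 0.825] ppm (saponin methyl region) while V147/V145 span
[2.625, 2.675]/[2.725, 2.775] ppm (secoiridoid region), which is the only
ordering consistent with the published 7-variable discriminant model the
package ships.

Each row is divided by its TMS-anchor bucket (the one containing 0.0 ppm),
which becomes exactly 1.0. The anchor is the *bucket integral*, not the
point maximum; the two differ only by a constant factor for a fixed line
shape, and the integral is robust to grid density (the choice is
switchable via the `anchor` argument if a different convention is
needed). Normalization removes global intensity scale (dilution, receiver
gain); it does **not** make spectra invariant to a change of the actual
TMS concentration, which rescales all other variables — exactly as in real
practice, where the reference concentration is fixed by the solvent batch.

No solvent-region exclusion is applied by default; `BucketConfig.exclude_windows`
can drop residual-solvent bands (e.g. CD₃OD ~3.3 ppm, HDO ~4.9 ppm) when
working with real spectra.

Column scaling: mean-centering plus unit-variance scaling ("uv") is the
default for all latent-variable models, the convention of the usual
chemometrics software; "center" and "pareto" are available. Zero-variance
columns (the TMS anchor is constant by construction) pass through centered
with a warning.

## Latent-variable models

**PCA** uses NIPALS with deterministic initialization (the column of
largest variance), convergence tolerance 1e-10, 500 iterations max, and a
sign convention that makes each loading's largest-magnitude entry
positive. Q² comes from Wold element-wise cross-validation: matrix entries
are deleted in 7 diagonal stripes, each component refitted on the
incomplete matrix (NIPALS with missing-value masking), deleted entries
predicted, and Q²(cum) = 1 − Π PRESSₐ/SSₐ. The optional stop rule retains
components while their per-component Q² exceeds a threshold (0.0 in the
pipeline). Commercial implementations use a proprietary deletion pattern;
equivalence is by convention, not bit-compatibility.

**PLS-DA** is NIPALS PLS2 on one-hot class indicators with X- and
Y-deflation per component, weight iteration started from the Y column of
largest variance (deterministic). R²Y accumulates the Y sum of squares
explained per component; the regression coefficients are
B = W(PᵀW)⁻¹Cᵀ.

**VIP** follows the standard formula; Σⱼ VIPⱼ² = p is checked to 1e-6 in
the tests. Screening uses strict inequality VIP > 1.

**OPLS-DA**: for a single response this is the Trygg–Wold algorithm. For
multi-class Y the orthogonal filter projects each candidate loading off
the orthonormalized span of XᵀY (the dummy-Y weight space) — a
block generalization the original papers leave open; the predictive part
is then a PLS2 fit on the filtered matrix with (classes − 1) components by
default. With zero orthogonal components the model reduces exactly to
PLS-DA. Predictive and orthogonal scores are mutually orthogonal by
construction (asserted to 1e-7 in tests).

**S-line**: p(cov)ⱼ = cov(t_p, xⱼ), p(corr)ⱼ = corr(t_p, xⱼ) for two-class
models. The pipeline computes it on centered (not variance-scaled) data:
on unit-variance columns the covariance degenerates to a correlation and
the magnitude axis that makes the S-plot useful disappears.

**Cross-validation**: stratified 7-fold by class (the conventional default;
configurable), each fold recentering X and Y by its training means;
Q² = 1 − PRESS/SSY with SSY pooled over dummy columns. A fold that would
swallow an entire class is reassigned with a warning.

**Permutation testing**: rows of Y are shuffled, the model is refitted at
fixed size, and (corr(Y_perm, Y), R²Y, Q²) recorded; 200 rounds by
default. Intercepts are taken from least-squares lines of R²Y and Q²
against the correlation *including* the unpermuted reference point,
matching the usual validate-plot convention. The unpermuted entry reuses
the cross-validation stream verbatim, so it equals `cross_validate`
exactly.

## Variable cascade and stepwise LDA

The cascade refits models per stage; the component count per stage is
chosen by a cross-validated stop rule (add a component while cumulative Q²
improves by > 0.01, capped at 6) because no fixed per-stage count is
canonical. Intersections are computed on original variable identities, so
reduction cannot cause index drift. Any stage that selects nothing raises
with the stage name.

Stepwise LDA minimizes Wilks' Λ (determinant ratio of within- to
total-scatter, computed from covariance-based scatter matrices) greedily,
gated by probability-of-F thresholds p_enter = 0.05 and p_remove = 0.10 —
the defaults of the mainstream statistics package for this procedure.
Whether that package internally uses pooled correlation rather than
covariance is undocumented; covariance is used here, and selection order
may differ from its output in marginal cases. Priors are equal by default
(configurable to proportional or explicit). A singular pooled covariance
is ridged once by max(1e-8·trace/p, 1e-12) on the diagonal with a warning;
LOOCV refits tolerate transiently depleted classes.

Classification functions follow Fisher: gₖ(x) = μₖᵀΣ⁻¹x − ½μₖᵀΣ⁻¹μₖ +
log πₖ; argmax over k is equivalent to the shared-covariance Gaussian
Bayes rule (asserted against a Mahalanobis oracle). Canonical axes solve
the between/within generalized eigenproblem. Published coefficient tables
import through `model_from_functions`, giving a model that classifies but
has no covariance or canonical axes.

## Synthetic cohorts

The generator emulates processed (phased, baseline-corrected,
TMS-referenced) spectra on a 16,384-point grid over [−0.525, 10.475] ppm —
wide enough that bucket edges never meet grid ends. Each compound is a
fixed list of Lorentzian lines (center, half-width, height); a sample's
abundance for a compound scales all its lines jointly and is drawn
log-normally with the design's mean and CV (positive, right-skewed, as
natural abundances are). Per-spectrum streams derive from
(cohort seed, class label, sample index), so single spectra are
reproducible in isolation and no global RNG state is touched.

Default constants, chosen once for realism and fixed:

* line half-width 0.004 ppm (≈ 2 Hz at 500 MHz); TMS line height 5.0;
  baseline 0.01; Gaussian noise SD 0.005 per grid point; concentration
  CV 0.2.
* species design (77 cLJF / 10 wLJF / 13 LF): saponin means
  0.05/0.5/1.0 (trace / intermediate / high), secoiridoid means
  0.3/1.0/0.3, sweroside 0.3/0.8/0.4 — the qualitative ordering reported
  for these markers. The two secoiridoids resonate in the same three
  windows and their lines share buckets at 0.05 ppm resolution.
* processing design (39 hot-air / 38 sun, cultivated material only):
  secoiridoid/sweroside means 0.26 vs 0.38 with CV 0.30 — a deliberately
  weak, high-variance contrast that produces models with high R²Y but
  much lower Q² ("good fitness, poor predictive ability"), the regime in
  which the binary analysis is interesting.

What the generator does **not** emulate: J-coupling multiplets, peak-shift
variation between samples, baseline drift and phase error, residual
solvent signals, or inter-compound correlations beyond the planted class
structure. Passing tests therefore demonstrate the correctness and the
qualitative behaviour of the algorithms under a known ground truth — not
that any particular accuracy will be attained on real spectra, where the
headline numbers depend on the cohort itself.

## Numerical notes and degenerate inputs

* NIPALS tolerances: 1e-10 relative score change, 500 iterations.
* Prediction ties in classifiers resolve to the lowest class index, with a
  warning.
* Single-class Y, infeasible splits, insufficient grid coverage, a missing
  or non-positive TMS bucket, and length mismatches all raise `ValueError`
  with specific messages.
* The pipeline fans its single seed out per stage by hashing the stage
  name (SHA-256, reduced below 2³¹), so toggling one stage never shifts
  another stage's stream; every derived seed is recorded in the report.

## Problem sizes

The shipped analyses run the full 100-sample, 200-variable cohorts; the
verification step fits on the 5–7 stepwise-selected variables as the
published workflow does; permutation testing uses 200 rounds in the
pipeline and acceptance script (50 in the quicker test-suite checks), and
planted-marker recovery is averaged over 20 cohort seeds.
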