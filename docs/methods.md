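# Methods

`placomp` implements a complete analysis chain for studying how
gestational exposures relate to placental cell-type composition inferred
from bulk DNA methylation. This note documents the statistical models,
the numerical choices behind them, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Cell-type deconvolution

Bulk placental methylation is modelled as a convex mixture of cell-type
signatures: for a sample with beta-value vector *b* over the panel's
marker CpGs and reference matrix *R* (CpGs × K cell types), the mixing
weights solve

    minimize ||b − R w||²   subject to  w ≥ 0,  Σ w ≤ 1,

the constrained-projection formulation standard for reference-based
methylation deconvolution, followed by renormalization of *w* to unit
sum. Because K is small (six placental cell types:
syncytiotrophoblasts, trophoblasts, stromal, endothelial, Hofbauer
cells, nucleated red blood cells), the quadratic program is solved
*exactly* by enumerating all active sets — each weight clamped at zero
or free, the sum constraint tight or slack — and keeping the feasible
equality-constrained least-squares candidate with the lowest objective.
The global optimum of a convex QP is the solution of its own active
set's equality problem, so it is always among the 2^(K+1) candidates.
This removes iterative-solver tolerances entirely; solutions are exact
to floating-point rounding. Enumeration is capped at K = 14 (16 384
candidate solves per sample), far above any methylation reference in
use.

CpGs are matched between bulk and panel by identifier, order
insensitively, with the dropped-CpG count logged. The minimum overlap
defaults to K at the function level; the pipeline requires 100 shared
CpGs for file-based runs, where panels are large and a tiny overlap
signals an input problem.

### Rounded zeros

Estimated proportions can be exactly zero (the cell type is below the
method's detection limit). Log-ratio analysis requires strictly
positive parts, so zeros are imputed by **multiplicative simple
replacement**: each zero becomes δ (default 1e-3, configurable) and the
nonzero parts of that row are rescaled by (1 − zδ), z the row's zero
count. This preserves the unit sum exactly and leaves all ratios among
originally nonzero parts untouched — the geometric requirements that
motivate zero replacement in compositional analysis. More elaborate
imputation schemes exist (e.g. PLS-based regression imputation); the
multiplicative rule was chosen deliberately as the simplest method
satisfying the geometry, and δ plays the role of a detection limit.
Note that a *measured* proportion smaller than δ is not raised to δ;
only true zeros are.

## Compositional regression

The K proportions are one multivariate outcome on the simplex. They are
mapped to K−1 Euclidean coordinates by the isometric log-ratio (ilr)
transform, using the pivot (sequential-binary-partition) basis in the
stored cell-type order: coordinate j contrasts part j against the
geometric mean of the later parts, with orthonormal scaling

    z_j = sqrt((K−j)/(K−j+1)) · ln( x_j / gmean(x_{j+1..K}) ).

Each coordinate is regressed by ordinary least squares on a shared
design: intercept, the three trimester-average PM2.5 exposures
(IQR-standardized), infant sex (overall model only), maternal age,
gestational age, race/ethnicity (reference White) and season of birth
(reference Winter). The basis choice is internal: every reported
quantity below is invariant to the pivot order (verified by a dedicated
test), though the raw coefficient matrix is not.

**Reported effects.** For trimester *t* with ilr-scale coefficient row
β_t, the per-IQR change in composition is

    Δ_t = ilr⁻¹(η_ref + β_t) − ilr⁻¹(η_ref),

where η_ref is the fitted linear predictor at a reference profile:
continuous covariates at their sample mean, categorical covariates at
their modal level, exposures at 0 (the median after IQR
standardization). Δ_t has components summing to zero — a composition
cannot gain one cell type without losing others.

**Overall test.** Whether trimester *t* moves the composition at all is
tested with Wilks' Λ on the full coefficient row across all K−1
coordinates, converted to an F statistic via Rao's approximation, which
is exact for a single-row hypothesis: F = ((ve−m+1)/m)(1−Λ)/Λ with
m = K−1 response coordinates and ve the residual degrees of freedom.

**Bootstrap inference.** Uncertainty comes from nonparametric case
resampling: whole records (composition, exposures, covariates) are
redrawn with replacement B times (default 1000), the model refit, and
each trimester's Δ and F recorded. Per-cell-type confidence intervals
are percentile intervals of the Δ draws. Case resampling (rather than
residual resampling) is robust to heteroscedasticity and is standard
for observational data; percentile (rather than BCa) intervals are the
plainest reading of "bootstrapped confidence intervals". Replicates
with rank-deficient designs (a rare covariate level absent from the
redraw) are redrawn, with a logged counter capped at 10% of B at the
function level; the pipeline relaxes the cap to 50% for sex-stratified
subsamples of ~100 records, where such redraws are routine rather than
pathological.

**Median-F p-value.** The overall per-trimester p-value is derived from
the median of the bootstrap F statistics, corrected for resampling
inflation. Raw case-resampled F statistics test "coefficient row = 0"
while their coefficients fluctuate around the *observed* estimate, so
they follow approximately a noncentral F(df1, df2, λ) with
λ ≈ df1·F_obs; referring their median directly to the central F
over-rejects badly under the null (empirically ~20–27% at α = 0.05).
The package therefore inverts the relationship: it finds the
noncentrality λ̂ whose median matches the observed bootstrap median and
refers λ̂/df1 to the central F(df1, df2). If the bootstrap median falls
below the central median the p-value is 1. This "bootstrap-corrected"
median-F test is calibrated (measured null rejection 4–9% at α = 0.05
across trimesters) while retaining the median's robustness to outlying
replicates and strong power against injected effects.

## Beta regression

As a secondary, per-cell-type analysis, each proportion is modelled as
Beta-distributed with mean μ_i = logistic(x_iᵀβ) and shape parameters
(μ_iφ, (1−μ_i)φ), φ a constant precision (log-parameterized
internally). Estimation is maximum likelihood: Newton ascent with
analytic score and observed-information Hessian, a backtracking line
search that only accepts likelihood-increasing steps, and pure Newton
steps once the gradient max-norm drops below 1e-2 — in that regime the
per-step likelihood gain falls below the floating-point noise of the
summed log-likelihood, and a noise-driven line search would stall.
Starting values are a linear fit on logit(y) plus a method-of-moments
precision. Convergence requires score max-norm < 1e-6; non-convergence
raises rather than returning a silently bad fit.

Default inference is Wald, from the observed information at the
optimum, with coefficients reported on the log-odds scale; a
case-resampling percentile bootstrap is available
(`bootstrap_beta_regression`) for interval-type sensitivity checks.
Boundary values of y raise an error naming the samples (deconvolved,
zero-replaced proportions are always interior); an optional squeeze
transform (y(n−1)+0.5)/n is available for external data.

## Pipeline conventions

- **IQR standardization** (x − median)/IQR, quartiles by linear
  interpolation, is computed per trimester on the *full analytic
  sample before stratification*, so "one IQR" has the same physical
  meaning in every stratum.
- **Strata**: an overall model (with a sex term) and separate female
  and male models (without one).
- **Sensitivity analysis** repeats everything excluding participants
  with preeclampsia or eclampsia.
- **Missing data**: complete-case on the modelled covariates and
  exposures, with logged drop counts.
- Every run writes a JSON log with the seed, config hash, per-stratum
  sample sizes, exclusion counts and bootstrap redraw counts; identical
  config and seed reproduce output files byte for byte.

## Synthetic-data generator

The generator emulates the statistical structure of a ~226-pair urban
Northeastern-US pregnancy cohort so that every stage has seeded inputs
with known truth:

- **Reference panel**: per-cell-type marker blocks, hypermethylated
  (0.5 + contrast/2) in their own type and hypomethylated elsewhere,
  with seeded Gaussian jitter (sd 0.02), clipped to [0,1]. Default 100
  markers per type, contrast 0.6.
- **Compositions**: sex-specific baselines set to the cohort's mean
  proportions (syncytiotrophoblast 0.623 female / 0.644 male, etc.),
  perturbed in ilr space by iid Gaussian noise, sd 0.25 per coordinate.
  That value was chosen so the marginal cell-type SDs match observed
  spreads (syncytiotrophoblast SD ≈ 0.065 against 0.069 observed) while
  keeping the mean within 0.01 of baseline.
- **Effects** are injected additively in ilr coordinates against
  IQR-standardized exposures (optionally restricted to one sex), so the
  compositional regression has an exactly recoverable truth on its own
  parameter scale.
- **Exposures**: trimester means (8.25, 8.24, 8.56) µg/m³, SDs
  (1.36, 1.34, 1.77), multivariate normal with cross-trimester
  correlation 0.4 (a plausible stand-in; within-pregnancy correlation
  is rarely reported), truncated positive by resampling.
- **Covariates**: sex (44.7% female), maternal age N(30.6, 5.6²)
  truncated at 18, gestational age N(39.0, 1.5²) clipped to (25, 43),
  race/ethnicity and season at the cohort's observed frequencies,
  complication flags at observed prevalences.
- **Bulk mixtures**: B = W·Rᵀ plus iid Gaussian beta-value noise
  (default sd 0.02), clipped to [0,1].

What the generator does *not* emulate: probe-level chemistry, batch and
dye effects, SNP-affected probes, spatial sampling variability within a
placenta, cell-type-specific methylation shifts caused by the exposure
itself, or Beta-distributed (heteroscedastic) measurement noise.
Passing tests therefore demonstrate correctness of the statistical
machinery under a clean mixture model, not robustness to array-level
artifacts, which are assumed to be handled upstream.

## Problem sizes in the test suite

The default suite and the acceptance script scale simulation studies to
desk sizes chosen by the package: bootstrap calibration uses 100–200
datasets of n = 300 with B = 200; CI coverage 60–100 datasets of
n = 500 with B = 200; beta-regression recovery 60–100 replicates of
n = 2000; the end-to-end sex-specificity study 10–20 cohorts of
n = 226 with B = 200. The exhaustive grid-search oracle for the
deconvolution QP runs at step 1e-3 for K ∈ {2, 3}.

## Known limitations

- The overall test assumes the multivariate linear model's residuals
  are well-behaved enough for Wilks' Λ; heavy-tailed ilr residuals are
  partially covered by the bootstrap but the median-F correction relies
  on the noncentral-F approximation of resampled statistics.
- No multiple-testing adjustment is applied across trimesters, strata
  or cell types, by design (the analysis is exploratory).
- Constant precision in the beta regression; no zero/one-inflated or
  variable-dispersion variants.
- The deconvolution assumes the reference panel's cell types span the
  tissue; unmodelled cell types bias all proportions.
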