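# Methods

## Model

For a gene set with genes *j = 1…J* measured in samples *i = 1…n* at doses
`D_i`, expression on the modeling scale is

    Y_ij = β0 + b_0j + f_j(D_i) + ε_ij,     ε_ij ~ N(0, σ²/w_ij)

with a gene-specific random intercept `b_0j` and, depending on the
candidate, a dose-response function `f_j` that is absent (null), linear
with gene-specific random slope, or a cubic B-spline whose coefficients
carry gene-specific random deviations. Random effects are modeled with a
**diagonal covariance** (independent coordinates), parameterized relative
to the residual variance; a full covariance is statistically richer but
unstable at the 10–20 genes per set this method typically sees, and the
diagonal family still absorbs gene-level heterogeneity in every
coordinate. The four candidates are:

| kind              | fixed effects        | random effects (per gene) |
|-------------------|----------------------|---------------------------|
| `null`            | intercept            | intercept                 |
| `linear_mixed`    | intercept + slope    | intercept + slope         |
| `nonlinear_fixed` | intercept + spline   | intercept                 |
| `nonlinear_mixed` | intercept + spline   | intercept + spline        |

Precision weights `w_ij` are present only for count data (below); they
rescale the residual variance per observation, exactly as observation
weights do in standard mixed-model software.

## Fitting

All candidates are fitted by **maximum likelihood, not REML**, so AIC and
likelihood-ratio comparisons across different fixed-effect structures are
valid. The fixed effects and σ² are profiled out analytically (GLS step and
a closed-form variance), leaving an optimization over the q relative
random-effect standard deviations on the log scale, solved with L-BFGS-B
using an analytic gradient (envelope theorem for the profiled parameters).
Per-gene covariance blocks share the sample design, so all gene blocks are
factorized in one batched Cholesky per likelihood evaluation.

Numerical choices: log-SDs bounded in [-10, 8] (the upper bound must be
generous or near-noiseless data cannot reach the interpolation regime);
σ² floored at 1e-12; two fixed starting points (relative SD 0.5 and 0.05),
keeping the better optimum — warm-started refits (bootstrap) use a single
start at the full-data estimate; convergence by L-BFGS-B's default
criteria with ftol 1e-10, flagged on the candidate. Fixed-effect systems
are solved with a pseudo-inverse (rcond 1e-10) because the spline design is
deliberately richer than the dose design (next section). Empirical-Bayes
random effects are the conditional means given the fitted variances.

Parameter counts for AIC (`AIC = 2k − 2ℓ`) use the rank of the
fixed-effect design plus the number of random-effect variances plus one
for σ². The LRT against the null refers `Λ = max(0, 2Δℓ)` to a χ² with
df = difference in those counts. This is an approximation on two grounds:
variance components sit on the boundary under the null, and the spline
fixed effects are rank-deficient; both push the test toward conservatism.
The simulation suite checks the realized type-I error of the full
selection procedure on flat pathways and finds it within [0.02, 0.10] at
α = 0.05, which we consider calibrated for a screening tool.

## Spline basis and the identifiability of the curve

The basis is a degree-3 B-spline with interior knots at the unique
(transformed) dose values excluding the two boundary doses: with L dose
levels that is K = L − 2 interior knots and K + d + 1 = L + 2 basis
functions. The basis therefore spans more directions than the design
identifies: the likelihood pins the curve down **only at the observed dose
levels**. Among all coefficient vectors with identical fitted values (and
identical likelihood), the reported curve is the one minimizing the
integrated squared second derivative, computed by projecting out the design
null space with a spline curvature penalty matrix. Without this step the
min-norm-coefficient representative oscillates between dose levels, which
is invisible to the likelihood but corrupts BMD and TCD readouts on narrow
response bands. Between-dose behavior remains an interpolation choice —
no estimator can recover features narrower than the dose spacing.

A single-function "basis" N(D) = D embeds the linear model in the spline
machinery; the spline-mixed fit restricted to it reproduces the linear
mixed model's likelihood, which the tests use as an internal oracle.
Spline candidates require at least 4 distinct dose levels (linear trends 3)
and are skipped, with a recorded reason, below that.

## Dose scale and counts preprocessing

Doses spanning several orders of magnitude should be log10-transformed
(`log10_dose=True`); zero (control) doses are mapped to a pseudo-dose of
one tenth of the smallest positive dose, recorded in the provenance and
used for back-transformation.

Counts are library-size normalized to `log2(CPM + 0.5)`. Per-feature NB
dispersion φ (variance µ + φµ²) is estimated by method of moments on
library-normalized counts and shrunk toward a lowess mean-dispersion trend
with a weight reflecting the moment estimator's degrees of freedom;
sub-Poisson features get φ = 0. Precision weights are the inverse
delta-method variance of log2 counts, `w = ln(2)² / (1/µ + φ)`, with µ the
expected count of the cell from the feature's mean CPM and the sample's
library size. This Gaussian-on-transformed-scale treatment (rather than a
true NB-GLMM likelihood) matches fitting linear mixed models to weighted
log expression; it is accurate for moderate-to-large counts and is a known
limitation for very low counts.

## Pre-filters

Three optional gene-set filters run before fitting, each a pure function
of the transformed data with strict (">") thresholds:

- **invariant** (on by default): drop when more than 50% of member genes
  have variance within the 10% quantile of lowest variances among *all*
  features in the dataset;
- **antagonistic** (on by default): drop when more than 50% of member gene
  pairs have negative Pearson correlation (zero-variance genes excluded
  from both numerator and denominator);
- **PC1** (off by default): drop when the first principal component of the
  member submatrix explains more than 70% of its variance. As specified
  this removes precisely the highly coherent sets a clean dose response
  produces, so it is not enabled unless asked for; the threshold and
  switch are exposed.

Raising any threshold can only move a set from drop to keep (monotone),
and decisions are fully determined by the reported diagnostics.

## BMD and TCD

`y0` is the fitted fixed-effect curve at the lowest (control) dose and SD
is the residual standard deviation σ̂ of the selected model — not the SD of
control observations, which would mix gene-level heterogeneity into the
band. The BMD is the first dose (scanning ascending, linear interpolation
between the 200 grid points) where `|f(D) − y0| ≥ z·σ̂`, a two-sided band
exit whose first-crossing rule covers biphasic curves; the direction of
departure is recorded. z defaults to 1 and is a direct multiplier of σ̂.

TCDs are strict sign changes of the analytic first derivative (maxima /
minima, classified by the second derivative) and of the analytic second
derivative (inflections) of the fitted spline, refined by root bracketing;
boundary doses are excluded and a linear best model has no TCDs. TCDs are
sorted ascending; TCD1 is the first.

Both are computed on the modeling dose scale and back-transformed to
natural units for reporting.

## Bootstrap confidence intervals

Each of `n_boot = 1000` replicates draws ⌈0.6·n⌉ **samples** (columns)
without replacement, allocated across dose levels by largest remainder so
every level keeps representation, refits the originally selected model
kind (warm-started), and recomputes BMD and TCDs. The CI is the 2.5/97.5
percentile band. Resampling samples rather than genes preserves the
within-gene dose series, which is the correlation structure the model
exploits; gene-level resampling would instead bootstrap the random-effect
population. Replicates are not re-run through model selection: reusing the
selected kind is cheaper and avoids mixing model-selection variability
into the threshold CI. Replicates where a threshold is undefined are
dropped and counted; a CI is reported unavailable when fewer than half the
replicates define it. TCD replicate values are matched to each original
TCD by type and nearest dose. Everything is reproducible from the seed.

## Clustering of divergent subgroups

Genes are clustered by k-means (25 restarts, fixed seed) on their
empirical-Bayes random-effect coordinates — baseline plus dose-effect
coefficients — standardized per dimension; k is the argmax of mean
silhouette over 2…k_max, with k = 1 declared when the best silhouette
falls below 0.25. Derived sets are named `<parent>__cluster<i>`, partition
the parent exactly, and are refit independently. Known limitation:
argmax-silhouette can over-split when a standardized coordinate carries no
structure at all (pure noise dimensions); in practice the EB coordinates
of genuinely divergent sets separate along several coordinates at once,
where selection is stable.

## Pipeline

Per gene set: size gate and filters → candidate fits → AIC/LRT selection.
Benjamini–Hochberg correction is applied across all *parent* sets that
reached fitting; a set is called significant when its best model is
non-null and its adjusted p < α. Significant sets get BMD/TCDs with
bootstrap CIs and, optionally, clustering with per-cluster refits (cluster
rows carry raw p only and point thresholds without bootstrap, keeping cost
bounded). Per-pathway seeds derive from the global seed and the pathway
name (CRC32), so serial and multi-worker runs are byte-identical.

## Synthetic data generator

The generator draws from exactly the model class the fitter assumes:
shared pathway shape (flat, linear, sigmoid, bell, U, antagonistic) scaled
by an effect size, gene random intercepts, multiplicative gene slope
perturbations (sign-flipped for half the genes in antagonistic sets),
Gaussian residual noise; for counts, the latent log2 mean is exponentiated,
scaled by a log-normal library factor (SD 0.1), and drawn NB with the
specified dispersion. Defaults mirror a typical in-vitro design: 8
half-log doses, 3 replicates, baseline 8 (log2 scale), intercept SD 1.0,
slope SD 0.2, residual SD 0.3, log10 dose modeling.

Shapes live on the normalized dose axis t ∈ [0, 1]; sigmoid (logistic,
center 0.5, width 0.15) and bell/U (Gaussian, center 0.5, width 0.18)
widths are chosen so the transition spans several intervals of the default
dose design — a shape narrower than the dose spacing would not be
identifiable from the design and could not serve as a recovery target.
Turning/inflection points and the band crossing for a given benchmark
response have closed forms, implemented independently of the grid-scanning
estimators so the two can cross-check each other.

What the generator does **not** emulate: realistic library-size
heterogeneity beyond the log-normal factor, batch effects, gene–gene
correlation beyond the shared pathway trend, compositional effects of a
full transcriptome, or heavy-tailed technical noise. Passing tests
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to everything real data does.

## Problem sizes in the test suite

The simulation-based tests use desk-scale designs chosen to keep the suite
fast while leaving each check statistically decisive: 6–8 dose levels × 3
replicates, 10–20 genes per set, 500 replicates for type-I calibration,
20 replicates per noise level for BMD recovery, and bootstrap defaults
(1000 × 60%) wherever the bootstrap contract itself is under test.

## Known limitations

- Gaussian mixed models on precision-weighted log2-CPM, not a true NB
  GLMM; very low counts are approximated.
- Diagonal random-effect covariance; correlated gene-level deviations are
  projected onto independent coordinates.
- χ² reference for the LRT with boundary variance components is
  approximate (empirically slightly conservative here).
- Between-dose curve behavior is an interpolation choice; thresholds
  falling between widely spaced doses inherit that uncertainty.
- No covariates other than dose; no batch correction; equal gene weights
  within a set.
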