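# pathdose

Pathway-level dose-response modeling for omics data: mixed-effects cubic
splines, benchmark doses (BMD) and trend-change doses (TCD) with bootstrap
confidence intervals.

## The problem

Toxicogenomics and pharmacogenomics experiments measure expression (RNA-seq
counts, microarray/proteomics/metabolomics log-intensities) across a series
of doses of a compound, and ask: *at what concentration does a biological
process begin to respond, and how?* Gene-by-gene dose-response fitting is
noisy and ignores that genes act in sets; `pathdose` instead models an
entire gene set at once, borrowing strength across genes while letting each
gene deviate from the shared trend.

For gene *j* in sample *i* the model is

```
Y_ij = β0 + b_0j + f_j(D_i) + ε_ij
```

where `β0` is the pathway's average expression, `b_0j ~ N(0, τ0²)` a
gene-specific random intercept, and `f_j(D)` the dose-response function:
either linear, `f_j(D) = (β1 + b_1j) D`, or a cubic B-spline with
gene-specific coefficients,

```
f_j(D) = Σ_k (β_k + b_kj) N_k(D),    k = 1 … K + d + 1,
```

with `N_k` the B-spline basis (degree d = 3, K interior knots placed at the
non-boundary dose levels) and independent gene-level deviations `b_kj`.
Four candidates — null (no dose effect), linear mixed, spline with fixed
coefficients, spline mixed — are fitted by maximum likelihood; the best
model is the lowest-AIC candidate whose likelihood-ratio test against the
null clears p < 0.05, and p-values are Benjamini–Hochberg-corrected across
gene sets. Counts first pass through a negative-binomial dispersion
estimate and enter the models as precision-weighted log2-CPM.

From the selected model's fitted curve the package derives:

- **BMD** — the first dose at which the curve exits the band
  `y0 ± z·SD` (`y0` = fitted response at the control dose, `SD` = residual
  standard deviation, `z` = 1 by default), covering monotone and biphasic
  curves alike;
- **TCDs** — doses of maxima, minima and inflection points of the curve,
  computed from analytic spline derivatives; `TCD1` is the lowest one;
- 95% confidence intervals for both, from 1000 refits on dose-stratified
  60% subsamples.

Divergent gene sets (e.g. half up-, half down-regulated) can be split by
k-means on the genes' fitted random-effect coordinates, with the number of
clusters chosen by silhouette, and each cluster refit as its own set.

## Worked example

`examples/` contains one narrative script per capability. Fitting a
simulated 12-gene pathway with a sigmoid response over 8 half-log doses
(`python examples/01_fit_one_pathway.py`):

```
dataset: 12 genes x 24 samples, 8 dose levels

model                 logLik       AIC  params       LRT p
null                 -363.43    732.86       3
linear_mixed         -107.43    224.86       5   6.59e-112
nonlinear_fixed       -92.29    204.57      10   6.43e-113
nonlinear_mixed       -83.94    207.87      20   6.74e-108

selected: nonlinear_fixed  (RMSE 0.291)
```

All three dose models beat the null decisively; the spline with shared
coefficients wins on AIC. Thresholds for a bell-shaped pathway
(`python examples/02_benchmark_and_trend_change_doses.py`):

```
best model: nonlinear_mixed
BMD  = 0.009579  (95% CI 0.007382 - 0.01115)
TCD1 = 0.04604  inflection  (95% CI 0.03962 - 0.05078)
TCD2 = 0.1801   maximum     (95% CI 0.1687 - 0.1971)
TCD3 = 0.6849   inflection  (95% CI 0.637 - 0.8065)
```

The BMD (in the original concentration units) marks where the pathway
first leaves its control band; the TCDs trace where the curve bends and
peaks. The other examples cover the full multi-pathway pipeline, divergent
gene clustering and the RNA-seq counts workflow, and the same pipeline is
available from the shell:

```bash
pathdose simulate --out-prefix demo --seed 2
pathdose run --matrix demo_matrix.tsv --metadata demo_metadata.tsv \
    --gmt demo_sets.gmt --omics log --log10-dose --out results/ --seed 1
```

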