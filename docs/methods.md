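# Methods

This note records the models the package implements, the defaults and why,
the numerical choices, and what the synthetic cohort does and does not
emulate.

## Data model

An `ExpressionDataset` holds a strictly positive samples × analytes RFU
matrix (or its log2 transform, tracked by a scale flag), per-analyte
annotations (SeqId, gene symbol, mitochondrial flag) and per-sample clinical
metadata (subtype, metastatic status, prior systemic therapy, IMDC risk,
sarcomatoid/rhabdoid features, overall-survival time in months and event
indicator).  Ingestion rejects missing or non-positive cells rather than
imputing: the platform's output is complete, and silent imputation would
distort the downstream variance estimates.  Analytes sharing a gene symbol
stay separate features through every matrix operation; collapse to genes
happens only in the enrichment stage, where the mapping must be explicit.

Cross-assay harmonization multiplies each analyte's RFU by its bridging
scalar.  Analytes without a scalar are dropped, never passed through
unscaled — mixing scaled and unscaled analytes would silently bias the fold
changes — and the drop count is recorded in the dataset provenance.

## Moderated differential expression

Each analyte g is fitted with the two-group design (intercept + subtype
indicator), so the effect is the ChRCC-minus-ccRCC mean difference on the
log2 scale and the residual variance s²_g has df = n − 2 degrees of freedom.
No covariates enter the design.  The variance ensemble is shrunk toward a
scaled-inverse-chi-square prior with hyperparameters (d₀, s₀²) estimated by
moment matching on e_g = log s²_g − ψ(df/2) + log(df/2): the excess of
var(e) over ψ′(df/2) identifies d₀ through a Newton inversion of the
trigamma function, and mean(e) identifies s₀²; a non-positive excess maps
to d₀ = ∞ (complete pooling).  The posterior variance
s̃²_g = (d₀s₀² + df·s²_g)/(d₀ + df) gives the moderated t on d₀ + df degrees
of freedom (normal reference when d₀ = ∞).  Setting d₀ = 0 recovers the
ordinary pooled-variance two-sample t exactly; both limits are tested.
Calls use |log2FC| ≥ 1 and Benjamini–Hochberg q ≤ 0.05, both thresholds
inclusive.

The paired tissue comparison (tumor vs matched normal) uses the Wilcoxon
signed-rank test: zeros discarded, midranks on tied magnitudes, exact
two-sided p for n ≤ 25 computed by a subset-sum convolution over the
sign-flip distribution of the doubled midranks (valid under ties), and the
continuity-corrected normal approximation above.  The exact/approximate
crossover at 25 keeps enumeration cheap where it is feasible.

## Over-representation analysis

The universe is the set of unique non-empty gene symbols on the analyte
panel after any feature-space restriction; a gene is a hit when at least one
of its analytes is called upregulated.  Genome-wide universes would make
every panel-biased set look enriched, and the choice is recorded in the
pipeline manifest.  Each set's overlap with the universe is tested with the
one-sided hypergeometric upper tail; sets with universe overlap < 2 are
skipped (degenerate tails would otherwise dominate the BH correction) and
reported.  Live pathway-database access is out of scope; collections come
from user GMT files, a packaged mini-collection of mitochondrial pathway
sets (real gene symbols, hand-curated) or, on synthetic cohorts, a generated
collection with one planted-pathway positive and random negatives.

## L1-penalized logistic solver

The solver minimizes (1/n)Σ[log(1+e^{η_i}) − y_i η_i] + λΣ|β_j| with an
unpenalized intercept by penalized IRLS: probabilities are clipped to
[10⁻⁵, 1−10⁻⁵] (the glmnet convention), the weighted-lasso subproblem is
solved by cyclic coordinate descent with soft thresholding, and convergence
is judged on the curvature-weighted coefficient change max_j xv_j·Δβ_j²
(default tolerance 10⁻¹⁰) plus a relative deviance-plateau stop at 10⁻¹⁰,
which terminates quasi-separable fits that would otherwise crawl along the
flat likelihood surface.  Paths over decreasing λ are warm-started, screen
features by the sequential strong rule 2λ_k − λ_{k−1} with a full KKT check
afterwards (screening therefore never changes the solution), and stop
refining once 99.9% of the null deviance is explained, with the saturated
solution inherited by smaller penalties.  λ_max = max_j |x_jᵀ(y − ȳ)|/n is
analytic.  Everything is numba-compiled and deterministic; KKT residuals at
tight tolerance are below 10⁻⁶ and the solution is checked against an
unpenalized Newton fit at λ = 0 and a dense coefficient grid on two-feature
problems.

## Penalty selection

Per fitting set, λ is chosen on a log-spaced grid from λ_max down two
decades (15 points) by stratified 5-fold cross-validation on held-out
binomial deviance.  Two choices matter and are deliberate:

* **Grouped folds.**  Inside a bootstrap resample, all copies of a
  duplicated source sample are assigned to the same fold.  Row-level folds
  leak duplicated samples between training and validation, which on pure
  noise drags λ far down the grid and selects dozens of spurious features
  per bootstrap; grouping removes the leak.
* **One-standard-error rule.**  The selected λ is the largest penalty whose
  mean deviance is within one SE of the minimum (the plain minimum is
  available as `rule="min"`).  The minimum rule admits cohort-level spurious
  correlations — which cross-validation within a fixed cohort cannot
  detect — and destroys the null calibration of the stability procedure;
  the one-SE rule restores it and matches the common glmnet convention for
  extracting coefficients.

## Bootstrap stability selection

Each of the (default 100) iterations draws a class-stratified bootstrap of
the full sample size — with only 18 cases, unstratified resampling would
occasionally produce single-class training sets — z-scales features on the
bootstrap (ddof = 1, the R `scale()` convention; zero-variance features are
excluded and reported), selects λ, fits, and records the nonzero features.
Out-of-bag samples are scored with the training scaling; sensitivity and
specificity use the predicted-probability threshold 0.5, and iterations
whose OOB set lacks a class contribute no AUROC and are tallied separately
rather than biasing the mean.  One master seed spawns per-iteration
substreams, so increasing the iteration count leaves earlier iterations
untouched and two runs with the same seed are bit-identical.

Features with selection frequency ≥ 1/3 are retained.  The final score's
coefficients come from a full-data L1 refit restricted to the retained
features at a CV-selected penalty (averaging bootstrap coefficients was the
considered alternative; the refit matches the convention of reporting one
sparse model).  The reported score is the weighted sum of z-scaled
expression values without the intercept.  An empty retained set is flagged
(`no_stable_features`), not an error.  Standardization is per bootstrap on
the training resample; a global standardization would leak location/scale
information from OOB samples into training.

## Survival

Kaplan–Meier estimation is delegated to lifelines; the log-rank statistic
is the observed-minus-expected chi-square with hypergeometric variance per
distinct event time (1 df), implemented vectorized so the maxstat scan and
its permutations are cheap, and cross-checked against lifelines and a
brute-force summation.  The maximally selected rank statistic evaluates
every distinct score within the (0.1, 0.9) quantile window as a threshold
(low: score ≤ cut), breaking ties toward the lower cutpoint.  Because
maximizing inflates type I error, the result carries both the naive
log-rank p at the selected cutpoint and, when requested, a seeded
permutation-adjusted p (default 1,000 label permutations).  Single-protein
analyses use a median split (ties at the median go low).  The univariable
Cox model is a scalar Newton–Raphson on the Breslow partial likelihood with
step halving, Wald intervals from the observed information, and a monotone-
likelihood guard (|β|·sd(x) > 10 flags non-convergence); Efron tie handling
is available by delegating to lifelines.  Days convert to months at
30.4375 days/month.  Samples lacking survival data are dropped with a
count.

## Synthetic cohort

log2 intensities are Normal(baseline_p + group·δ_p, σ) with per-analyte
baselines uniform on [6, 12] and σ = 1.0 by default; RFU = 2^log2, i.e. a
log-normal assay model matching the pipeline's log2-then-linear-model
assumption.  Defaults mirror the study conditions: 18 cases vs 197
controls; 1,000 analytes (desk-scale stand-in for the 7,289-analyte panel)
with 400 mitochondria-flagged; 24 planted upregulated analytes with δ
spanning 2.5–3.8 (18 of them mitochondrial); three downregulated analytes
at −2.5, −1.2, −1.0; clinical covariates drawn independently of expression
at the cohort's marginal frequencies; and survival with hazard
h₀·exp(β·score), β = 0.8, h₀ = ln2/24 per month (median OS two years at
score 0), uniform censoring calibrated by bisection to the target censored
fraction (default 0.4) within ±0.05.  The true per-sample score is the
z-scored sum of the planted mitochondrial analytes' log2 values.

Covariates follow subtype-specific marginal frequencies, so subtype-
covariate association (e.g. prior therapy far commoner among cases) is
present by construction and exercises the multivariable adjustment;
conditional on subtype, covariates are independent of expression.

What the generator does **not** emulate: aptamer cross-reactivity, plate
and batch effects, heavy-tailed or skewed RFU noise, covariate–expression
dependence beyond subtype, and correlation structure among analytes beyond
the planted effects.  Tests passing on this
generator therefore demonstrate the correctness and calibration of the
machinery under the stated model, not robustness to real-data artifacts.

## Problem sizes in the test suite

The acceptance-style tests run at the study's group sizes (18 vs 197) with
desk-scale feature counts: 800 mitochondria-flagged analytes and 100
bootstrap iterations for the planted-signature recovery (10 replicates),
600 analytes and 50 iterations for the pure-noise null calibration (20
runs), 2,000 analytes for the global-null differential-expression check,
and the full default cohort for the end-to-end determinism check.  These
sizes are the package's chosen simulation scale; the generator accepts the
full panel size behind the same interface.

## Known limitations

* The empirical-Bayes estimator assumes a common df across analytes (true
  for the two-group design) and no mean–variance trend.
* The stability procedure's selection frequencies are conditional on one
  cohort; they quantify resampling stability, not replication across
  cohorts.
* OOB sensitivity/specificity at threshold 0.5 can span the full [0, 1]
  range when OOB positive counts are tiny, as with 18 cases.
* The maxstat permutation adjustment permutes scores against survival
  jointly, which assumes exchangeability under the null.
* The Cox implementation is univariable by design; multivariable survival
  modelling is out of scope.
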