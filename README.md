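# mitosig

Plasma-proteomic discrimination of chromophobe renal cell carcinoma (ChRCC)
from clear-cell renal cell carcinoma (ccRCC).

ChRCC is a rare kidney-cancer subtype whose cells accumulate abnormal
mitochondria, and this mitochondrial phenotype leaks into the circulating
proteome: plasma levels of β-oxidation enzymes, mitochondrial ribosomal and
chaperone proteins, and creatine-kinase energy-buffering enzymes run higher
in ChRCC than in ccRCC.  `mitosig` implements the full analysis that turns a
SomaScan-style relative-fluorescence-unit (RFU) matrix into a compact
mitochondrial diagnostic signature:

1. **Ingestion & harmonization** — a minimal ADAT dialect or a TSV triple;
   11K→7K cross-assay bridging by per-analyte multiplicative scalars
   (un-bridged analytes are dropped and counted).
2. **Moderated differential expression** — per-analyte two-group linear
   models on log2 intensities with empirical-Bayes variance moderation:
   s̃²_g = (d₀s₀² + df·s²_g)/(d₀ + df), t_g = log2FC_g / (s̃_g·√(1/n₁+1/n₂))
   on d₀ + df degrees of freedom; calls at |log2FC| ≥ 1 and
   Benjamini–Hochberg q ≤ 0.05.
3. **Pathway over-representation** — aptamer→gene collapse, one-sided
   hypergeometric tails against GMT gene-set collections, BH across sets.
4. **Mitochondria-restricted bootstrap-LASSO stability selection** — across
   100 class-stratified bootstrap resamples, an L1-penalized logistic model
   (own coordinate-descent solver) is fitted on z-scaled log2 intensities
   with the penalty chosen per bootstrap by grouped, stratified 5-fold CV
   (one-SE rule on binomial deviance); out-of-bag samples yield per-iteration
   AUROC / sensitivity / specificity.  Features selected in ≥ 1/3 of
   bootstraps are retained, and a full-data penalized refit gives the score
   **score = Σ_f coef_f · z_f**, evaluated by ROC/AUROC overall and in
   metastatic-only and treatment-naïve subsets, with multivariable logistic
   adjustment for prior therapy, IMDC risk and sarcomatoid/rhabdoid features.
5. **Survival** — Kaplan–Meier curves, log-rank tests, maximally selected
   rank-statistic cutpoints (with optional permutation-adjusted p), median
   splits, and univariable Cox models (Breslow ties).

Because the study's patient-level data are not public, the package ships a
first-class synthetic-cohort generator (`mitosig.synthetic`) that emulates
the study's structure — 18 ChRCC vs 197 ccRCC, planted upregulated analytes
with log2FC in the 2.5–3.8 range (mostly mitochondria-flagged), three
downregulated analytes at −2.5/−1.2/−1.0, clinical covariates at the
cohort's marginal frequencies, and overall survival with hazard
h₀·exp(β·score) — so every stage is testable end to end.

## Worked example

```python
from mitosig import synthetic as syn, diffexpr, signature

spec = syn.SyntheticCohortSpec(seed=7)          # 18 vs 197, 1000 analytes
data, truth = syn.generate_cohort(spec)
data = syn.attach_survival(data, truth, spec)
log2 = data.log2()

de = diffexpr.ModeratedTTest(log2).fit()
print(de.summary())

res = signature.StabilitySelection.from_dataset(log2, restrict_mito=True) \
               .fit(n_iterations=100, seed=7)
print(res.summary())
```

prints (abridged):

```
Moderated differential expression (ChRCC vs ccRCC)
==================================================
analytes tested:      1000
prior df d0:          3338.35
prior variance s0^2:  0.9980
call thresholds:      |log2FC| >= 1.0, q <= 0.05
upregulated:          24
downregulated:        2

Bootstrap-LASSO stability selection
===================================
iterations:            100
retention threshold:   0.333
features considered:   400
retained features:     14
  seq-00001: frequency 1.00, coefficient +0.3727
  seq-00002: frequency 0.97, coefficient +0.4215
  ...
full-cohort AUROC:     1.000
mean OOB AUROC:        1.000
median OOB sens/spec:  1.00 / 1.00
```

Here the moderated-t stage recovers 24 of this cohort's 24 planted
upregulated analytes (2 of 3 planted downregulated ones clear both
thresholds), the stability stage retains 14 of the 18 planted mitochondrial
analytes at the 1/3 frequency threshold, and the resulting score separates
the two subtypes perfectly on this strongly-separated synthetic cohort.
`res.score(...)`, `res.roc()`, `mitosig.survival.maxstat_cutpoint(...)` then
stratify new samples and survival.

## Command line

```sh
mitosig simulate --spec spec.yaml --out cohort/      # synthetic cohort
mitosig run --config cfg.yaml                        # full pipeline
mitosig de / enrich / select / survive ...           # per-stage commands
```

`mitosig run` writes seven text artifacts (DE table, enrichment table,
stability model JSON, overall and subset ROC TSVs, survival results JSON,
and a reproducibility manifest with the seed and a config hash); identical
configs and seeds give bit-identical outputs.

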