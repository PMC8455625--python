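# Methods

## Feature representation

Two channels per gene on a harmonized cancer-gene panel (the intersection
of the panels available on every platform involved, ordered by the first):

* **Mutation channel** (`GENE:mut`, binary). A sample is "mutant" in a gene
  iff at least one call's consequence class alters the protein-coding
  sequence: missense, nonsense, frameshift, in-frame indel, or splice site.
  Silent, intronic, intergenic, UTR and other non-coding calls never set
  the bit. Splice-site calls are included as coding-affecting, following
  standard somatic-filtering practice. Samples absent from the call table
  are wild-type (all zeros) — absence of evidence is coded as "not
  present". Consequence labels are mapped through a single documented
  synonym table that accepts both MAF-style (`Missense_Mutation`) and plain
  (`missense`) spellings; unknown labels are an error, not a guess.
* **Expression channel** (`GENE:expr`, continuous, dimensionless).
  `log2(FPKM + 1)`, then the per-gene median across the cohort's samples is
  subtracted. The +1 pseudo-count (configurable) keeps zero FPKM finite.
  Median centering is per gene by default because it makes the feature
  *relative to this cohort*, which is what lets a model trained on one
  platform transfer to another: any per-gene location shift (library
  chemistry, quantification pipeline) cancels exactly. A cohort-global
  median mode exists for sensitivity analysis. Per-gene centering is the
  default because cross-platform transfer is the point of the design.

Gene symbols are uppercased everywhere on ingest so the mutation,
expression and panel files key together.

## Signature training

Per drug, elastic net on the standardized design:

    (1/2n) Σ (y_i − β0 − x_i·β)² + λ(α‖β‖₁ + (1−α)/2 ‖β‖₂²)

* **α grid**: {0.1, 0.325, 0.55, 0.775, 1.0} — five points spanning
  ridge-like to lasso.
* **λ path**: per α, 100 log-spaced values from
  λ_max = max_j |⟨z_j, y−ȳ⟩| / (n·max(α, 10⁻³)) down to 10⁻⁴·λ_max.
  λ_max is the smallest penalty at which the lasso-type solution is
  identically zero, so the path starts at the empty model and descends.
* **Cross-validation**: 10-fold, mean squared error. Fold labels come from
  a seeded shuffle of sample positions dealt round-robin, so the assignment
  is a pure function of (seed, n, n_folds) and training is reproducible end
  to end. Ties in CV error break toward larger λ, then larger α — the
  sparser model.
* **Standardization**: features are scaled to unit variance internally
  (binary mutation indicators included, no special casing) so λ is
  comparable across features; coefficients are transformed back to the
  original feature scale before locking. Zero-variance features get
  coefficient 0.
* **Degenerate input**: a constant response yields an intercept-only model
  with a warning rather than an error, so a screen with a few flat drugs
  still trains end to end; fewer than 2·n_folds samples is an error.

The solve at a fixed (α, λ) is scikit-learn's coordinate descent
(tolerance 10⁻⁹, warm-started along each descending λ path); the test
suite pins it against the ridge closed form (α=0) and the single-predictor
soft-threshold formula (α=1) computed independently.

A fitted model is **locked**: an immutable (intercept, named coefficients,
α, λ, seed) record. Serialization is a long-format TSV with `repr`-level
floats (exact round trip); zero coefficients are omitted from the file and
restored from the recorded feature namespace.

## Scoring

score(d, s) = β0_d + Σ_f β_d[f]·x_s[f], aligned by feature *name* — column
order is irrelevant. Lower score = predicted more sensitive (the score is a
predicted Z-scored IC50). Under the default `zero_fill` policy a feature
missing from the scored cohort contributes 0, the neutral value under both
encodings (cohort median expression; wild type); the per-drug count of
filled features is logged. An `error` policy lists the missing features
instead. Zero-fill is the default because cross-cohort panels are
intersected up front, so missing features are rare and neutral.

## Validation statistics

* **External correlation**: higher AUC means less sensitive while a lower
  score means more sensitive, so each drug's scores are correlated with
  *negative* AUC (Pearson; p from the t transform on n−2 df; 95% CI by
  Fisher z). Benjamini–Hochberg step-up adjustment is applied across the
  tested drugs; drugs with <3 paired samples are skipped with a warning.
  The BH implementation is the literal step-up definition
  (adjᵢ = min_{j≥i} p₍ⱼ₎·m/j, capped at 1) and is cross-checked against
  statsmodels in the tests. Published validation tables print the CI as
  [upper, lower]; exports here use (ci_low, ci_high).
* **Biomarker concordance**: each indication is a predicate (drug, optional
  tumor-site filter, rule, expected direction). Rules: mutated/wild-type
  gene sets, specific protein changes (e.g. V600E/V600K, matched against
  protein-altering calls only), expression above a within-cohort quantile
  (ties negative, strictly-greater comparison), or an annotation flag
  (receptor status, promoter methylation and similar phenotypic calls).
  Scores are compared between marker groups with Welch's unequal-variance
  t-test (the default unpaired t-test in most statistical environments; df
  by Welch–Satterthwaite). The verdict is a pure function of the sign of
  the mean difference, the p-value, and two thresholds: significant
  (p < 0.05) in the expected direction → concordant; significant the wrong
  way → discordant; expected direction with 0.05 ≤ p < 0.10 → borderline;
  otherwise not significant.
* **Interaction test**: logistic regression
  `response ~ treatment + score + treatment:score` by maximum likelihood
  (statsmodels Newton, tolerance 10⁻⁸, ≤100 iterations), Wald p for the
  interaction term (a likelihood-ratio variant is available). A
  significant interaction is what makes the score a *predictive* biomarker
  — it modifies the effect of that treatment — as opposed to a prognostic
  one that tracks outcome in every arm. Non-convergence and separation are
  reported as errors, never as silent estimates; quasi-separation is
  flagged when any coefficient exceeds 15 in absolute value on the
  standardized-score scale. Two-sided p-values throughout.

## Discovery scan

For each (drug, gene) with mutation frequency ≥ 5% (and optionally
restricted to an allowlist of named drugs), OLS of the drug's scores on
[intercept, mutation, one-hot(tumor site − reference)]. The site block
separates pan-cancer association from tissue enrichment; the reference
level is the lexicographically first site, and the mutation t-statistic is
invariant to that choice. Pairs are ranked by signed t ascending (most
negative = most sensitizing; an |t| option serves two-sided discovery),
ties broken lexicographically on (drug, gene). The top ceil(fraction·K)
pairs (default 1%) are carried forward; ceiling guarantees non-empty
output at small K. Rank-deficient designs (e.g. a mutation perfectly
confounded with one site) are skipped with a logged reason. The ranking
uses raw t; BH-adjusted p-values are attached for context only.

## Synthetic cohorts

The generators emulate the statistical structure the pipeline assumes, not
the biology of any real dataset:

* **Training**: FPKM = max(2^N(μ_g, σ_g) − 1, 0) per gene; Bernoulli(π_g)
  mutation status emitted as missense calls with random protein changes,
  plus decoy silent/intronic calls (rate 0.05 per gene-sample) so the
  consequence filter is always exercised; response = sparse linear truth
  over the *preprocessed* features + N(0, σ²), then Z-scored per drug
  (matching the per-drug standardization of the training target). Default
  study conditions: 500 samples, 60 genes, 10 drugs, 5 nonzero
  coefficients per drug with magnitudes 0.5–1.5 of either sign, σ = 0.5,
  mutation rates 5–35%, log2 expression means 1–6 with SD 0.6–1.4 —
  chosen as a realistic desk-scale stand-in for a screen of ~10³ lines on
  a ~700-gene panel.
* **External**: shares the training truth; per-gene location shifts are
  added to expression means (the platform effect median centering must
  remove) and response is AUC — a decreasing logistic transform of the
  standardized true linear predictor plus Gaussian noise, clipped to
  [0, 1].
* **Clinical**: Bernoulli treatment assignment; binary response from
  logit⁻¹(b0 + b_t·T + b_s·s + b_ts·T·s); a percent-response column is
  drawn consistently with the 50% responder threshold (responders 51–100%,
  others 0–50%).

All generators are pure functions of (config, seed). What passing tests on
these cohorts show is that the *pipeline machinery* is correct — recovery
of planted linear effects, neutralization of location-type batch effects,
calibrated error rates. What they do not show: robustness to nonlinear
drug response, copy-number or fusion effects, correlated co-mutation
structure, tumor-type-specific expression programs, or non-location batch
effects (scale/quantile distortions). Conclusions about real cohorts need
real cohorts.

## Numerical and design notes

* Readers reject, rather than repair, invariant violations (duplicate gene
  symbols, negative FPKM, duplicate response keys, non-boolean flags),
  naming the offending row/column. Duplicated expression gene symbols are
  rejected rather than aggregated because any merge rule would be a guess.
* AUC is assumed on [0, 1]; an `--auc-percent` flag divides by 100.
* Exact float round trips everywhere they matter: model files and score
  matrices are written with 17 significant digits and read back with
  pandas' round-trip float parser.
* Test problem sizes (e.g. 10 simulated drugs, 100-seed scan replicates,
  1000-replicate calibration at n = 200) were chosen as the smallest scales
  at which the checked properties are statistically sharp.

## Known limitations

* Only linear, additive signatures; no interactions between features.
* The mutation channel is presence/absence — zygosity, clonality and
  variant-level effect differences are out of scope, as are fusions,
  methylation and copy number (consumable only as annotation flags).
* The interaction model contains exactly the three named terms; additional
  clinical covariates are not adjusted for.
* The discovery scan fits one model per (drug, gene) pair; a joint
  multi-mutation model would share variance differently.
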