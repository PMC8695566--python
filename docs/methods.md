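# Methods

This note documents the statistical model behind the synthetic cohorts, the
estimators and their numerical choices, and the design decisions taken where
the problem left the design open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The synthetic cohort model

The generator (`icimeth.simulate`) emulates a pan-cancer multi-omic study:
per-tumor-type case groups with methylation (β values), RNA-seq counts, a
MAF-like mutation table and overall survival. Its latent state per case is:

- a **responder flag**, Bernoulli with a per-type rate
  (`responder_rate_by_type`, default an even grading 0.03–0.30 across
  types, mimicking the wide spread of ICI-favorable fractions across tumor
  types);
- an **immune hot/cold cluster**: responders are hot with probability
  1 − `cluster_flip` (default 0.9), non-responders with probability
  `hot_background` (default 0.3). This keeps the two infiltration clusters
  of comparable size — as infiltration clusters are in real cohorts — while
  enriching responders in the hot one. Survival is exponential with
  type-specific baseline scales and hazard ratio `survival_hr` (default 2)
  of cold over hot, censored administratively (uniform 6–60 months);
- two **continuous drivers**: a per-case mutation-rate multiplier
  (log-normal, ×`tmb_shift` = 3 in responders) feeding the Poisson
  truncation/non-truncation mutation counts, and a TGF-β pathway activity
  (normal, −`tgfb_shift` = 1 in responders) feeding the pathway genes'
  log₂ expression means with their regulatory sign.

Methylation is generated in M-space (per-probe baseline N(0, 1.5²), case
noise N(0, `noise_sd`²), default 0.5) and mapped to β. The
`n_informative` probes add an `effect_m`-scaled shift (default 2 M-units)
whose driver is split 60% / 25% / 15% between the binary cluster, the
standardized log mutation rate, and the standardized TGF-β activity.
The split encodes that tumor methylomes carry more than a binary
infiltration state — hypermutator-associated and TGF-β-associated
methylation exist alongside immune-cell composition — and it is what gives
a trained classifier information the cluster-level naive predictor cannot
have; with a purely binary driver the two would share one information
ceiling, which contradicts how such models behave on real cohorts. The
first `n_signature` probes instead mix `n_cell_types` cell-type β
archetypes with Dirichlet weights whose CD8-like component concentrates in
hot-cluster cases; the archetype matrix doubles as the deconvolution
reference. All probe/gene-level parameters come from a random stream keyed
by the seed alone, case-level draws from a stream keyed by
(seed, case_stream) — an external cohort is therefore the *same assay* on
*new patients*, with a configurable fraction of probe IDs renamed to
emulate a different chip, plus clinical response and progression-free
survival columns.

**What the generator does not emulate:** probe annotation (islands,
coordinates), spatially correlated probes, batch effects, missing values
(matrices are complete), type-specific methylation baselines, and any
dependence structure between TMB and TGF-β beyond the shared responder
flag. Passing tests therefore demonstrate correctness and calibration of
the pipeline's statistics under its assumed structure, not performance on
TCGA-like data.

## Estimators

- **β→M transform**: M = log₂(β/(1−β)), base 2 by array-analysis
  convention so |logFC| > 1 means a two-fold methylation-odds change.
  β is clamped to [10⁻³, 1−10⁻³] on input to keep M finite.
- **Moderated t**: per-feature two-group OLS fit; residual variances shrunk
  toward a prior s₀² with prior df d₀ estimated by matching the mean and
  variance of log s² to the theoretical log-χ² moments (digamma/trigamma;
  the trigamma equation is inverted by bracketed root-finding). If the
  observed variances are under-dispersed the prior df is infinite and all
  features share s₀². Features constant in both groups get p = 1. Degrees
  of freedom d₀ + df; normal tail when d₀ = ∞. The implementation is
  cross-checked against limma's eBayes in the test suite.
- **Differential expression** is median-of-ratios normalization,
  log₂(x+1), then the same moderated t — a deliberate simplification of
  count-model DE: the pipeline consumes only (logFC, adjusted p, direction),
  and the simulation-based calling tests (null FDR, 4-fold power) bound its
  behavior. All-zero genes are excluded and reported as untested.
- **BH adjustment** wraps the standard step-up procedure (statsmodels).
- **TMB**: (2·truncation + non-truncation)/45; the divisor (a per-exome-
  megabase normalization) is a parameter. Unrecognized variant classes are
  counted and ignored; absent cases get TMB 0 with a warning.
- **Label thresholds**: type-7 (linear-interpolation) quantiles, strict
  inequalities on both arms, thresholds pooled over all cases ignoring
  tumor type. Under independence of the two arms the positive rate is
  0.25 × 0.5 = 12.5%; on the default cohort the responder coupling raises
  it to ≈19%.
- **Deconvolution**: min ‖Rf − b‖² s.t. f ≥ 0, Σf ≤ 1. NNLS solves the
  relaxed problem; only when its optimum violates the simplex bound is the
  Σf = 1 face re-solved with SLSQP (exact, and the constraint then binds).
  A rank-deficient reference triggers a warned ridge stabilization (10⁻⁶).
- **PAM (k = 2)**: classic BUILD + SWAP on the Euclidean distance matrix,
  iterated to a local optimum; deterministic, no RNG. Cluster 2 is the
  group with the larger mean *observed* OS time (censoring ignored, as a
  plain mean-survival reading; a restricted-mean variant would slot in at
  the same place). The relabeling is idempotent.
- **SVM kernel scale**: σ² = λ·d·s̄² with s̄² the mean per-feature variance
  of the *original* training cases (before oversampling) and d the feature
  count. The dimension factor is required: squared distances grow linearly
  in d, so a scale of λ·s̄² alone (the verbal "mean variance times λ" rule)
  degenerates to a near-identity kernel beyond a handful of features —
  observed as constant predictions at every λ in 1..20. `svm_gamma`
  exposes the un-normalized form for low-dimensional use. C is fixed at 1;
  λ ties break toward the smaller value.
- **Oversampling** duplicates positive training indices with replacement up
  to the negative count; the negative multiset is never altered; applied
  inside each CV training fold and each split's training set only.
- **Splits** are stratified by label (at ~10–20% positives unstratified
  splits routinely lose the positive class); a split whose test half lacks
  positives is redrawn with a logged count. λ is either fixed (the
  single-tuning protocol used throughout the analysis scripts, λ = 13) or
  re-selected by CV per training split (`refit_lambda`).
- **Null controls**: random-probe comparisons are *paired* — the true set
  is re-evaluated on each control's split seeds — and ties count ½, so
  under a no-signal cohort the win indicators are exchangeable. Because a
  fixed probe set retains its chance association with noise labels across
  resplits of one cohort, the zero-signal calibration check redraws the
  cohort every few comparisons; only across independent cohorts is the
  win rate a binomial-calibrated 0.5. The "total random" baseline compares
  the labels with an independent shuffle; a rate-p random predictor has
  expected F1 = p.
- **Dendrogram adjacency**: average-linkage Euclidean hierarchical
  clustering on M-values; consecutive leaves form a 2×2 contingency tested
  by χ². Linkage is configurable in code; average linkage is the default
  for array profiles.

## Problem sizes

The default `SimConfig` — 8 types × 188 cases, 5,000 probes,
300 informative, 200 signature, 2,000 genes, effect 2 M-units — is the
package's full-scale study condition; the acceptance checks run at this
scale. Control experiments (permutation, random-probe, complementarity)
use 3–4-type cohorts of 300–500 cases, which preserve every qualitative
contrast while keeping a full run in minutes on one CPU. The
random-probe-control experiment additionally uses a *sparse-universe*
cohort (signal probes ≈2.6% of the chip) because on the default cohort 10%
of probes carry signal and equal-sized random sets are themselves
informative — on a real 450K array the signature is a vanishing fraction
of the chip, and the sparse variant is the faithful analog.

## Known limitations

- The surrogate label is itself a model; on synthetic data its prevalence
  floor under the threshold rule is 12.5%, above the severe imbalance seen
  in real pan-cancer labeling, so oversampling is exercised but less
  stressed than in practice.
- The deconvolution reference is synthetic archetypes, not a published
  leukocyte reference; the computation's shape (constrained projection,
  fraction clustering) is preserved, absolute fractions are not meaningful.
- Mean observed survival ignores censoring when orienting clusters; with
  heavy differential censoring the cluster-2 convention could flip.
- λ = 13 is carried as the fixed-protocol default; on other data the CV
  path should be preferred.
- The combined-model evaluation standardizes per feature within training
  splits; no cross-block weighting is attempted.
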