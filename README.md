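# icimeth

Pan-cancer prediction of immune-checkpoint-inhibitor (ICI) responsiveness
from DNA methylation profiles.

Only a minority of cancer patients respond to checkpoint blockade, and no
single established biomarker (tumor mutation burden, PD-L1 expression, MSI)
predicts response reliably across tumor types. DNA methylation is a rich,
clinically accessible readout of the tumor immune microenvironment. This
package implements, end to end, a pipeline that builds a methylation-based
response classifier on a pan-cancer cohort — and, because no large public
immunotherapy cohort with methylation profiling exists, ships a synthetic
cohort generator with the statistical structure the analysis assumes, so
every stage is testable offline. It is aimed at computational biologists
studying epigenetic immunotherapy biomarkers and at methodologists who want
a fully reproducible reference implementation of this class of pipeline.

## The method

**Surrogate labels.** With no measured clinical response, a case is labeled
*responsive* when it simultaneously has

- TMB above the pan-cancer upper quartile, with
  TMB = (2·truncation + non-truncation) / 45 — truncation mutations
  (Frame_Shift_Ins/Del, Nonsense, Splice_Site) count double; and
- a TGF-β pathway score below the pan-cancer median, where the score is the
  regulatory-direction-weighted average of per-gene z-scored
  log₂ CPM-normalized expression over the TGF-β signaling pathway.

Both high mutation burden and low TGF-β activity are established,
complementary correlates of checkpoint-inhibitor benefit; their conjunction
yields a rare positive class that motivates the oversampling below.

**Feature selection.** β values are logit-transformed to M-values,
M = log₂(β/(1−β)). Per tumor type (with > 5 positive cases), cases are
deconvolved against reference immune methylation profiles (non-negative
least squares on the signature probes, fractions summing to ≤ 1) and
PAM-clustered (k = 2); the longer-mean-survival group is *cluster 2*. Three
responsiveness indicators are tested between clusters — overall survival
(log-rank), TMB (Mann-Whitney U), PD-L1/CD274 expression (moderated
differential expression) — with BH correction across tumor types
(FDR < 0.01). Differentially methylated probes between clusters
(empirical-Bayes moderated t on M-values, |logFC| > 1, adjusted p < 0.01)
are then *direction-voted*: a probe is a feature for an indicator when it
is a DMP with the same sign in at least half of that indicator's
significant tumor types. The three voted sets are merged with the
immune-signature probes.

**Classifier.** An RBF-kernel SVM, K(a,b) = exp(−‖a−b‖²/(2σ²)) with the
kernel scale tied to the data, σ² = λ·d·s̄² (s̄² = mean per-feature training
variance, d = feature count), and only the integer multiplier λ ∈ 1..20
tuned by stratified 5-fold cross-validation. Positive training cases are
resampled with replacement to the number of negatives before every fit.
Comparators: L1 logistic regression, random forest, kNN, and a *naive*
predictor that calls each tumor type's higher-mean-TMB cluster positive.

**Evaluation battery.** F1, MCC and AUC over repeated stratified 80/20
splits; equal-sized random-probe controls; label-permutation nulls with a
closed-form "total random" baseline; separation of held-out biomarkers
(PD-1, CTLA4, CD8⁺ fraction, MSI) between predicted groups; per-tumor-type
metrics with the predicted-vs-true positive-proportion Spearman ρ; a χ²
test of responsiveness dependence between dendrogram-adjacent cases; and
transfer to an external cohort on a partially overlapping probe set.

## Worked example

The numbered scripts under `analysis/` run the study on the synthetic
cohort (8 tumor types, 1,504 cases, 5,000 probes of which 300 carry
immune-related signal):

```bash
python analysis/01_simulate_cohort.py      # writes results/cohort
python analysis/02_label_cases.py
python analysis/03_cluster_and_select.py
python analysis/04_train_and_evaluate.py
python analysis/05_null_controls.py
python analysis/06_complementarity_and_external.py
```

Output of `02_label_cases.py`:

```
18.88% of 1504 cases labeled positive (TMB > 2.32, score < 0.050)
```

so roughly one case in five satisfies both the TMB and TGF-β criteria —
the class imbalance the oversampling step absorbs. `03_cluster_and_select.py`
reports that the OS / TMB / PD-L1 indicators separate the infiltration
clusters in 8 / 6 / 5 of the 8 tumor types and that the direction vote
recovers all 300 planted informative probes:

```
300/300 planted informative probes recovered among 300 voted probes
```

`04_train_and_evaluate.py` then shows the trained SVM dominating the naive
cluster-TMB predictor, and the predicted per-type positive proportions
tracking the true ones:

```
model metric   mean  ci_low  ci_high  n_splits
  SVM     f1 0.8572  0.8470   0.8674        20
  SVM    mcc 0.8262  0.8117   0.8406        20
  SVM    auc 0.9877  0.9862   0.9892        20
naive     f1 0.4712  0.4589   0.4836        20
naive    mcc 0.3287  0.3101   0.3473        20
SVM vs naive: mean MCC diff +0.497, Wilcoxon p = 1.91e-06
predicted-vs-true positive proportion: mean Spearman rho 0.713 over 20 test sets
```

`05_null_controls.py` confirms the performance is not an artifact: with the
labels permuted the model's MCC collapses to the total-random baseline
(+0.003 vs +0.001), the responsiveness of dendrogram-adjacent cases is
strongly dependent (χ² = 1031.7, p = 2.3×10⁻²²⁶), and in a probe universe
where planted probes are a realistically small fraction of the chip they
beat 100/100 equal-sized random sets (mean F1 0.895 vs 0.604).
`06_complementarity_and_external.py` retrains on the 400 feature probes
present on the external cohort's chip and transfers with F1 0.826 /
AUC 0.991, with progression-free survival significantly longer in predicted
responders (log-rank p = 2.6×10⁻¹³).

A thin CLI wraps the same stages (`icimeth simulate`, `icimeth label`,
`icimeth run-all --seed 1 --out out/`).

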