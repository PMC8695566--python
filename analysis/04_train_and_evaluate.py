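"""Train the oversampled RBF-SVM on the selected probes and evaluate it.

Evaluates the SVM (lambda = 13, the single-tuning protocol) against the
naive cluster-TMB predictor and the L1-logistic / random-forest / kNN
comparators over repeated stratified 80/20 splits, with per-tumor-type
metrics and the predicted-vs-true positive-proportion Spearman correlation.
Writes report.tsv, per_type.tsv and rho.tsv.
"""

import argparse

import pandas as pd

from icimeth.evaluate import feature_matrix, per_type_eval, repeated_split_eval
from icimeth.labeling import compute_tmb
from icimeth.pipeline import _naive_from_flat, read_cohort


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", default="results")
    parser.add_argument("--splits", type=int, default=20)
    parser.add_argument("--comparator-splits", type=int, default=5,
                        help="comparator models are slower; fewer splits")
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    bundle = read_cohort(f"{args.results}/cohort")
    labels = pd.read_csv(f"{args.results}/labels.tsv", sep="\t", index_col=0)["label"]
    features = pd.read_csv(f"{args.results}/features.tsv", sep="\t", index_col=0)
    clusters = pd.read_csv(f"{args.results}/clusters.tsv", sep="\t", index_col=0)

    tmb = compute_tmb(bundle.mutations, bundle.case_ids)
    naive = (_naive_from_flat(clusters, tmb)
             .reindex(bundle.case_ids).fillna(0).astype(int))
    X = feature_matrix(bundle, list(features.index))
    report = repeated_split_eval(
        X, labels, models=("SVM",), n_splits=args.splits, seed=args.seed,
        lam=13.0, extra_predictions={"naive": naive},
    )
    agg = report.aggregate()
    agg.to_csv(f"{args.results}/report.tsv", sep="\t", index=False)
    print(agg.round(4).to_string(index=False))
    cmp = report.paired_tests("SVM", "naive", "mcc")
    print(f"SVM vs naive: mean MCC diff {cmp['mean_diff']:+.3f}, "
          f"Wilcoxon p = {cmp['wilcoxon_p']:.2e}")

    comp = repeated_split_eval(
        X, labels, models=("SVM", "LR_L1", "RF", "kNN"),
        n_splits=args.comparator_splits, seed=args.seed, lam=13.0,
    )
    comp_agg = comp.aggregate()
    comp_agg.to_csv(f"{args.results}/comparators.tsv", sep="\t", index=False)
    print("\ncomparator models (shared splits):")
    print(comp_agg.round(4).to_string(index=False))

    per_type, rho = per_type_eval(report, bundle.clinical, labels)
    per_type.to_csv(f"{args.results}/per_type.tsv", sep="\t", index=False)
    rho.to_csv(f"{args.results}/rho.tsv", sep="\t", index=False)
    vals = rho["spearman_rho"].dropna()
    if len(vals):
        print(f"\npredicted-vs-true positive proportion: mean Spearman rho "
              f"{vals.mean():.3f} over {len(vals)} test sets")


if __name__ == "__main__":
    main()
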