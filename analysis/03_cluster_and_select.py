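"""Infiltration clustering, indicator tests and direction-voted feature selection.

Per tumor type with enough positive cases, cases are deconvolved against the
immune reference, PAM-partitioned into two clusters (cluster 2 = longer mean
survival), and the OS / TMB / PD-L1 indicators are tested between clusters
with BH correction across types. DMPs between clusters are direction-voted
across the indicator-significant types and merged with the usable signature
probes. Writes clusters.tsv, indicators.tsv and features.tsv.
"""

import argparse

import pandas as pd

from icimeth.pipeline import PipelineConfig, read_cohort, select_features_stage


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", default="results")
    args = parser.parse_args()

    bundle = read_cohort(f"{args.results}/cohort")
    labels = pd.read_csv(f"{args.results}/labels.tsv", sep="\t", index_col=0)["label"]
    fs, indicators, extra = select_features_stage(bundle, labels, PipelineConfig())

    fs.table.to_csv(f"{args.results}/features.tsv", sep="\t")
    indicators.to_csv(f"{args.results}/indicators.tsv", sep="\t", index=False)
    extra["clusters"].to_csv(f"{args.results}/clusters.tsv", sep="\t")

    sig = indicators.groupby("indicator")["significant"].sum()
    print("tumor types significant per indicator (FDR < 0.01):")
    print(sig.to_string())
    per_ind = fs.table["indicators"].str.get_dummies(sep=",").sum()
    print(f"\nselected {len(fs)} probes; per provenance:")
    print(per_ind.to_string())
    if bundle.informative_probes:
        voted = [p for p in fs.probes if p not in set(bundle.signature_probes)]
        hits = len(set(voted) & set(bundle.informative_probes))
        print(f"\n{hits}/{len(bundle.informative_probes)} planted informative "
              f"probes recovered among {len(voted)} voted probes")


if __name__ == "__main__":
    main()
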