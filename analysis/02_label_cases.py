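"""Construct surrogate ICI-responsiveness labels from TMB and the TGF-beta score.

A case is labeled positive when its tumor mutation burden exceeds the
pan-cancer upper quartile AND its TGF-beta pathway score falls below the
pan-cancer median. Writes results/labels.tsv and prints the class balance
per tumor type.
"""

import argparse

from icimeth.labeling import assign_labels, compute_tgfb_score, compute_tmb
from icimeth.pathways import default_pathway
from icimeth.pipeline import read_cohort


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", default="results")
    args = parser.parse_args()

    bundle = read_cohort(f"{args.results}/cohort")
    tmb = compute_tmb(bundle.mutations, bundle.case_ids)
    score = compute_tgfb_score(bundle.counts, default_pathway())
    resp = assign_labels(tmb, score)
    resp.table.to_csv(f"{args.results}/labels.tsv", sep="\t")

    print(f"{resp.positive_fraction:.2%} of {len(resp.table)} cases labeled positive "
          f"(TMB > {resp.tmb_threshold:.2f}, score < {resp.score_threshold:.3f})")
    by_type = resp.labels.groupby(bundle.clinical["tumor_type"]).mean()
    print("positive fraction by tumor type:")
    print(by_type.round(3).to_string())


if __name__ == "__main__":
    main()
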