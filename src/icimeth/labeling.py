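"""Surrogate ICI-responsiveness labels from mutation burden and TGF-beta score.

Large pan-cancer immunotherapy cohorts with methylation profiling do not
exist, so responsiveness is defined indirectly: a case is positive when its
tumor mutation burden (TMB) is above the pan-cancer upper quartile AND its
TGF-beta pathway score is below the pan-cancer median, both thresholds
computed over all cases ignoring tumor type. High TMB and low TGF-beta
activity are independent, established correlates of checkpoint-inhibitor
benefit; their conjunction yields a rare positive class (12.5% under
independence, less when the two are dependent).

TMB here is a weighted per-megabase-scaled mutation count,
(2 x truncation + non-truncation) / 45, where truncation mutations
(frameshift indels, nonsense, splice-site) count double.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from icimeth.diffstats import normalize_counts
from icimeth.simulate import TRUNCATION_CLASSES, NONTRUNCATION_CLASSES

logger = logging.getLogger(__name__)

TMB_DIVISOR = 45.0  # exome megabase-equivalent


@dataclass
class MutationSummary:
    """Per-case truncation/non-truncation counts and the derived TMB."""

    table: pd.DataFrame  # index case; columns truncation, nontruncation, tmb
    ignored_classes: dict[str, int]

    @property
    def tmb(self) -> pd.Series:
        return self.table["tmb"]


@dataclass
class PathwayScore:
    """Direction-weighted average of per-gene z-scored log expression."""

    score: pd.Series  # per case
    genes_used: list[str]
    weights: pd.Series


@dataclass
class ResponseLabels:
    """Binary responsiveness labels with their threshold provenance."""

    table: pd.DataFrame  # index case; columns tmb, tgfb_score, label
    tmb_threshold: float
    score_threshold: float

    @property
    def labels(self) -> pd.Series:
        return self.table["label"]

    @property
    def positive_fraction(self) -> float:
        return float(self.table["label"].mean())


def compute_tmb(
    mutations: pd.DataFrame, case_ids, divisor: float = TMB_DIVISOR
) -> MutationSummary:
    """Tally truncation/non-truncation mutations per case and derive TMB.

    ``mutations`` must carry ``Tumor_Sample_Barcode`` and
    ``Variant_Classification`` columns. Variant classes outside the eight
    recognized ones are ignored (counted and logged); cases absent from the
    table get TMB 0.
    """
    case_ids = pd.Index(case_ids)
    vc = mutations["Variant_Classification"]
    recognized = set(TRUNCATION_CLASSES) | set(NONTRUNCATION_CLASSES)
    ignored = vc[~vc.isin(recognized)].value_counts().to_dict()
    if ignored:
        logger.warning("ignored %d mutations in unrecognized classes: %s",
                       sum(ignored.values()), ignored)

    barcode = mutations["Tumor_Sample_Barcode"]
    trunc = (
        barcode[vc.isin(TRUNCATION_CLASSES)].value_counts().reindex(case_ids, fill_value=0)
    )
    nontrunc = (
        barcode[vc.isin(NONTRUNCATION_CLASSES)].value_counts().reindex(case_ids, fill_value=0)
    )
    missing = ~case_ids.isin(barcode.unique())
    if missing.any():
        logger.warning("%d cases absent from mutation table; TMB set to 0", missing.sum())

    tmb = (2.0 * trunc + nontrunc) / divisor
    table = pd.DataFrame(
        {"truncation": trunc, "nontruncation": nontrunc, "tmb": tmb}, index=case_ids
    )
    return MutationSummary(table=table, ignored_classes=ignored)


def compute_tgfb_score(expression: pd.DataFrame, pathway: pd.DataFrame) -> PathwayScore:
    """Score each case by direction-weighted average pathway expression.

    Expression counts are normalized (median-of-ratios), log2(x+1)
    transformed and z-scored per gene across cases; the score is
    sum(w_g * z_gc) / sum(|w_g|) over the pathway genes present in the
    matrix. Zero-variance genes contribute z = 0.
    """
    pathway = pathway.set_index("gene")["weight"] if "gene" in pathway.columns else pathway
    present = [g for g in pathway.index if g in expression.index]
    if not present:
        raise ValueError("no pathway gene present in the expression matrix")
    weights = pathway.loc[present].astype(float)

    norm = normalize_counts(expression)
    logx = np.log2(norm.loc[present] + 1.0)
    mu = logx.mean(axis=1)
    sd = logx.std(axis=1, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning("%d zero-variance pathway genes scored as z=0", int(zero_var.sum()))
    z = logx.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)

    score = z.mul(weights, axis=0).sum(axis=0) / weights.abs().sum()
    return PathwayScore(score=score, genes_used=present, weights=weights)


def assign_labels(tmb: MutationSummary, score: PathwayScore) -> ResponseLabels:
    """Label positive the cases with TMB > Q3(TMB) and score < median(score).

    Both thresholds are pan-cancer (all cases pooled, linear-interpolation
    quantiles); comparisons are strict, so cases sitting exactly on a
    threshold are negative.
    """
    cases = tmb.table.index
    if not cases.equals(score.score.index):
        if set(cases) != set(score.score.index):
            raise ValueError("TMB and score case sets differ")
        score = PathwayScore(score.score.reindex(cases), score.genes_used, score.weights)
    if len(cases) < 4:
        raise ValueError("need at least 4 cases for a meaningful upper quartile")

    q3 = float(np.quantile(tmb.tmb.to_numpy(), 0.75))  # type-7 interpolation
    med = float(np.quantile(score.score.to_numpy(), 0.5))
    label = ((tmb.tmb > q3) & (score.score < med)).astype(int)
    table = pd.DataFrame(
        {"tmb": tmb.tmb, "tgfb_score": score.score, "label": label}, index=cases
    )
    return ResponseLabels(table=table, tmb_threshold=q3, score_threshold=med)
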