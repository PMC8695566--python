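"""Readers/writers and the end-to-end pipeline driver.

The driver executes label -> cluster -> select-features -> train/evaluate
over a cohort bundle, writing every intermediate as TSV/JSON into an
artifact directory together with a manifest (config hash, seed, package
version). Stages are checkpointed: a rerun skips stages whose outputs
already exist, and a resumed run produces outputs identical to a full one
because every stage is a deterministic function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from icimeth import __version__
from icimeth.diffstats import beta_to_m, moderated_t
from icimeth.evaluate import (
    EvaluationReport, feature_matrix, per_type_eval, repeated_split_eval,
)
from icimeth.features import FeatureSet, assemble_feature_set, dmps_per_type, vote_probes_table
from icimeth.infiltration import INDICATORS, cluster_all_types, indicator_tests, significant_types
from icimeth.labeling import TMB_DIVISOR, assign_labels, compute_tgfb_score, compute_tmb
from icimeth.models import DEFAULT_LAMBDA_GRID
from icimeth.pathways import default_pathway
from icimeth.simulate import BETA_CLAMP, CohortBundle, SimConfig, generate_cohort

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# TSV interchange

def _write_matrix(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t")


def _read_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    bad = df.columns[df.dtypes == object]
    if len(bad):
        cell = df[bad[0]].map(lambda v: not _is_number(v)).idxmax()
        raise ValueError(f"non-numeric matrix cell at row {cell!r}, column {bad[0]!r}")
    return df


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def write_bundle(bundle: CohortBundle, out_dir: Path) -> None:
    """Write a cohort as beta/counts/mutations/clinical (+truth) TSV files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_matrix(bundle.beta, out_dir / "beta.tsv")
    _write_matrix(bundle.counts, out_dir / "counts.tsv")
    bundle.mutations.to_csv(out_dir / "mutations.tsv", sep="\t", index=False)
    bundle.clinical.to_csv(out_dir / "clinical.tsv", sep="\t")
    if bundle.truth is not None:
        bundle.truth.to_csv(out_dir / "truth.tsv", sep="\t")
    if bundle.reference is not None:
        _write_matrix(bundle.reference, out_dir / "reference.tsv")
    meta = {"informative_probes": bundle.informative_probes,
            "signature_probes": bundle.signature_probes}
    (out_dir / "probes.json").write_text(json.dumps(meta))


def read_cohort(in_dir: Path, clamp: float = BETA_CLAMP) -> CohortBundle:
    """Read a bundle directory, align case sets and clamp beta values.

    Cases present in only some tables are dropped (intersection) with a
    logged report; beta values at 0/1 are clamped inside (0, 1).
    """
    in_dir = Path(in_dir)
    beta = _read_matrix(in_dir / "beta.tsv")
    counts = _read_matrix(in_dir / "counts.tsv")
    mutations = pd.read_csv(in_dir / "mutations.tsv", sep="\t", comment="#")
    clinical = pd.read_csv(in_dir / "clinical.tsv", sep="\t", index_col=0, comment="#")

    cases = beta.columns.intersection(counts.columns).intersection(clinical.index)
    if len(cases) == 0:
        raise ValueError("no case present in all of beta, counts and clinical")
    dropped = (len(set(beta.columns) | set(counts.columns) | set(clinical.index))
               - len(cases))
    if dropped:
        logger.warning("dropped %d cases missing from at least one table", dropped)

    n_clamped = int(((beta <= 0) | (beta >= 1)).to_numpy().sum())
    if n_clamped:
        logger.warning("clamped %d beta values into (%g, %g)", n_clamped, clamp, 1 - clamp)
    beta = beta.clip(lower=clamp, upper=1 - clamp)

    truth = reference = None
    if (in_dir / "truth.tsv").exists():
        truth = pd.read_csv(in_dir / "truth.tsv", sep="\t", index_col=0).loc[cases]
    if (in_dir / "reference.tsv").exists():
        reference = _read_matrix(in_dir / "reference.tsv")
    informative, signature = [], []
    if (in_dir / "probes.json").exists():
        meta = json.loads((in_dir / "probes.json").read_text())
        informative = meta.get("informative_probes", [])
        signature = meta.get("signature_probes", [])

    bundle = CohortBundle(
        beta=beta[cases], counts=counts[cases],
        mutations=mutations[mutations["Tumor_Sample_Barcode"].isin(cases)],
        clinical=clinical.loc[cases], truth=truth,
        informative_probes=informative, signature_probes=signature,
        reference=reference,
    )
    bundle.check_aligned()
    return bundle


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "pipeline_out"
    tmb_divisor: float = TMB_DIVISOR
    lfc_threshold: float = 1.0
    dmp_p_threshold: float = 0.01
    fdr_threshold: float = 0.01
    min_positives_selection: int = 5      # types need MORE than this many positives
    min_pos_frac_eval: float = 0.05
    min_pos_eval: int = 20
    lam: float | None = None              # None: select once by CV
    lam_grid: tuple = DEFAULT_LAMBDA_GRID
    n_splits: int = 100
    test_frac: float = 0.2
    seed: int = 0

    def hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # location, not analysis identity
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


# ---------------------------------------------------------------------------
# stages

def select_features_stage(
    bundle: CohortBundle,
    labels: pd.Series,
    config: PipelineConfig,
) -> tuple[FeatureSet, pd.DataFrame, dict]:
    """Cluster per type, run indicator tests, vote DMPs, assemble features."""
    pos_by_type = labels.groupby(bundle.clinical["tumor_type"]).sum()
    eligible = sorted(pos_by_type.index[pos_by_type > config.min_positives_selection])
    if not eligible:
        raise ValueError("no tumor type has enough positive cases for selection")
    logger.info("feature selection over %d tumor types: %s", len(eligible), eligible)

    clin = bundle.clinical[bundle.clinical["tumor_type"].isin(eligible)]
    assignments = cluster_all_types(bundle.beta, bundle.reference, clin)
    tmb = compute_tmb(bundle.mutations, bundle.case_ids, config.tmb_divisor)
    indicators = indicator_tests(
        assignments, tmb, bundle.counts, bundle.clinical, config.fdr_threshold
    )

    # One cluster-2-vs-cluster-1 DMP call per tumor type serves all three
    # indicators (the clusters do not change per indicator).
    m_values = beta_to_m(bundle.beta)
    results_by_type = {}
    for tt, asg in assignments.items():
        cases = asg.assignment.index
        groups = (asg.assignment == 2).astype(int).to_numpy()
        results_by_type[tt] = moderated_t(m_values[cases], groups)
    dmps = dmps_per_type(results_by_type, config.lfc_threshold, config.dmp_p_threshold)

    per_indicator = {}
    for ind in INDICATORS:
        sig = significant_types(indicators, ind)
        if sig:
            per_indicator[ind] = vote_probes_table(dmps, sig)
        else:
            logger.warning("indicator %s has no significant tumor type", ind)
    fs = assemble_feature_set(per_indicator, bundle.signature_probes, bundle.beta)

    flat = pd.concat(
        [a.assignment.rename("cluster").to_frame().assign(tumor_type=tt)
         for tt, a in assignments.items()]
    )
    return fs, indicators, {"assignments": assignments, "clusters": flat, "tmb": tmb}


def run_pipeline(config: PipelineConfig, resume: bool = True) -> Path:
    """Execute the full analysis, checkpointing each stage to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"config_hash": config.hash(), "seed": config.seed,
                "version": __version__,
                "config": dataclasses.asdict(config)}
    if manifest_path.exists() and resume:
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") != config.hash():
            raise ValueError("existing artifact directory was built with a different config")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    def done(*names):
        return resume and all((out / n).exists() for n in names)

    # stage: simulate
    cohort_dir = out / "cohort"
    if not done("cohort/beta.tsv"):
        logger.info("stage simulate")
        write_bundle(generate_cohort(config.sim), cohort_dir)
    bundle = read_cohort(cohort_dir)

    # stage: label
    if not done("labels.tsv"):
        logger.info("stage label")
        tmb = compute_tmb(bundle.mutations, bundle.case_ids, config.tmb_divisor)
        score = compute_tgfb_score(bundle.counts, default_pathway())
        resp = assign_labels(tmb, score)
        resp.table.to_csv(out / "labels.tsv", sep="\t")
        (out / "label_thresholds.json").write_text(json.dumps(
            {"tmb_q3": resp.tmb_threshold, "score_median": resp.score_threshold}))
    labels = pd.read_csv(out / "labels.tsv", sep="\t", index_col=0)["label"]

    # stage: cluster + select features
    if not done("features.tsv", "clusters.tsv", "indicators.tsv"):
        logger.info("stage select-features")
        fs, indicators, extra = select_features_stage(bundle, labels, config)
        fs.table.to_csv(out / "features.tsv", sep="\t")
        indicators.to_csv(out / "indicators.tsv", sep="\t", index=False)
        extra["clusters"].to_csv(out / "clusters.tsv", sep="\t")
    features = pd.read_csv(out / "features.tsv", sep="\t", index_col=0)
    clusters = pd.read_csv(out / "clusters.tsv", sep="\t", index_col=0)

    # stage: train + evaluate
    if not done("report.json"):
        logger.info("stage evaluate")
        X = feature_matrix(bundle, list(features.index))
        tmb = compute_tmb(bundle.mutations, bundle.case_ids, config.tmb_divisor)
        naive = _naive_from_flat(clusters, tmb).reindex(bundle.case_ids).fillna(0).astype(int)
        report = repeated_split_eval(
            X, labels, models=("SVM",), n_splits=config.n_splits,
            test_frac=config.test_frac, seed=config.seed, lam=config.lam,
            lam_grid=config.lam_grid,
            extra_predictions={"naive": naive},
        )
        per_type, rho = per_type_eval(
            report, bundle.clinical, labels,
            min_pos_frac=config.min_pos_frac_eval, min_pos=config.min_pos_eval,
        )
        agg = report.aggregate()
        payload = {
            "aggregate": agg.to_dict(orient="records"),
            "per_split": report.per_split.to_dict(orient="records"),
            "lambda": report.config["lam"],
            "mean_spearman_rho": (float(np.nanmean(rho["spearman_rho"]))
                                  if len(rho) else None),
        }
        (out / "report.json").write_text(json.dumps(payload, indent=2))
        if len(per_type):
            per_type.to_csv(out / "per_type.tsv", sep="\t", index=False)
    return out


def _naive_from_flat(clusters: pd.DataFrame, tmb) -> pd.Series:
    """Flat clusters.tsv -> per-case naive labels (higher-mean-TMB cluster)."""
    pieces = []
    for tt, sub in clusters.groupby("tumor_type"):
        s = sub["cluster"]
        t = tmb.tmb.loc[s.index]
        means = t.groupby(s).mean()
        if len(means) < 2 or means.iloc[0] == means.iloc[1]:
            pos = means.index[0]
        else:
            pos = means.idxmax()
        pieces.append((s == pos).astype(int))
    return pd.concat(pieces)
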