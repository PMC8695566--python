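"""Synthetic pan-cancer cohort generator.

Emulates the statistical structure the downstream analysis assumes without
any external download: per-tumor-type case groups, a latent two-cluster
immune-infiltration structure expressed both in a block of "informative"
CpG probes (M-value shift between clusters) and in a mixture-of-archetypes
immune signature block, mutation counts whose derived TMB is elevated in
latent responders, TGF-beta pathway expression suppressed in responders,
checkpoint marker genes (CD274/PDCD1/CTLA4), CD8+ fraction and MSI status
separated by responder state, and exponential survival with a configurable
hazard ratio between the latent clusters.

Everything is reproducible bit-for-bit from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from icimeth.pathways import TGFB_PATHWAY, MARKER_GENES

TRUNCATION_CLASSES = (
    "Frame_Shift_Ins", "Nonsense_Mutation", "Frame_Shift_Del", "Splice_Site",
)
NONTRUNCATION_CLASSES = (
    "Missense_Mutation", "In_Frame_Del", "In_Frame_Ins", "Nonstop_Mutation",
)

BETA_CLAMP = 1e-3


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic pan-cancer cohort.

    Parameters
    ----------
    n_types, cases_per_type
        Number of tumor types and cases per type (scalar or one count per
        type).
    n_probes, n_informative, n_signature
        Total CpG probes; probes carrying the latent-cluster M-value shift;
        probes forming the immune-infiltration signature block.
    n_genes
        Expression genes (the TGF-beta pathway and marker genes are a prefix
        of the gene list).
    effect_m
        Mean M-value shift of informative probes between latent clusters.
    responder_rate_by_type
        Per-type probability that a case is a latent responder; defaults to
        an even grading from 0.05 to 0.35, mimicking the wide spread of
        positive-case proportions across tumor types.
    tmb_shift
        Multiplicative factor on expected mutation counts in responders.
    tgfb_shift
        Log2-scale expression shift applied against the pathway direction in
        responders (responders end up with low TGF-beta scores).
    survival_hr
        Hazard ratio of the immune-cold latent cluster over the immune-hot
        (responder-enriched) cluster.
    noise_sd
        Per-case M-value noise standard deviation.
    cluster_flip
        Probability that a responder falls OUTSIDE the immune-hot cluster.
    hot_background
        Probability that a non-responder falls inside the immune-hot
        cluster; together with ``cluster_flip`` this keeps the two clusters
        of comparable size (as infiltration clusters are in real cohorts)
        while enriching responders in the hot one.
    """

    n_types: int = 8
    cases_per_type: int | Sequence[int] = 188
    n_probes: int = 5000
    n_informative: int = 300
    n_signature: int = 200
    n_genes: int = 2000
    effect_m: float = 2.0
    responder_rate_by_type: Sequence[float] | None = None
    tmb_shift: float = 3.0
    tgfb_shift: float = 1.0
    survival_hr: float = 2.0
    noise_sd: float = 0.5
    cluster_flip: float = 0.1
    hot_background: float = 0.3
    marker_shift: float = 1.0
    n_cell_types: int = 6
    dispersion: float = 0.1
    seed: int = 0

    def counts_per_type(self) -> np.ndarray:
        if np.isscalar(self.cases_per_type):
            return np.full(self.n_types, int(self.cases_per_type))
        return np.asarray(self.cases_per_type, dtype=int)

    def rates(self) -> np.ndarray:
        if self.responder_rate_by_type is None:
            return np.linspace(0.03, 0.30, self.n_types)
        return np.asarray(self.responder_rate_by_type, dtype=float)

    def validate(self) -> None:
        counts = self.counts_per_type()
        rates = self.rates()
        if self.n_types <= 0 or self.n_probes <= 0 or self.n_genes <= 0:
            raise ConfigError("dimensions must be positive")
        if (counts < 2).any():
            raise ConfigError("need at least 2 cases per tumor type")
        if len(counts) != self.n_types or len(rates) != self.n_types:
            raise ConfigError("per-type vectors must have length n_types")
        if self.n_informative + self.n_signature > self.n_probes:
            raise ConfigError("informative + signature probes exceed n_probes")
        if ((rates < 0) | (rates > 1)).any() or not 0 <= self.cluster_flip <= 1:
            raise ConfigError("rates must lie in [0, 1]")
        if self.noise_sd < 0 or self.tmb_shift <= 0:
            raise ConfigError("noise_sd must be >= 0 and tmb_shift > 0")


@dataclass
class CohortBundle:
    """Aligned multi-omic tables for one cohort.

    ``beta`` is probes x cases (values strictly inside (0, 1)); ``counts``
    is genes x cases (nonnegative integers); ``mutations`` is a MAF-like
    long table; ``clinical`` is indexed by case with ``tumor_type``,
    ``os_time`` and ``os_event`` columns (external cohorts add ``response``
    and PFS fields). ``truth`` holds the generator's latent state and is
    absent for real data.
    """

    beta: pd.DataFrame
    counts: pd.DataFrame
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame | None = None
    informative_probes: list[str] = field(default_factory=list)
    signature_probes: list[str] = field(default_factory=list)
    reference: pd.DataFrame | None = None
    #: synthetic only: informative probe -> which latent variable drives it
    #: ("cluster", "tmb" or "tgfb")
    probe_drivers: pd.Series | None = None

    @property
    def case_ids(self) -> pd.Index:
        return self.clinical.index

    def check_aligned(self) -> None:
        cases = self.clinical.index
        if not (self.beta.columns.equals(cases) and self.counts.columns.equals(cases)):
            raise ValueError("case IDs differ across bundle tables")


def _clamp_beta(beta: np.ndarray, eps: float = BETA_CLAMP) -> np.ndarray:
    return np.clip(beta, eps, 1.0 - eps)


def _m_to_beta(m: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + 2.0 ** (-m))


def _gene_names(n_genes: int) -> list[str]:
    named = [g for g, _ in TGFB_PATHWAY] + list(MARKER_GENES)
    if n_genes < len(named):
        raise ConfigError(f"n_genes must be at least {len(named)}")
    return named + [f"GENE{i:05d}" for i in range(n_genes - len(named))]


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


#: Partition of the informative probes by what drives their M-value shift:
#: a fraction tracks the binary hot/cold cluster, the rest track the
#: continuous latent mutation rate and TGF-beta activity (methylation in
#: real tumors reflects more than a binary infiltration state, which is
#: what gives a trained classifier its edge over the cluster-level naive
#: predictor).
INFORMATIVE_SPLIT = {"cluster": 0.6, "tmb": 0.25, "tgfb": 0.15}


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_cohort(config: SimConfig, case_stream: int = 1) -> CohortBundle:
    """Draw one synthetic pan-cancer cohort under ``config``.

    The latent state per case is a responder flag (per-type Bernoulli rate)
    and an immune-hot/cold infiltration cluster: responders are hot with
    probability 1 - cluster_flip, non-responders with probability
    hot_background. ``truth['cluster']`` is 1 for hot (the low-hazard,
    responder-enriched group that the pipeline should relabel cluster 2).

    Probe- and gene-level parameters (baseline methylation, informative
    shift directions, signature archetypes, gene expression means) are
    drawn from a random stream keyed by the seed alone, while cases come
    from a stream keyed by (seed, case_stream): two cohorts with the same
    seed but different ``case_stream`` share the array design and assay
    behavior but contain independent patients (how an external validation
    cohort relates to a discovery cohort).
    """
    config.validate()
    rng_design = np.random.default_rng([config.seed, 11])
    rng = np.random.default_rng([config.seed, case_stream])

    # design-level draws (shared across case streams)
    baseline = rng_design.normal(0.0, 1.5, size=config.n_probes)
    direction = rng_design.choice([-1.0, 1.0], size=config.n_informative)
    archetypes = rng_design.beta(
        0.4, 0.4, size=(config.n_signature, config.n_cell_types)
    )
    log_mu = rng_design.normal(4.0, 1.0, size=config.n_genes)

    counts_per_type = config.counts_per_type()
    rates = config.rates()
    n_cases = int(counts_per_type.sum())
    types = [f"T{t + 1:02d}" for t in range(config.n_types)]
    tumor_type = np.repeat(types, counts_per_type)
    case_ids = pd.Index(
        [f"{tt}-{i:04d}" for tt, i in zip(tumor_type, range(n_cases))], name="case"
    )

    rate_per_case = np.repeat(rates, counts_per_type)
    responder = rng.random(n_cases) < rate_per_case
    p_hot = np.where(responder, 1.0 - config.cluster_flip, config.hot_background)
    cluster = (rng.random(n_cases) < p_hot).astype(int)  # 1 = immune hot

    # Continuous latent drivers: per-case mutation-rate multiplier (log-
    # normal around tmb_shift^responder) and TGF-beta pathway activity
    # (responders suppressed). Both feed expression/mutations AND a share
    # of the informative probes.
    mut_factor = np.where(responder, config.tmb_shift, 1.0) * np.exp(
        rng.normal(0.0, 0.4, size=n_cases)
    )
    z_mut = _standardize(np.log(mut_factor))
    tgfb_activity = -config.tgfb_shift * responder + rng.normal(
        0.0, 0.5 * config.tgfb_shift, size=n_cases
    )
    z_tgfb = _standardize(tgfb_activity)

    probe_ids = pd.Index([f"cg{i:08d}" for i in range(config.n_probes)], name="probe")
    signature_probes = list(probe_ids[: config.n_signature])
    informative_probes = list(
        probe_ids[config.n_signature : config.n_signature + config.n_informative]
    )

    # Methylation: per-probe baseline M plus noise; informative probes add
    # an effect_m-scaled shift driven by cluster, z_mut or z_tgfb.
    m = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(config.n_probes, n_cases))
    n_clu = int(round(INFORMATIVE_SPLIT["cluster"] * config.n_informative))
    n_tmb = int(round(INFORMATIVE_SPLIT["tmb"] * config.n_informative))
    driver = np.empty((config.n_informative, n_cases))
    driver[:n_clu] = cluster[None, :].astype(float)
    driver[n_clu : n_clu + n_tmb] = z_mut[None, :]
    driver[n_clu + n_tmb :] = z_tgfb[None, :]
    driver_names = pd.Series(
        ["cluster"] * n_clu + ["tmb"] * n_tmb
        + ["tgfb"] * (config.n_informative - n_clu - n_tmb),
        index=pd.Index(informative_probes, name="probe"),
    )
    info_slice = slice(config.n_signature, config.n_signature + config.n_informative)
    m[info_slice, :] += config.effect_m * direction[:, None] * driver
    beta = _clamp_beta(_m_to_beta(m))

    # Signature block: mixtures of cell-type methylation archetypes; the
    # CD8-like component (index 0) is concentrated in hot-cluster cases.
    alpha_base = np.full(config.n_cell_types, 6.0)
    fractions = np.empty((n_cases, config.n_cell_types))
    for c in range(n_cases):
        a = alpha_base.copy()
        a[0] = 3.0 + 12.0 * cluster[c] + 4.0 * responder[c]
        fractions[c] = rng.dirichlet(a)
    sig = archetypes @ fractions.T + rng.normal(0.0, 0.02, size=(config.n_signature, n_cases))
    beta[: config.n_signature, :] = _clamp_beta(sig)
    beta_df = pd.DataFrame(beta, index=probe_ids, columns=case_ids)

    # Expression: log2-scale gene means; TGF-beta pathway genes follow the
    # latent activity times their regulatory weight, checkpoint markers are
    # elevated in responders.
    gene_ids = pd.Index(_gene_names(config.n_genes), name="gene")
    shift = np.zeros((config.n_genes, n_cases))
    pathway_w = {g: w for g, w in TGFB_PATHWAY}
    for i, g in enumerate(gene_ids):
        if g in pathway_w:
            shift[i] = tgfb_activity * pathway_w[g]
        elif g in MARKER_GENES:
            shift[i] = config.marker_shift * responder
    size_factor = 2.0 ** rng.normal(0.0, 0.25, size=n_cases)
    mu = (2.0 ** (log_mu[:, None] + shift)) * size_factor[None, :]
    expr = _negative_binomial(rng, mu, config.dispersion)
    counts_df = pd.DataFrame(expr, index=gene_ids, columns=case_ids)

    # Mutations: Poisson truncation/non-truncation counts scaled by the
    # continuous mutation-rate factor; a sprinkle of Silent rows exercises
    # the TMB variant-class filter.
    n_trunc = rng.poisson(6.0 * mut_factor)
    n_nontrunc = rng.poisson(50.0 * mut_factor)
    n_silent = rng.poisson(4.0, size=n_cases)
    rows_case, rows_class = [], []
    for c in range(n_cases):
        k = n_trunc[c] + n_nontrunc[c] + n_silent[c]
        rows_case.append(np.repeat(case_ids[c], k))
        rows_class.append(
            np.concatenate([
                rng.choice(TRUNCATION_CLASSES, n_trunc[c]),
                rng.choice(NONTRUNCATION_CLASSES, n_nontrunc[c]),
                np.repeat("Silent", n_silent[c]),
            ])
        )
    all_cases = np.concatenate(rows_case)
    mutations = pd.DataFrame({
        "Tumor_Sample_Barcode": all_cases,
        "Hugo_Symbol": rng.choice(gene_ids.to_numpy(), all_cases.size),
        "Variant_Classification": np.concatenate(rows_class),
    })

    # Survival: exponential per type; the responder-enriched cluster has the
    # lower hazard; uniform administrative censoring.
    base_scale = 24.0 * 2.0 ** rng.normal(0.0, 0.3, size=config.n_types)
    scale_per_case = np.repeat(base_scale, counts_per_type)
    scale = np.where(cluster == 1, scale_per_case, scale_per_case / config.survival_hr)
    t_event = rng.exponential(scale)
    t_censor = rng.uniform(6.0, 60.0, size=n_cases)
    os_time = np.minimum(t_event, t_censor)
    os_event = (t_event <= t_censor).astype(int)
    clinical = pd.DataFrame(
        {"tumor_type": tumor_type, "os_time": os_time, "os_event": os_event},
        index=case_ids,
    )

    msi = rng.random(n_cases) < np.where(responder, 0.25, 0.05)
    truth = pd.DataFrame(
        {
            "responder": responder.astype(int),
            "cluster": cluster,
            "cd8_fraction": fractions[:, 0],
            "msi": msi.astype(int),
        },
        index=case_ids,
    )
    reference = pd.DataFrame(
        archetypes,
        index=pd.Index(signature_probes, name="probe"),
        columns=[f"cell{k}" for k in range(config.n_cell_types)],
    )

    return CohortBundle(
        beta=beta_df,
        counts=counts_df,
        mutations=mutations,
        clinical=clinical,
        truth=truth,
        informative_probes=informative_probes,
        signature_probes=signature_probes,
        reference=reference,
        probe_drivers=driver_names,
    )


def generate_external_cohort(
    config: SimConfig, probe_overlap_fraction: float
) -> CohortBundle:
    """An independent validation cohort on a partially different probe set.

    Emulates a cohort profiled on a different methylation chip: only
    ``round(probe_overlap_fraction * n_probes)`` probe IDs are shared with
    the reference design (the rest are renamed to chip-specific IDs while
    keeping their generative role). The clinical table gains a binary
    ``response`` column (the latent responder flag, i.e. measured clinical
    benefit) plus progression-free survival ``pfs_time``/``pfs_event``.
    """
    if not 0 < probe_overlap_fraction <= 1:
        raise ConfigError("probe_overlap_fraction must lie in (0, 1]")
    bundle = generate_cohort(config, case_stream=2)  # same design, new patients
    rng = np.random.default_rng([config.seed, 850])

    n_shared = int(round(probe_overlap_fraction * config.n_probes))
    keep = np.zeros(config.n_probes, dtype=bool)
    keep[rng.choice(config.n_probes, size=n_shared, replace=False)] = True
    new_ids = [
        pid if k else f"ext_{pid}" for pid, k in zip(bundle.beta.index, keep)
    ]
    renamed = dict(zip(bundle.beta.index, new_ids))
    bundle.beta.index = pd.Index(new_ids, name="probe")
    bundle.signature_probes = [renamed[p] for p in bundle.signature_probes]
    bundle.informative_probes = [renamed[p] for p in bundle.informative_probes]
    if bundle.reference is not None:
        bundle.reference.index = pd.Index(
            [renamed[p] for p in bundle.reference.index], name="probe"
        )
    if bundle.probe_drivers is not None:
        bundle.probe_drivers.index = pd.Index(
            [renamed[p] for p in bundle.probe_drivers.index], name="probe"
        )

    responder = bundle.truth["responder"].to_numpy().astype(bool)
    pfs_scale = np.where(responder, 18.0, 8.0)
    t_event = rng.exponential(pfs_scale)
    t_censor = rng.uniform(3.0, 30.0, size=len(responder))
    bundle.clinical = bundle.clinical.assign(
        response=responder.astype(int),
        pfs_time=np.minimum(t_event, t_censor),
        pfs_event=(t_event <= t_censor).astype(int),
    )
    return bundle
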