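"""Immune-infiltration representation, two-cluster partition, indicator tests.

Each case's methylation profile over a signature probe set is deconvolved
against reference cell-type methylation archetypes by constrained least
squares (fractions nonnegative, summing to at most one). Within each tumor
type, cases are partitioned into two groups by PAM (partitioning around
medoids, k = 2, Euclidean distance on fraction vectors); the group with the
longer mean observed survival time is called cluster 2, so cluster identity
is comparable across tumor types.

Three per-type indicator tests then ask whether the two infiltration
clusters differ in known correlates of checkpoint-inhibitor benefit:
overall survival (log-rank), tumor mutation burden (Mann-Whitney U) and
PD-L1/CD274 expression (taken from the differential-expression results
between clusters). Per indicator, p-values are BH-adjusted ACROSS tumor
types, and types passing FDR < 0.01 gate the downstream feature voting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls
from scipy.stats import mannwhitneyu
from lifelines.statistics import logrank_test

from icimeth.diffstats import bh_adjust, differential_expression
from icimeth.labeling import MutationSummary

logger = logging.getLogger(__name__)

PDL1_GENE = "CD274"
INDICATORS = ("OS", "TMB", "PDL1")


@dataclass
class DeconvolutionResult:
    """Estimated immune-cell-type fractions per case (rows) and fit residuals."""

    fractions: pd.DataFrame
    residual: pd.Series


@dataclass
class ClusterAssignment:
    """A two-cluster partition of one tumor type's cases.

    ``assignment`` maps case -> {1, 2} with cluster 2 the longer-mean-OS
    group; ``indicators`` is filled by :func:`indicator_tests`.
    """

    tumor_type: str
    assignment: pd.Series
    medoids: tuple[str, str]
    indicators: pd.DataFrame | None = field(default=None)


def _solve_fractions(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||R f - b|| subject to f >= 0 and sum(f) <= 1.

    NNLS gives the optimum of the relaxed problem; only when its solution
    violates the simplex bound is the sum(f) = 1 face re-solved exactly.
    """
    f, _ = nnls(R, b)
    total = f.sum()
    if total <= 1.0 + 1e-9:
        return f
    x0 = f / total
    res = minimize(
        lambda x: 0.5 * np.sum((R @ x - b) ** 2),
        x0,
        jac=lambda x: R.T @ (R @ x - b),
        bounds=[(0.0, None)] * R.shape[1],
        constraints=[{"type": "eq", "fun": lambda x: x.sum() - 1.0,
                      "jac": lambda x: np.ones_like(x)}],
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    return np.maximum(res.x, 0.0)


def deconvolve(meth_beta: pd.DataFrame, reference: pd.DataFrame) -> DeconvolutionResult:
    """Project each case's signature-probe beta vector onto reference profiles.

    Parameters
    ----------
    meth_beta
        probes x cases beta matrix (any probe superset of the reference).
    reference
        signature probes x cell types beta archetypes.
    """
    shared = reference.index.intersection(meth_beta.index)
    if len(shared) == 0:
        raise ValueError("no signature probe shared with the reference")
    R = reference.loc[shared].to_numpy(dtype=float)
    B = meth_beta.loc[shared].to_numpy(dtype=float)

    if np.linalg.matrix_rank(R) < R.shape[1]:
        logger.warning("rank-deficient reference; applying ridge stabilization")
        lam = 1e-6
        R = np.vstack([R, np.sqrt(lam) * np.eye(R.shape[1])])
        B = np.vstack([B, np.zeros((R.shape[1], B.shape[1]))])

    fracs = np.empty((B.shape[1], R.shape[1]))
    resid = np.empty(B.shape[1])
    for j in range(B.shape[1]):
        fracs[j] = _solve_fractions(R, B[:, j])
        resid[j] = float(np.linalg.norm(R @ fracs[j] - B[:, j]))
    return DeconvolutionResult(
        fractions=pd.DataFrame(fracs, index=meth_beta.columns, columns=reference.columns),
        residual=pd.Series(resid, index=meth_beta.columns),
    )


def _pam_two(X: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """PAM (BUILD + SWAP) with k = 2 on Euclidean distances. Deterministic."""
    n = X.shape[0]
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    # BUILD: first medoid minimizes total distance; second maximizes gain.
    m1 = int(np.argmin(D.sum(axis=1)))
    gain = np.sum(np.maximum(D[:, m1][None, :] - D, 0.0), axis=1)
    gain[m1] = -np.inf
    m2 = int(np.argmax(gain))
    medoids = [m1, m2]

    def cost(meds):
        return float(np.minimum(D[:, meds[0]], D[:, meds[1]]).sum())

    best = cost(medoids)
    improved = True
    while improved:
        improved = False
        for i in range(2):
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[i] = h
                c = cost(trial)
                if c < best - 1e-12:
                    best, medoids, improved = c, trial, True
    labels = (D[:, medoids[1]] < D[:, medoids[0]]).astype(int)
    labels[medoids[0]] = 0
    labels[medoids[1]] = 1
    return labels, (medoids[0], medoids[1])


def cluster_two(
    fractions: DeconvolutionResult | pd.DataFrame,
    clinical: pd.DataFrame,
    tumor_type: str = "",
) -> ClusterAssignment:
    """Two-cluster PAM partition, relabeled so cluster 2 outlives cluster 1.

    "Longer survival" is the larger mean of observed OS times (censoring
    ignored); the rule is idempotent and makes cluster 2 the putative
    immune-favorable group in every tumor type.
    """
    F = fractions.fractions if isinstance(fractions, DeconvolutionResult) else fractions
    cases = F.index
    if len(cases) < 4:
        raise ValueError("need at least 4 cases to cluster")
    X = F.to_numpy(dtype=float)
    if np.allclose(X, X[0], atol=1e-12):
        raise ValueError("degenerate clustering: all fraction vectors identical")

    raw, med_idx = _pam_two(X)
    os_time = clinical.loc[cases, "os_time"].to_numpy(dtype=float)
    mean0 = os_time[raw == 0].mean()
    mean1 = os_time[raw == 1].mean()
    # cluster 2 = longer mean observed survival
    if mean1 >= mean0:
        labels = np.where(raw == 1, 2, 1)
        medoids = (cases[med_idx[0]], cases[med_idx[1]])
    else:
        labels = np.where(raw == 0, 2, 1)
        medoids = (cases[med_idx[1]], cases[med_idx[0]])
    return ClusterAssignment(
        tumor_type=tumor_type,
        assignment=pd.Series(labels, index=cases, name="cluster"),
        medoids=(str(medoids[0]), str(medoids[1])),
    )


def cluster_all_types(
    beta: pd.DataFrame, reference: pd.DataFrame, clinical: pd.DataFrame
) -> dict[str, ClusterAssignment]:
    """Deconvolve once, then PAM-partition each tumor type separately."""
    decon = deconvolve(beta, reference)
    out: dict[str, ClusterAssignment] = {}
    for tt, sub in clinical.groupby("tumor_type", sort=True):
        frac = decon.fractions.loc[sub.index]
        out[tt] = cluster_two(frac, clinical, tumor_type=str(tt))
    return out


def _logrank_p(os_time, os_event, groups) -> float:
    g = np.asarray(groups)
    try:
        res = logrank_test(
            os_time[g == 1], os_time[g == 2],
            event_observed_A=os_event[g == 1], event_observed_B=os_event[g == 2],
        )
        p = float(res.p_value)
    except Exception:  # degenerate strata
        p = np.nan
    if not np.isfinite(p):
        logger.warning("log-rank undefined; reporting p = 1")
        return 1.0
    return p


def indicator_tests(
    assignments: Mapping[str, ClusterAssignment],
    tmb: MutationSummary,
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Test OS, TMB and PD-L1 differences between clusters per tumor type.

    Returns a long table (tumor_type, indicator, p, direction, fdr,
    significant); FDR is BH-adjusted across tumor types within each
    indicator. ``direction`` is +1 when the quantity is higher in cluster 2.
    Each :class:`ClusterAssignment` also receives its rows in
    ``.indicators``.
    """
    rows = []
    for tt, asg in assignments.items():
        cases = asg.assignment.index
        g = asg.assignment.to_numpy()
        os_time = clinical.loc[cases, "os_time"].to_numpy(dtype=float)
        os_event = clinical.loc[cases, "os_event"].to_numpy(dtype=int)
        p_os = _logrank_p(os_time, os_event, g)
        d_os = 1 if os_time[g == 2].mean() >= os_time[g == 1].mean() else -1

        t = tmb.tmb.loc[cases].to_numpy(dtype=float)
        try:
            p_tmb = float(mannwhitneyu(t[g == 2], t[g == 1], alternative="two-sided").pvalue)
        except ValueError:  # all values identical
            p_tmb = 1.0
        d_tmb = 1 if np.median(t[g == 2]) >= np.median(t[g == 1]) else -1

        de = differential_expression(expression[cases], (g == 2).astype(int))
        if PDL1_GENE in de.table.index:
            row = de.table.loc[PDL1_GENE]
            p_pdl1, d_pdl1 = float(row["p"]), int(row["direction"]) or 1
        else:
            logger.warning("%s absent from expression matrix for %s", PDL1_GENE, tt)
            p_pdl1, d_pdl1 = 1.0, 1

        rows += [
            {"tumor_type": tt, "indicator": "OS", "p": p_os, "direction": d_os},
            {"tumor_type": tt, "indicator": "TMB", "p": p_tmb, "direction": d_tmb},
            {"tumor_type": tt, "indicator": "PDL1", "p": p_pdl1, "direction": d_pdl1},
        ]

    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    for ind in INDICATORS:
        mask = table["indicator"] == ind
        table.loc[mask, "fdr"] = bh_adjust(table.loc[mask, "p"].to_numpy())
    table["significant"] = table["fdr"] < fdr_threshold

    for tt, asg in assignments.items():
        asg.indicators = table[table["tumor_type"] == tt].reset_index(drop=True)
    return table


def significant_types(indicator_table: pd.DataFrame, indicator: str) -> list[str]:
    """Tumor types where ``indicator`` passed the cross-type FDR gate."""
    sel = indicator_table[
        (indicator_table["indicator"] == indicator) & indicator_table["significant"]
    ]
    return sorted(sel["tumor_type"].tolist())
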