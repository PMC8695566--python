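"""Differential methylation and expression statistics.

Methylation beta values are logit-transformed to M-values
(M = log2(beta / (1 - beta))), which stabilizes variance and makes the
|logFC| > 1 calling threshold mean a two-fold change in methylation odds.
Two-group testing uses an empirical-Bayes moderated t: per-feature residual
variances are shrunk toward a pooled prior (s0^2, d0) estimated by moment
matching on the log residual variances, and p-values come from a t
distribution with d0 + df degrees of freedom. This is the standard
microarray-style shrinkage estimator; with thousands of features and small
groups it dominates the per-feature t-test.

Differential expression applies the same moderated test to
log2(median-of-ratios-normalized counts + 1); the pipeline only consumes
(logFC, adjusted p, direction), so the heavier count-model machinery is
deliberately not reproduced here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats, optimize
from statsmodels.stats.multitest import multipletests


@dataclass
class DifferentialResult:
    """Per-feature two-group differential test results.

    ``table`` columns: logFC (group2 mean minus group1 mean), t (moderated),
    p, adj_p (Benjamini-Hochberg), direction (+1/-1, sign of logFC);
    ``d0``/``s0_sq`` are the empirical-Bayes prior degrees of freedom and
    prior variance, ``df`` the residual degrees of freedom. ``untested``
    lists features excluded before testing (all-zero genes).
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    df: int
    untested: list[str]


def beta_to_m(beta):
    """Logit-transform methylation beta values: M = log2(beta / (1 - beta))."""
    arr = np.asarray(beta, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("beta values must lie strictly inside (0, 1)")
    out = np.log2(arr / (1.0 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    return out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    arr = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + 2.0 ** (-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(out, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(out, index=m.index)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fit_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log residual variances.

    Uses the classic result that log s^2 ~ log(sigma^2) + log chi^2_df / df,
    whose mean and variance involve digamma/trigamma at df/2; the excess
    variance of the observed log s^2 over trigamma(df/2) identifies
    trigamma(d0/2). No finite solution (under-dispersed variances) means
    complete shrinkage: d0 = inf, s0^2 = mean variance.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_var = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if e_var <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    # invert trigamma(d0/2) = e_var
    sol = optimize.brentq(
        lambda x: special.polygamma(1, x) - e_var, 1e-6, 1e8, xtol=1e-10
    )
    d0 = 2.0 * sol
    s0_sq = float(np.exp(np.mean(e) + special.digamma(sol) - np.log(sol)))
    return d0, s0_sq


def moderated_t(matrix, groups, d0_override: float | None = None) -> DifferentialResult:
    """Empirical-Bayes moderated two-group t-test per feature (row).

    Parameters
    ----------
    matrix
        features x cases array or DataFrame (M-values or log expression).
    groups
        Binary assignment per case; logFC is mean(group 1) - mean(group 0),
        i.e. positive direction = higher in group 1.
    d0_override
        Force the prior degrees of freedom (0 disables shrinkage and
        recovers the ordinary pooled t; inf gives complete shrinkage).
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(X.shape[0])
    g = np.asarray(groups).astype(int)
    if set(np.unique(g)) - {0, 1}:
        raise ValueError("groups must be binary 0/1")
    n1, n2 = int((g == 0).sum()), int((g == 1).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 cases per group")

    x1, x2 = X[:, g == 0], X[:, g == 1]
    logfc = x2.mean(axis=1) - x1.mean(axis=1)
    df = n1 + n2 - 2
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df

    d0, s0_sq = _fit_prior(s2, df) if d0_override is None else (d0_override, float(np.mean(s2)))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(se > 0, p, 1.0)  # constant features: no evidence

    table = pd.DataFrame(
        {
            "logFC": logfc,
            "t": t,
            "p": p,
            "adj_p": bh_adjust(p),
            "direction": np.sign(logfc).astype(int),
        },
        index=index,
    )
    return DifferentialResult(table=table, d0=float(d0), s0_sq=float(s0_sq), df=df, untested=[])


def call_dmps(
    result: DifferentialResult, lfc_threshold: float = 1.0, p_threshold: float = 0.01
) -> set[tuple[str, int]]:
    """Differentially methylated probes: |logFC| > lfc AND adj_p < p, strictly."""
    t = result.table
    hit = (t["logFC"].abs() > lfc_threshold) & (t["adj_p"] < p_threshold)
    return {(probe, int(d)) for probe, d in zip(t.index[hit], t.loc[hit, "direction"])}


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios library-size normalization (DESeq-style size factors).

    Size factors are the per-case median ratio to the geometric-mean
    reference gene, computed over genes expressed in every case; falls back
    to total-count scaling when no gene qualifies.
    """
    X = counts.to_numpy(dtype=float)
    positive = (X > 0).all(axis=1)
    if positive.sum() >= 1:
        log_ref = np.log(X[positive]).mean(axis=1)
        sf = np.exp(np.median(np.log(X[positive]) - log_ref[:, None], axis=0))
    else:
        totals = X.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    return pd.DataFrame(X / sf[None, :], index=counts.index, columns=counts.columns)


def differential_expression(counts: pd.DataFrame, groups) -> DifferentialResult:
    """Two-group differential expression on RNA-seq counts.

    Counts are median-of-ratios normalized, transformed to
    log2(normalized + 1) and passed through :func:`moderated_t`; logFC is
    therefore on the log2 expression scale. Genes with zero counts in every
    case are excluded and reported in ``untested``.
    """
    X = counts.to_numpy()
    if np.any(X < 0):
        raise ValueError("counts must be nonnegative")
    nonzero = counts.index[(X > 0).any(axis=1)]
    untested = [g for g in counts.index if g not in set(nonzero)]
    norm = normalize_counts(counts.loc[nonzero])
    logx = np.log2(norm + 1.0)
    res = moderated_t(logx, groups)
    res.untested = untested
    return res


def call_degs(
    result: DifferentialResult, lfc_threshold: float = 1.0, p_threshold: float = 0.01
) -> set[tuple[str, int]]:
    """Differentially expressed genes under the |log2FC| > 1, adj_p < 0.01 rule."""
    return call_dmps(result, lfc_threshold, p_threshold)
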