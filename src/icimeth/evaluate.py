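"""Evaluation battery: repeated splits, null controls, biomarker checks.

Model performance is summarized by F1, the Matthews correlation coefficient
(MCC) and ROC AUC (when decision scores exist), averaged over repeated
stratified 80/20 train/test splits. The battery around it probes whether
the performance is real: random probe sets of the same size, label
permutations (with a "total random" analytic baseline), separation of
held-out biomarkers (PD-1, CTLA4, CD8+ fraction, MSI) between predicted
groups, per-tumor-type metrics with a predicted-vs-true positive-proportion
Spearman correlation, a dendrogram-adjacency chi-square dependence test,
external-cohort application after probe intersection, and a combined
methylation + expression model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.metrics import f1_score, matthews_corrcoef, roc_auc_score
from sklearn.model_selection import train_test_split
from lifelines.statistics import logrank_test

from icimeth.diffstats import beta_to_m, normalize_counts
from icimeth.features import FeatureSet
from icimeth.models import (
    DEFAULT_LAMBDA_GRID, SVMConfig, TrainedModel, grid_search_cv,
    train_comparators, train_svm,
)
from icimeth.simulate import CohortBundle

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics

def metrics(y_true, y_pred, scores=None) -> dict[str, float | None]:
    """F1, MCC and (when scores are given) ROC AUC.

    MCC is 0 whenever a contingency marginal is zero; AUC is None when
    ``y_true`` has a single class.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    out = {
        "f1": float(f1_score(y_true, y_pred, zero_division=0)),
        "mcc": float(matthews_corrcoef(y_true, y_pred)),
        "auc": None,
    }
    if scores is not None and len(np.unique(y_true)) == 2:
        out["auc"] = float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))
    return out


def feature_matrix(bundle: CohortBundle, feature_set: FeatureSet | Sequence[str]) -> pd.DataFrame:
    """Cases x probes M-value matrix restricted to the selected probes."""
    probes = feature_set.probes if isinstance(feature_set, FeatureSet) else list(feature_set)
    missing = [p for p in probes if p not in bundle.beta.index]
    if missing:
        raise KeyError(f"{len(missing)} selected probes absent from the beta matrix")
    return beta_to_m(bundle.beta.loc[probes]).T


# ---------------------------------------------------------------------------
# repeated-split evaluation

@dataclass
class EvaluationReport:
    """Per-split metrics plus per-case test-set predictions per model."""

    per_split: pd.DataFrame          # columns: split, model, f1, mcc, auc
    predictions: dict[str, list[pd.Series]]
    scores: dict[str, list[pd.Series | None]]
    config: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Mean and normal-theory 95% CI per model and metric."""
        rows = []
        for model, grp in self.per_split.groupby("model"):
            for metric in ("f1", "mcc", "auc"):
                vals = grp[metric].dropna().to_numpy(dtype=float)
                if vals.size == 0:
                    continue
                mean = float(vals.mean())
                half = 1.96 * vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
                rows.append({"model": model, "metric": metric, "mean": mean,
                             "ci_low": mean - half, "ci_high": mean + half,
                             "n_splits": int(vals.size)})
        return pd.DataFrame(rows)

    def metric_vector(self, model: str, metric: str) -> np.ndarray:
        sub = self.per_split[self.per_split["model"] == model]
        return sub.sort_values("split")[metric].to_numpy(dtype=float)

    def paired_tests(self, model_a: str, model_b: str, metric: str) -> dict[str, float]:
        """Paired t-test and Wilcoxon signed-rank on per-split metric vectors."""
        a = self.metric_vector(model_a, metric)
        b = self.metric_vector(model_b, metric)
        t_p = float(stats.ttest_rel(a, b).pvalue)
        if np.allclose(a, b):
            w_p = 1.0
        else:
            w_p = float(stats.wilcoxon(a, b).pvalue)
        return {"t_p": t_p, "wilcoxon_p": w_p,
                "mean_diff": float(np.mean(a) - np.mean(b))}


def _stratified_split(y: np.ndarray, test_frac: float, seed: int, stratify: bool):
    idx = np.arange(len(y))
    for attempt in range(20):
        tr, te = train_test_split(
            idx, test_size=test_frac, random_state=seed + 1000 * attempt,
            stratify=y if stratify else None, shuffle=True,
        )
        if y[te].sum() > 0 and y[tr].sum() > 0:
            if attempt:
                logger.warning("resampled split %d time(s) to get test positives", attempt)
            return tr, te
    raise ValueError("could not draw a split containing positive cases")


def repeated_split_eval(
    X: pd.DataFrame,
    y,
    models: Sequence[str] = ("SVM",),
    n_splits: int = 100,
    test_frac: float = 0.2,
    seed: int = 0,
    lam: float | None = None,
    lam_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    refit_lambda: bool = False,
    standardize: bool = False,
    stratify: bool = True,
    folds: int = 5,
    extra_predictions: Mapping[str, pd.Series] | None = None,
) -> EvaluationReport:
    """Train and test each model on ``n_splits`` stratified 80/20 splits.

    ``lam`` fixes the SVM kernel multiplier; when None it is selected once
    by 5-fold CV on the full data (the single-tuning protocol) unless
    ``refit_lambda`` re-runs the grid search inside every training split.
    ``standardize`` z-scores each feature on the training split and applies
    the training moments to the test split (used by the combined model).
    ``extra_predictions`` are fixed per-case label vectors (e.g. the naive
    cluster-TMB predictor) evaluated on each split's test cases.
    """
    y = pd.Series(np.asarray(y).astype(int), index=X.index)
    yv = y.to_numpy()
    if lam is None and "SVM" in models and not refit_lambda:
        lam = grid_search_cv(X, yv, grid=lam_grid, folds=folds, seed=seed).lam
        logger.info("selected lambda = %g by full-data CV", lam)

    comparator_kinds = [m for m in models if m in ("LR_L1", "RF", "kNN")]
    records = []
    predictions: dict[str, list[pd.Series]] = {m: [] for m in models}
    scorelists: dict[str, list[pd.Series | None]] = {m: [] for m in models}
    if extra_predictions:
        for name in extra_predictions:
            predictions[name] = []
            scorelists[name] = []

    for split in range(n_splits):
        split_seed = seed + 7919 * (split + 1)
        tr, te = _stratified_split(yv, test_frac, split_seed, stratify)
        X_tr, X_te = X.iloc[tr], X.iloc[te]
        y_tr, y_te = yv[tr], yv[te]
        if standardize:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0, ddof=0).replace(0, 1.0)
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd

        fitted: dict[str, TrainedModel] = {}
        if "SVM" in models:
            use_lam = lam
            if refit_lambda:
                use_lam = grid_search_cv(
                    X_tr, y_tr, grid=lam_grid, folds=folds, seed=split_seed
                ).lam
            fitted["SVM"] = train_svm(X_tr, y_tr, SVMConfig(lam=use_lam, seed=split_seed))
        if comparator_kinds:
            comp = train_comparators(X_tr, y_tr, seed=split_seed, folds=folds)
            fitted.update({k: v for k, v in comp.items() if k in comparator_kinds})

        for name, model in fitted.items():
            pred = model.predict(X_te)
            sc = model.decision_scores(X_te)
            m = metrics(y_te, pred, sc)
            records.append({"split": split, "model": name, **m})
            predictions[name].append(pd.Series(pred, index=X_te.index))
            scorelists[name].append(
                pd.Series(sc, index=X_te.index) if sc is not None else None
            )
        if extra_predictions:
            for name, full_pred in extra_predictions.items():
                pred = full_pred.loc[X_te.index].to_numpy()
                m = metrics(y_te, pred, None)
                records.append({"split": split, "model": name, **m})
                predictions[name].append(pd.Series(pred, index=X_te.index))
                scorelists[name].append(None)

    return EvaluationReport(
        per_split=pd.DataFrame(records),
        predictions=predictions,
        scores=scorelists,
        config={"n_splits": n_splits, "test_frac": test_frac, "seed": seed,
                "lam": lam, "refit_lambda": refit_lambda,
                "standardize": standardize, "stratify": stratify},
    )


# ---------------------------------------------------------------------------
# null controls

def random_probe_control(
    bundle: CohortBundle,
    feature_set: FeatureSet | Sequence[str],
    y,
    n_controls: int = 100,
    n_splits: int = 2,
    seed: int = 0,
    lam: float = 13.0,
) -> pd.DataFrame:
    """Compare the selected probes against equal-sized random probe sets.

    Every control draws uniformly from the full probe universe and runs the
    identical SVM train/eval protocol (fixed lambda) on the same split
    seeds. Returns one row per control with the control's and the true
    set's mean F1/MCC and win flags.
    """
    probes = feature_set.probes if isinstance(feature_set, FeatureSet) else list(feature_set)
    universe = bundle.beta.index.to_numpy()
    if len(universe) <= len(probes):
        raise ValueError("probe universe not larger than the feature set")
    rng = np.random.default_rng(seed)

    def _mean_metrics(probe_list, eval_seed):
        X = feature_matrix(bundle, probe_list)
        rep = repeated_split_eval(
            X, y, models=("SVM",), n_splits=n_splits, seed=eval_seed, lam=lam,
        )
        agg = rep.aggregate().set_index("metric")["mean"]
        return float(agg["f1"]), float(agg["mcc"])

    # Each comparison is paired: the true set is re-evaluated on the SAME
    # split seeds as its control, so under a no-signal null the win
    # indicator is an exchangeable coin flip (ties score 1/2).
    rows = []
    for c in range(n_controls):
        ctrl = list(rng.choice(universe, size=len(probes), replace=False))
        pair_seed = seed + 65537 * (c + 1)
        true_f1, true_mcc = _mean_metrics(probes, pair_seed)
        f1c, mccc = _mean_metrics(ctrl, pair_seed)
        rows.append({
            "control": c, "control_f1": f1c, "control_mcc": mccc,
            "true_f1": true_f1, "true_mcc": true_mcc,
            "win_f1": (true_f1 > f1c) + 0.5 * (true_f1 == f1c),
            "win_mcc": (true_mcc > mccc) + 0.5 * (true_mcc == mccc),
        })
    return pd.DataFrame(rows)


def expected_random_f1(prevalence: float) -> float:
    """Closed-form F1 of an independent random predictor at rate p.

    If predictions are positive with the same probability p as the truth
    and independent of it, precision = recall = p, so F1 = p.
    """
    return float(prevalence)


def permutation_null(
    X: pd.DataFrame,
    y,
    n_perm: int = 100,
    n_splits: int = 1,
    seed: int = 0,
    lam: float = 13.0,
) -> pd.DataFrame:
    """Retrain on label permutations; report the trained and total-random nulls.

    "Predicted random" rows give the SVM's test metrics after the labels
    were shuffled; "total random" rows compare the labels directly with an
    independent shuffle (no model), whose expected F1 equals the positive
    prevalence.
    """
    y = pd.Series(np.asarray(y).astype(int), index=X.index)
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_perm):
        perm = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
        rep = repeated_split_eval(
            X, perm, models=("SVM",), n_splits=n_splits,
            seed=seed + 13 * (b + 1), lam=lam,
        )
        agg = rep.aggregate().set_index("metric")["mean"]
        shuffled = rng.permutation(y.to_numpy())
        direct = metrics(y.to_numpy(), shuffled)
        rows.append({
            "perm": b,
            "model_f1": float(agg["f1"]), "model_mcc": float(agg["mcc"]),
            "total_random_f1": direct["f1"], "total_random_mcc": direct["mcc"],
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# biomarker separation and per-type metrics

def biomarker_separation(bundle: CohortBundle, report: EvaluationReport,
                         model: str = "SVM") -> pd.DataFrame:
    """Do held-out biomarkers separate predicted-positive from negative cases?

    Per test split, the mean of each biomarker is computed in the predicted
    positive and negative groups; the per-split means are then compared
    across splits (Mann-Whitney U for PD-1/CTLA4 expression, t-test for the
    CD8+ fraction and the MSI-unstable proportion). Splits where either
    predicted group is empty are skipped for that biomarker.
    """
    if bundle.truth is None:
        raise ValueError("biomarker separation needs the synthetic truth table")
    logexpr = np.log2(normalize_counts(bundle.counts) + 1.0)
    markers = {
        "PDCD1": ("mwu", logexpr.loc["PDCD1"]),
        "CTLA4": ("mwu", logexpr.loc["CTLA4"]),
        "CD8_fraction": ("ttest", bundle.truth["cd8_fraction"]),
        "MSI_proportion": ("ttest", bundle.truth["msi"].astype(float)),
    }
    per_split_means: dict[str, list[tuple[float, float]]] = {k: [] for k in markers}
    for pred in report.predictions[model]:
        pos = pred.index[pred == 1]
        neg = pred.index[pred == 0]
        if len(pos) == 0 or len(neg) == 0:
            continue
        for name, (_, values) in markers.items():
            per_split_means[name].append(
                (float(values.loc[pos].mean()), float(values.loc[neg].mean()))
            )

    rows = []
    for name, (test, _) in markers.items():
        pairs = per_split_means[name]
        if len(pairs) < 3:
            rows.append({"biomarker": name, "p": np.nan,
                         "mean_positive": np.nan, "mean_negative": np.nan,
                         "n_splits": len(pairs)})
            continue
        a = np.array([p for p, _ in pairs])
        b = np.array([n for _, n in pairs])
        if np.allclose(a, b):
            p = 1.0
        elif test == "mwu":
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        else:
            p = float(stats.ttest_rel(a, b).pvalue)
        rows.append({"biomarker": name, "p": p,
                     "mean_positive": float(a.mean()),
                     "mean_negative": float(b.mean()),
                     "n_splits": len(pairs)})
    return pd.DataFrame(rows)


def per_type_eval(
    report: EvaluationReport,
    clinical: pd.DataFrame,
    y: pd.Series,
    model: str = "SVM",
    min_pos_frac: float = 0.05,
    min_pos: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tumor-type metrics and predicted-vs-true proportion correlation.

    Qualifying tumor types have more than ``min_pos_frac`` of cases and
    more than ``min_pos`` cases labeled positive in the full cohort. The
    second return value holds one Spearman rho per split between the
    predicted and true positive proportions over qualifying types present
    in that split's test set (NaN when fewer than 3 types are present).
    """
    y = pd.Series(y).astype(int)
    types = clinical["tumor_type"]
    pos_by_type = y.groupby(types).sum()
    n_by_type = types.value_counts()
    qualifying = sorted(
        tt for tt in n_by_type.index
        if pos_by_type.get(tt, 0) > min_pos and
        pos_by_type.get(tt, 0) / n_by_type[tt] > min_pos_frac
    )
    if not qualifying:
        logger.warning("no tumor type passes the per-type evaluation gate")
        return pd.DataFrame(), pd.DataFrame()

    rows, rho_rows = [], []
    for split, pred in enumerate(report.predictions[model]):
        test_types = types.loc[pred.index]
        true_props, pred_props = [], []
        for tt in qualifying:
            cases = pred.index[test_types == tt]
            if len(cases) == 0:
                continue
            yt = y.loc[cases].to_numpy()
            yp = pred.loc[cases].to_numpy()
            m = metrics(yt, yp) if len(np.unique(yt)) > 1 else {
                "f1": float(f1_score(yt, yp, zero_division=0)), "mcc": np.nan, "auc": None}
            rows.append({"split": split, "tumor_type": tt,
                         "f1": m["f1"], "mcc": m["mcc"],
                         "true_prop": float(yt.mean()), "pred_prop": float(yp.mean())})
            true_props.append(float(yt.mean()))
            pred_props.append(float(yp.mean()))
        if len(true_props) >= 3 and len(set(true_props)) > 1 and len(set(pred_props)) > 1:
            rho = float(stats.spearmanr(true_props, pred_props).statistic)
        else:
            rho = np.nan
        rho_rows.append({"split": split, "spearman_rho": rho,
                         "n_types": len(true_props)})
    return pd.DataFrame(rows), pd.DataFrame(rho_rows)


# ---------------------------------------------------------------------------
# dendrogram adjacency

def dendrogram_adjacency_test(meth_m: pd.DataFrame, labels) -> dict:
    """Chi-square dependence of neighboring cases' labels along a dendrogram.

    Cases are ordered by average-linkage Euclidean hierarchical clustering
    of their M-value profiles (``meth_m`` is probes x cases); consecutive
    leaf pairs form a 2x2 contingency of (label_i, label_{i+1}).
    """
    y = pd.Series(labels).astype(int)
    cases = meth_m.columns
    if len(cases) < 3:
        raise ValueError("need at least 3 cases")
    if y.loc[cases].nunique() < 2:
        return {"chi2": np.nan, "p": np.nan, "table": None}
    Z = hierarchy.linkage(meth_m.T.to_numpy(dtype=float), method="average",
                          metric="euclidean")
    order = hierarchy.leaves_list(Z)
    seq = y.loc[cases[order]].to_numpy()
    table = np.zeros((2, 2))
    for a, b in zip(seq[:-1], seq[1:]):
        table[a, b] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi2, p = np.nan, np.nan
    else:
        chi2, p = stats.chi2_contingency(table)[:2]
    return {"chi2": float(chi2), "p": float(p), "table": table}


# ---------------------------------------------------------------------------
# external cohort and combined model

def apply_external(
    feature_set: FeatureSet | Sequence[str],
    training_bundle: CohortBundle,
    training_labels,
    external_bundle: CohortBundle,
    lam: float = 13.0,
    seed: int = 0,
) -> dict:
    """Retrain on the probe intersection and score the external cohort.

    The feature set is intersected with the external chip's probes, the SVM
    is retrained on the training cohort restricted to that intersection and
    applied to the external cases; metrics are computed against the
    external clinical ``response`` column, and progression-free survival is
    compared between predicted groups by log-rank.
    """
    probes = feature_set.probes if isinstance(feature_set, FeatureSet) else list(feature_set)
    shared = [p for p in probes if p in external_bundle.beta.index]
    if not shared:
        raise ValueError("no selected probe exists on the external chip")

    X_tr = feature_matrix(training_bundle, shared)
    model = train_svm(X_tr, np.asarray(training_labels).astype(int),
                      SVMConfig(lam=lam, seed=seed))
    X_ext = feature_matrix(external_bundle, shared)
    pred = model.predict(X_ext)
    scores = model.decision_scores(X_ext)
    y_ext = external_bundle.clinical["response"].to_numpy().astype(int)
    m = metrics(y_ext, pred, scores)

    clin = external_bundle.clinical
    pos, neg = pred == 1, pred == 0
    if pos.any() and neg.any():
        lr = logrank_test(
            clin.loc[pos, "pfs_time"], clin.loc[neg, "pfs_time"],
            event_observed_A=clin.loc[pos, "pfs_event"],
            event_observed_B=clin.loc[neg, "pfs_event"],
        )
        pfs_p = float(lr.p_value)
    else:
        pfs_p = np.nan
    return {"n_shared_probes": len(shared), "metrics": m,
            "pfs_logrank_p": pfs_p,
            "predictions": pd.Series(pred, index=clin.index)}


def combined_model_eval(
    bundle: CohortBundle,
    meth_features: FeatureSet | Sequence[str],
    expr_genes: Sequence[str],
    labels,
    n_splits: int = 100,
    seed: int = 0,
    lam: float | None = None,
) -> dict[str, EvaluationReport]:
    """Methylation-only, expression-only and combined SVMs on shared splits.

    Blocks are concatenated after per-feature (hence per-block)
    standardization fitted on each training split. Feature IDs must not
    collide across blocks.
    """
    X_meth = feature_matrix(bundle, meth_features)
    logexpr = np.log2(normalize_counts(bundle.counts) + 1.0)
    X_expr = logexpr.loc[list(expr_genes)].T
    if set(X_meth.columns) & set(X_expr.columns):
        raise ValueError("feature ID collision between methylation and expression blocks")
    X_comb = pd.concat([X_meth, X_expr], axis=1)

    out = {}
    for name, X in (("methylation", X_meth), ("expression", X_expr),
                    ("combined", X_comb)):
        out[name] = repeated_split_eval(
            X, labels, models=("SVM",), n_splits=n_splits, seed=seed,
            lam=lam, standardize=True,
        )
    return out
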