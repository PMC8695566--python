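"""Oversampled, variance-scaled RBF-SVM classifier and comparators.

The positive (responsive) class is rare (~10%), so every model is trained
on data where positive cases have been resampled with replacement up to the
number of negatives. The SVM uses an RBF kernel
K(a, b) = exp(-||a - b||^2 / (2 sigma^2)) whose scale is tied to the data:
sigma^2 = lambda x (mean per-feature variance of the TRAINING cases), with
only the multiplier lambda tuned (integer grid 1..20 by default, 5-fold
stratified cross-validation on F1, oversampling applied inside each
training fold only). Comparators: L1 logistic regression, random forest,
k-nearest neighbors, and a naive predictor that calls the higher-mean-TMB
infiltration cluster positive within each tumor type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from icimeth.infiltration import ClusterAssignment
from icimeth.labeling import MutationSummary

DEFAULT_LAMBDA_GRID: tuple[int, ...] = tuple(range(1, 21))


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameters; sigma^2 = lam x mean feature variance."""

    lam: float = 13.0
    C: float = 1.0
    oversample: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reproduce it.

    ``feature_ids`` fixes the column contract for prediction;
    ``mean_variance`` is the training-data mean per-feature variance behind
    the kernel scale (SVM only). ``has_scores`` says whether
    :meth:`decision_scores` is meaningful (the naive predictor has none).
    """

    kind: str
    estimator: object
    feature_ids: list[str]
    mean_variance: float | None = None
    lam: float | None = None
    has_scores: bool = True
    params: dict = field(default_factory=dict)

    def _check(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_ids:
            raise ValueError("prediction features differ from training features")
        return X.to_numpy(dtype=float)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self._check(X))

    def decision_scores(self, X: pd.DataFrame) -> np.ndarray | None:
        if not self.has_scores:
            return None
        arr = self._check(X)
        if hasattr(self.estimator, "decision_function"):
            return self.estimator.decision_function(arr)
        return self.estimator.predict_proba(arr)[:, 1]


def oversample(labels, seed: int) -> np.ndarray:
    """Indices of negatives plus positives resampled up to the negative count.

    Returns positional indices into ``labels``; the negative multiset is
    untouched, positives are drawn with replacement until the classes
    balance.
    """
    y = np.asarray(labels).astype(int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("oversampling needs both classes present")
    rng = np.random.default_rng(seed)
    drawn = rng.choice(pos, size=len(neg), replace=True)
    return np.concatenate([neg, drawn])


def _balanced(X: np.ndarray, y: np.ndarray, seed: int, do_oversample: bool):
    if not do_oversample:
        return X, y
    idx = oversample(y, seed)
    return X[idx], y[idx]


def svm_gamma(
    X_train: np.ndarray, lam: float, normalize_dim: bool = True
) -> tuple[float, float]:
    """(gamma, mean_variance) for K = exp(-gamma ||a-b||^2).

    The kernel scale is tied to the data as sigma^2 = lam x s2bar x d
    (s2bar = mean per-feature training variance, d = feature count), i.e.
    gamma = 1 / (2 lam d s2bar): squared distances grow linearly with the
    feature count, so the scale must too or the kernel degenerates to the
    identity for any useful d. ``normalize_dim=False`` drops the d factor
    (sigma^2 = lam x s2bar), usable only for handfuls of features.
    """
    s2bar = float(X_train.var(axis=0, ddof=1).mean())
    if s2bar <= 0:
        raise ValueError("zero mean feature variance; kernel scale undefined")
    d = X_train.shape[1] if normalize_dim else 1
    return 1.0 / (2.0 * lam * d * s2bar), s2bar


def train_svm(X: pd.DataFrame, y, config: SVMConfig) -> TrainedModel:
    """Fit the RBF-SVM on (optionally oversampled) training cases.

    The kernel scale is computed from the ORIGINAL training cases (before
    resampling) so duplicated positives do not distort it.
    """
    arr = X.to_numpy(dtype=float)
    yv = np.asarray(y).astype(int)
    gamma, s2bar = svm_gamma(arr, config.lam)
    Xb, yb = _balanced(arr, yv, config.seed, config.oversample)
    est = SVC(C=config.C, kernel="rbf", gamma=gamma, random_state=config.seed)
    est.fit(Xb, yb)
    return TrainedModel(
        kind="SVM", estimator=est, feature_ids=list(X.columns),
        mean_variance=s2bar, lam=config.lam, params={"C": config.C},
    )


def _cv_score(fit_fn, X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    """Mean validation F1 over stratified folds; oversampling inside folds."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = []
    for k, (tr, va) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError("training fold with a single class; reduce folds")
        est = fit_fn(X[tr], y[tr], seed + k)
        scores.append(f1_score(y[va], est.predict(X[va]), zero_division=0))
    return float(np.mean(scores))


def grid_search_cv(
    X: pd.DataFrame,
    y,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> SVMConfig:
    """Pick the SVM lambda maximizing mean 5-fold validation F1.

    Ties break toward the smaller lambda. Oversampling and the kernel scale
    are both recomputed inside each training fold, so no information leaks
    from validation folds.
    """
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    arr = X.to_numpy(dtype=float)
    yv = np.asarray(y).astype(int)

    def make_fit(lam):
        def fit(Xtr, ytr, s):
            gamma, _ = svm_gamma(Xtr, lam)
            Xb, yb = _balanced(Xtr, ytr, s, True)
            return SVC(C=C, kernel="rbf", gamma=gamma, random_state=s).fit(Xb, yb)
        return fit

    best_lam, best_score = None, -np.inf
    for lam in sorted(grid):
        score = _cv_score(make_fit(lam), arr, yv, folds, seed)
        if score > best_score + 1e-12:
            best_lam, best_score = lam, score
    return SVMConfig(lam=float(best_lam), C=C, seed=seed)


_COMPARATOR_GRIDS: dict[str, list[dict]] = {
    "LR_L1": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
    "RF": [
        {"n_estimators": n, "max_depth": d}
        for n in (100, 300) for d in (None, 10)
    ],
    "kNN": [{"n_neighbors": k} for k in (3, 5, 11, 21)],
}


def _make_estimator(kind: str, params: dict, seed: int):
    if kind == "LR_L1":
        return LogisticRegression(
            l1_ratio=1.0, solver="liblinear", max_iter=2000,
            random_state=seed, **params,
        )
    if kind == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if kind == "kNN":
        return KNeighborsClassifier(**params)
    raise ValueError(f"unknown comparator kind: {kind}")


def train_comparators(
    X: pd.DataFrame, y, seed: int = 0, folds: int = 5,
    grids: Mapping[str, list[dict]] | None = None,
) -> dict[str, TrainedModel]:
    """Grid-search and fit the L1-LR, RF and kNN comparators.

    Each model's grid is searched independently with the same stratified
    folds and in-fold oversampling protocol as the SVM.
    """
    arr = X.to_numpy(dtype=float)
    yv = np.asarray(y).astype(int)
    grids = dict(grids or _COMPARATOR_GRIDS)
    out: dict[str, TrainedModel] = {}
    for kind, grid in grids.items():
        best_params, best_score = None, -np.inf
        for params in grid:
            def fit(Xtr, ytr, s, _k=kind, _p=params):
                Xb, yb = _balanced(Xtr, ytr, s, True)
                return _make_estimator(_k, _p, s).fit(Xb, yb)
            score = _cv_score(fit, arr, yv, folds, seed)
            if score > best_score + 1e-12:
                best_params, best_score = params, score
        Xb, yb = _balanced(arr, yv, seed, True)
        est = _make_estimator(kind, best_params, seed).fit(Xb, yb)
        out[kind] = TrainedModel(
            kind=kind, estimator=est, feature_ids=list(X.columns),
            params=dict(best_params),
        )
    return out


def naive_predict(
    assignments: Mapping[str, ClusterAssignment] | pd.Series,
    tmb: MutationSummary,
    case_ids=None,
) -> pd.Series:
    """Label positive every case in its tumor type's higher-mean-TMB cluster.

    Accepts either the per-type :class:`ClusterAssignment` mapping or a flat
    case -> cluster Series (clusters compared within the series as a whole).
    Ties in mean TMB break toward cluster 1.
    """
    if isinstance(assignments, pd.Series):
        flat = {"": assignments}
    else:
        flat = {tt: asg.assignment for tt, asg in assignments.items()}
    pieces = []
    for tt, clusters in flat.items():
        t = tmb.tmb.loc[clusters.index]
        means = t.groupby(clusters).mean()
        if len(means) < 2 or means.iloc[0] == means.iloc[1]:
            positive_cluster = means.index[0]
        else:
            positive_cluster = means.idxmax()
        pieces.append((clusters == positive_cluster).astype(int))
    pred = pd.concat(pieces)
    if case_ids is not None:
        pred = pred.reindex(case_ids)
    return pred.rename("naive_label")
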