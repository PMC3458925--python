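"""Random-Forest Gini-importance feature ranking with pair-aware folds.

The forest itself is scikit-learn's RandomForestClassifier; this module
owns the protocol around it: cross-validation folds that never split an
ortholog pair (both members of a pair share a group id and always land in
the same fold), averaging of Gini importances across folds, ranking, and
out-of-fold evaluation of feature subsets.  A simple backward-elimination
variant (drop the lowest-importance 20% per round, keep the subset with
the best out-of-fold AUC) is provided for feature selection; it is not
equivalent to varSelRF's algorithm.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

from .scoring import EvaluationResult, roc_auc

__all__ = [
    "gini_impurity",
    "pair_folds",
    "rank_features",
    "evaluate_rf",
    "backward_eliminate",
    "RankingResult",
    "PairedGiniRanker",
]


def gini_impurity(p: Sequence[float]) -> float:
    """Gini impurity 1 - sum(p_k^2) of a class-frequency vector."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("class frequencies must be non-negative and sum to 1")
    return float(1.0 - np.sum(p**2))


@dataclasses.dataclass
class RankingResult:
    features: list[str]
    mean_gini: np.ndarray
    sd_gini: np.ndarray
    rank: np.ndarray  # permutation of 1..n_features, 1 = most important
    fold_importances: np.ndarray | None = None  # (n_folds, n_features)

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": self.features,
                "mean_gini": self.mean_gini,
                "sd_gini": self.sd_gini,
                "rank": self.rank,
            }
        )
        return df.sort_values("rank").reset_index(drop=True)

    def top(self, n: int) -> list[str]:
        return list(self.table()["feature"].head(n))


def pair_folds(groups: Sequence, n_folds: int, seed: int) -> list[np.ndarray]:
    """Random fold assignment by group (ortholog pair) id.

    Returns per-fold boolean test masks over samples; members sharing a
    group id always share a fold.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    fold_of_group = {g: i % n_folds for i, g in enumerate(uniq[order])}
    sample_fold = np.array([fold_of_group[g] for g in groups])
    return [sample_fold == k for k in range(n_folds)]


def _validate(X: pd.DataFrame, y, groups) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    X = pd.DataFrame(X)
    y = np.asarray(y)
    if groups is None:
        groups = np.arange(len(X))
    groups = np.asarray(groups)
    if not (len(X) == len(y) == len(groups)):
        raise ValueError("X, y and groups must have equal length")
    return X, y, groups


def rank_features(
    X: pd.DataFrame,
    y: Sequence,
    groups: Sequence | None = None,
    n_trees: int = 5000,
    n_folds: int = 5,
    seed: int = 0,
    n_jobs: int = 1,
) -> RankingResult:
    """Rank features by mean Gini importance across pair-aware CV folds."""
    X, y, groups = _validate(X, y, groups)
    masks = pair_folds(groups, n_folds, seed)
    importances = []
    for k, test_mask in enumerate(masks):
        train = ~test_mask
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + k, n_jobs=n_jobs
        )
        clf.fit(X.values[train], y[train])
        importances.append(clf.feature_importances_)
    imp = np.vstack(importances)
    mean = imp.mean(axis=0)
    sd = imp.std(axis=0, ddof=1)
    order = np.argsort(-mean, kind="stable")
    rank = np.empty(len(mean), dtype=int)
    rank[order] = np.arange(1, len(mean) + 1)
    return RankingResult(list(X.columns), mean, sd, rank, fold_importances=imp)


def evaluate_rf(
    X: pd.DataFrame,
    y: Sequence,
    feature_subset: Sequence[str] | None = None,
    groups: Sequence | None = None,
    n_trees: int = 5000,
    n_folds: int = 5,
    seed: int = 0,
    pos_label=1,
    n_jobs: int = 1,
) -> EvaluationResult:
    """Out-of-fold RF evaluation: pooled probabilities -> accuracy and AUC."""
    X, y, groups = _validate(X, y, groups)
    if feature_subset is not None:
        unknown = [f for f in feature_subset if f not in X.columns]
        if unknown:
            raise ValueError(f"unknown feature names: {unknown}")
        X = X[list(feature_subset)]
    masks = pair_folds(groups, n_folds, seed)
    proba = np.empty(len(X))
    for k, test_mask in enumerate(masks):
        train = ~test_mask
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + k, n_jobs=n_jobs
        )
        clf.fit(X.values[train], y[train])
        pos_col = list(clf.classes_).index(pos_label)
        proba[test_mask] = clf.predict_proba(X.values[test_mask])[:, pos_col]
    is_pos = y == pos_label
    pred_pos = proba > 0.5
    tp = int(np.count_nonzero(pred_pos & is_pos))
    tn = int(np.count_nonzero(~pred_pos & ~is_pos))
    fp = int(np.count_nonzero(pred_pos & ~is_pos))
    fn = int(np.count_nonzero(~pred_pos & is_pos))
    auc = roc_auc(list(proba[is_pos]), list(proba[~is_pos]))
    return EvaluationResult(tp=tp, tn=tn, fp=fp, fn=fn, auc=auc)


def backward_eliminate(
    X: pd.DataFrame,
    y: Sequence,
    groups: Sequence | None = None,
    drop_fraction: float = 0.2,
    min_features: int = 2,
    n_trees: int = 1000,
    n_folds: int = 5,
    seed: int = 0,
    n_jobs: int = 1,
) -> tuple[list[str], float]:
    """Iteratively drop the lowest-importance fraction of features and keep
    the subset with the best out-of-fold AUC."""
    X = pd.DataFrame(X)
    current = list(X.columns)
    best_subset, best_auc = current, -np.inf
    while len(current) >= min_features:
        res = evaluate_rf(
            X, y, feature_subset=current, groups=groups,
            n_trees=n_trees, n_folds=n_folds, seed=seed, n_jobs=n_jobs,
        )
        if res.auc > best_auc:
            best_subset, best_auc = list(current), res.auc
        if len(current) == min_features:
            break
        ranking = rank_features(
            X[current], y, groups=groups, n_trees=n_trees,
            n_folds=n_folds, seed=seed, n_jobs=n_jobs,
        )
        keep = max(min_features, int(np.ceil(len(current) * (1 - drop_fraction))))
        if keep == len(current):
            keep = len(current) - 1
        current = ranking.top(keep)
    return best_subset, float(best_auc)


class PairedGiniRanker(BaseEstimator):
    """sklearn-style estimator wrapping :func:`rank_features`.

    ``fit(X, y, groups=...)`` populates ``ranking_``, ``mean_gini_``,
    ``sd_gini_`` and ``feature_names_``.
    """

    def __init__(self, n_trees: int = 5000, n_folds: int = 5, seed: int = 0, n_jobs: int = 1):
        self.n_trees = n_trees
        self.n_folds = n_folds
        self.seed = seed
        self.n_jobs = n_jobs

    def fit(self, X, y, groups=None) -> "PairedGiniRanker":
        result = rank_features(
            X, y, groups=groups, n_trees=self.n_trees,
            n_folds=self.n_folds, seed=self.seed, n_jobs=self.n_jobs,
        )
        self.result_ = result
        self.feature_names_ = result.features
        self.mean_gini_ = result.mean_gini
        self.sd_gini_ = result.sd_gini
        self.ranking_ = result.rank
        return self
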