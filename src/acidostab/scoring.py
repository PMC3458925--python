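"""Relative-difference scoring of ortholog pairs.

For an oriented pair (seq1 = putative AP, seq2 = putative NP) each feature
contributes a bounded, sign-symmetric relative difference

    d_i = (x_i(seq1) - x_i(seq2)) / (x_i(seq1) + x_i(seq2)),    d_i = 0 if both are 0,

and the pair score is the linear combination ``S = sum_i w_i d_i`` over ten
composition features.  A positive score predicts that seq1 is the more
acidostable (AP) member.  Weights are constrained to [-1, 1] and fitted by
a stochastic hill climb that maximises the number of correctly oriented
training pairs; the published weight set is shipped and loadable with
:func:`published_weights`.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "SCORING_FEATURES",
    "published_weights",
    "relative_difference",
    "delta_matrix",
    "score_pair",
    "hill_climb",
    "HillClimbScorer",
    "EvaluationResult",
    "evaluate_ortholog_pairs",
    "evaluate_cross_pairs",
    "roc_auc",
    "roc_points",
]

#: The ten scoring features, in canonical weight order.
SCORING_FEATURES = (
    "x_K", "x_small", "x_T", "x_tiny", "x_aliphatic",
    "x_aromatic", "x_I", "x_LQ", "x_Q", "x_Y",
)

DIFFERENCE_MODES = ("symmetric", "plain", "reference")


def published_weights() -> dict[str, float]:
    """The shipped weight set for the ten scoring features."""
    path = resources.files("acidostab.data") / "scoring_weights.json"
    with open(str(path)) as fh:
        return json.load(fh)


def _delta(x1: float, x2: float, mode: str) -> float:
    if mode == "symmetric":
        s = x1 + x2
        return (x1 - x2) / s if s != 0 else 0.0
    if mode == "plain":
        return x1 - x2
    if mode == "reference":
        return (x1 - x2) / x2 if x2 != 0 else 0.0
    raise ValueError(f"unknown difference mode {mode!r}")


def relative_difference(
    f1: Mapping[str, float],
    f2: Mapping[str, float],
    features: Sequence[str] = SCORING_FEATURES,
    mode: str = "symmetric",
) -> dict[str, float]:
    """Per-feature relative difference of seq1 vs seq2."""
    missing = [n for n in features if n not in f1 or n not in f2]
    if missing:
        raise ValueError(f"feature vectors missing {missing}")
    return {n: _delta(float(f1[n]), float(f2[n]), mode) for n in features}


def delta_matrix(
    pairs: Sequence[tuple[Mapping[str, float], Mapping[str, float]]],
    features: Sequence[str] = SCORING_FEATURES,
    mode: str = "symmetric",
) -> np.ndarray:
    """Stack relative differences into an (n_pairs, n_features) array."""
    rows = [
        [
            _delta(float(f1[n]), float(f2[n]), mode)
            for n in features
        ]
        for f1, f2 in pairs
    ]
    return np.asarray(rows, dtype=float)


def score_pair(
    deltas: Mapping[str, float], weights: Mapping[str, float]
) -> float:
    """Signed linear score; positive predicts the first sequence is AP."""
    return float(sum(weights[n] * deltas[n] for n in weights))


# ---------------------------------------------------------------------------
# Hill-climbing trainer
# ---------------------------------------------------------------------------

def _objective(X: np.ndarray, w: np.ndarray) -> int:
    # pairs strictly above zero count as correct (a zero score is incorrect)
    return int(np.count_nonzero(X @ w > 0))


def hill_climb(
    X: np.ndarray,
    iterations: int = 100_000,
    seed: int = 0,
    restarts: int = 5,
    step: float = 0.1,
) -> tuple[np.ndarray, list[list[int]]]:
    """Fit weights in [-1, 1] maximising correctly oriented pairs.

    ``X`` holds delta rows of AP-first oriented pairs.  Each restart draws
    random initial weights, then repeatedly perturbs one uniformly chosen
    weight by a uniform step in [-step, step] (clamped) and keeps the move
    only when the number of positively scored pairs strictly increases.
    The returned weights are the element-wise mean of the best vectors of
    the restarts that attain the highest objective (averaging only
    converged runs keeps a single stuck restart from dragging the
    consensus off the optimum); the second value holds one
    accepted-objective trace per restart.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("need a non-empty 2-D delta matrix")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    n_feat = X.shape[1]
    best_weights = []
    traces: list[list[int]] = []
    for _ in range(max(1, restarts)):
        w = rng.uniform(-1.0, 1.0, size=n_feat)
        scores = X @ w  # maintained incrementally: one column update per move
        obj = int(np.count_nonzero(scores > 0))
        trace = [obj]
        ks = rng.integers(n_feat, size=int(iterations))
        deltas = rng.uniform(-step, step, size=int(iterations))
        for k, d in zip(ks, deltas):
            new_wk = min(1.0, max(-1.0, w[k] + d))
            trial = scores + (new_wk - w[k]) * X[:, k]
            new_obj = int(np.count_nonzero(trial > 0))
            if new_obj > obj:
                obj = new_obj
                w[k] = new_wk
                scores = trial
                trace.append(obj)
        best_weights.append((obj, w.copy()))
        traces.append(trace)
    top = max(obj for obj, _ in best_weights)
    winners = [w for obj, w in best_weights if obj == top]
    return np.mean(winners, axis=0), traces


class HillClimbScorer(ClassifierMixin, BaseEstimator):
    """sklearn-style classifier over oriented ortholog-pair delta rows.

    ``fit(X, y)`` expects delta rows and labels in {+1, -1} giving each
    row's true orientation (+1: first sequence is AP).  Rows are folded to
    AP-first orientation (X * y) before hill climbing, so the fitted
    weights score correctly oriented pairs positive.

    Attributes
    ----------
    weights_ : ndarray of shape (n_features,)
    n_iter_ : total proposal count
    traces_ : accepted-objective traces per restart
    """

    def __init__(
        self,
        iterations: int = 100_000,
        restarts: int = 5,
        step: float = 0.1,
        seed: int = 0,
    ):
        self.iterations = iterations
        self.restarts = restarts
        self.step = step
        self.seed = seed

    def fit(self, X, y=None) -> "HillClimbScorer":
        X = np.asarray(X, dtype=float)
        if y is None:
            y = np.ones(len(X))
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {1.0, -1.0}:
            raise ValueError("orientation labels must be +1 or -1")
        oriented = X * y[:, None]
        self.weights_, self.traces_ = hill_climb(
            oriented, self.iterations, self.seed, self.restarts, self.step
        )
        self.n_iter_ = int(self.iterations) * max(1, self.restarts)
        self.classes_ = np.array([-1.0, 1.0])
        return self

    def decision_function(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise ValueError("HillClimbScorer is not fitted")
        return np.asarray(X, dtype=float) @ self.weights_

    def predict(self, X) -> np.ndarray:
        s = self.decision_function(X)
        # zero scores predict the negative (reversed) orientation
        return np.where(s > 0, 1.0, -1.0)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class EvaluationResult:
    tp: int
    tn: int
    fp: int
    fn: int
    auc: float

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else 0.0

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["accuracy"] = self.accuracy
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def evaluate_ortholog_pairs(
    deltas: np.ndarray, weights: np.ndarray | Mapping[str, float]
) -> EvaluationResult:
    """Score AP-first oriented pairs; each pair also contributes its
    reversal as a negative case, so by antisymmetry tn = tp and fp = fn."""
    w = _as_vector(weights)
    scores = np.asarray(deltas, dtype=float) @ w
    tp = int(np.count_nonzero(scores > 0))
    fn = len(scores) - tp
    auc = roc_auc(list(scores), list(-scores))
    return EvaluationResult(tp=tp, tn=tp, fp=fn, fn=fn, auc=auc)


def evaluate_cross_pairs(
    ap_features: Sequence[Mapping[str, float]],
    np_features: Sequence[Mapping[str, float]],
    weights: Mapping[str, float],
    mode: str = "symmetric",
) -> EvaluationResult:
    """Score every (AP_i, NP_j) combination AP-first (the all-against-all
    non-ortholog challenge)."""
    if not ap_features or not np_features:
        raise ValueError("both feature lists must be non-empty")
    names = list(weights)
    w = np.array([weights[n] for n in names])
    A = np.array([[float(f[n]) for n in names] for f in ap_features])
    B = np.array([[float(f[n]) for n in names] for f in np_features])
    scores = np.empty((len(A), len(B)))
    for j in range(len(B)):
        if mode == "symmetric":
            s = A + B[j]
            d = np.where(s != 0, (A - B[j]) / np.where(s == 0, 1.0, s), 0.0)
        elif mode == "plain":
            d = A - B[j]
        elif mode == "reference":
            ref = B[j]
            d = np.where(ref != 0, (A - ref) / np.where(ref == 0, 1.0, ref), 0.0)
        else:
            raise ValueError(f"unknown difference mode {mode!r}")
        scores[:, j] = d @ w
    flat = scores.ravel()
    tp = int(np.count_nonzero(flat > 0))
    fn = flat.size - tp
    auc = roc_auc(list(flat), list(-flat))
    return EvaluationResult(tp=tp, tn=tp, fp=fn, fn=fn, auc=auc)


def _as_vector(weights) -> np.ndarray:
    if isinstance(weights, Mapping):
        return np.array([weights[n] for n in weights], dtype=float)
    return np.asarray(weights, dtype=float)


def roc_auc(scores_pos: Sequence[float], scores_neg: Sequence[float]) -> float:
    """AUC by the rank-sum (Mann-Whitney) formulation, ties counted 0.5."""
    if len(scores_pos) == 0 or len(scores_neg) == 0:
        raise ValueError("both score lists must be non-empty")
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    n_pos, n_neg = len(pos), len(neg)
    u = r_pos - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def roc_points(
    scores_pos: Sequence[float], scores_neg: Sequence[float]
) -> list[tuple[float, float]]:
    """(FPR, TPR) points of the empirical ROC curve, threshold descending."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    pts = [(0.0, 0.0)]
    for t in thresholds:
        tpr = float(np.count_nonzero(pos >= t)) / len(pos)
        fpr = float(np.count_nonzero(neg >= t)) / len(neg)
        pts.append((fpr, tpr))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return pts
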