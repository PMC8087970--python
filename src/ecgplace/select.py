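"""Hybrid feature selection: information-theoretic filters plus a wrapper.

The selection pipeline first ranks all 16 features with one of five filter
criteria, then runs backward elimination along that ranking against a
classifier's cross-validated accuracy:

* ``ENTROPY`` — univariate information gain, i.e. the mutual information of
  each feature with the placement label, descending;
* ``MIFS`` — greedy mutual-information feature selection: relevance minus
  beta times the summed redundancy with already-selected features;
* ``MRMR`` — maximum relevance, minimum redundancy: relevance minus the
  *mean* redundancy with already-selected features;
* ``JMI`` — joint mutual information: the sum over selected features s of
  I((x, s); y);
* ``RELIEF`` — ReliefF weights from k nearest hits and misses, descending.

Mutual information is the plug-in estimate on an equal-frequency
discretization (default 10 bins), in bits.  Backward elimination starts from
all 16 features and drops the lowest-priority remaining feature at each step,
returning the subset size with the best cross-validated accuracy (ties go to
the smaller subset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .models_ml import ModelSpec, build_estimator

__all__ = [
    "FILTER_METHODS",
    "SelectConfig",
    "CVSpec",
    "RankedFeatures",
    "SelectedSubset",
    "discretize_equal_frequency",
    "mutual_information",
    "rank_filter",
    "backward_eliminate",
]

FILTER_METHODS = ("MIFS", "MRMR", "JMI", "ENTROPY", "RELIEF")


@dataclass(frozen=True)
class SelectConfig:
    """Hyperparameters of the filter criteria (the methods' free knobs)."""

    n_bins: int = 10          # equal-frequency bins for MI estimation
    mifs_beta: float = 1.0    # redundancy weight in MIFS
    relief_k: int = 10        # nearest hits/misses in ReliefF

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.relief_k < 1:
            raise ValueError("relief_k must be >= 1")


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation protocol for the wrapper stage."""

    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class RankedFeatures:
    """One filter method's full priority ordering of the features.

    ``order`` lists 1-based feature IDs, highest priority first; ``scores``
    are the criterion values at which each feature was ranked (aligned with
    ``order``).
    """

    method: str
    order: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.method not in FILTER_METHODS:
            raise ValueError(f"unknown filter method {self.method!r}")
        n = len(self.order)
        if sorted(self.order) != list(range(1, n + 1)):
            raise ValueError("order must be a permutation of 1..n")
        if len(self.scores) != n:
            raise ValueError("scores must align with order")


@dataclass(frozen=True)
class SelectedSubset:
    """Result of backward elimination along one ranking."""

    method: str
    kept_feature_ids: tuple[int, ...]
    k: int
    cv_accuracy: float
    accuracy_by_k: dict[int, float] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not 1 <= self.k:
            raise ValueError("k must be >= 1")
        if len(self.kept_feature_ids) != self.k:
            raise ValueError("kept_feature_ids must have length k")


def discretize_equal_frequency(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Map a real-valued column to integer bin codes with ~equal counts.

    A column that is already discrete (at most ``n_bins`` distinct values)
    keeps its exact value partition, so the plug-in MI on such input equals
    the direct summation over its joint table.  Duplicate quantile edges
    collapse, so a constant column maps to a single bin (and thus carries
    zero information).
    """
    x = np.asarray(x, dtype=float)
    values, codes = np.unique(x, return_inverse=True)
    if values.size <= n_bins:
        return codes
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def _mi_discrete(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two discrete code vectors."""
    n = a.size
    joint: dict[tuple[int, int], int] = {}
    ca: dict[int, int] = {}
    cb: dict[int, int] = {}
    for ai, bi in zip(a.tolist(), b.tolist()):
        joint[(ai, bi)] = joint.get((ai, bi), 0) + 1
        ca[ai] = ca.get(ai, 0) + 1
        cb[bi] = cb.get(bi, 0) + 1
    mi = 0.0
    for (ai, bi), c in joint.items():
        p_ab = c / n
        mi += p_ab * np.log2(p_ab * n * n / (ca[ai] * cb[bi]))
    return max(mi, 0.0)  # clamp -0.0 from rounding


def _pair_code(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # injective code for the joint variable (a, b)
    return a * (b.max() + 1) + b


def mutual_information(x: np.ndarray, y: np.ndarray,
                       n_bins: int = 10) -> float:
    """MI (bits) between a real feature column and binary labels.

    The feature is discretized into ``n_bins`` equal-frequency bins and the
    plug-in estimate is computed on the empirical joint distribution.  A
    constant column has a single effective bin and MI exactly 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must share a length of at least 2")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    return _mi_discrete(discretize_equal_frequency(x, n_bins), y.astype(int))


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    return y


def _greedy_rank(rel: np.ndarray, codes: list[np.ndarray], y: np.ndarray,
                 method: str, beta: float) -> tuple[list[int], list[float]]:
    """Greedy forward ordering under MIFS / MRMR / JMI criteria (0-based)."""
    d = len(codes)
    remaining = list(range(d))
    order: list[int] = []
    scores: list[float] = []
    # caches for pairwise redundancy and joint-MI terms
    red: dict[tuple[int, int], float] = {}
    jmi: dict[tuple[int, int], float] = {}

    def redundancy(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in red:
            red[key] = _mi_discrete(codes[i], codes[j])
        return red[key]

    def joint_with(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in jmi:
            jmi[key] = _mi_discrete(_pair_code(codes[i], codes[j]), y)
        return jmi[key]

    while remaining:
        best_f, best_score = None, -np.inf
        for f in remaining:  # ascending feature index = ID tie-break
            if not order:
                score = rel[f]
            elif method == "MIFS":
                score = rel[f] - beta * sum(redundancy(f, s) for s in order)
            elif method == "MRMR":
                score = rel[f] - np.mean([redundancy(f, s) for s in order])
            else:  # JMI
                score = sum(joint_with(f, s) for s in order)
            if score > best_score:
                best_f, best_score = f, score
        order.append(best_f)
        scores.append(float(best_score))
        remaining.remove(best_f)
    return order, scores


def _relief_weights(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """ReliefF weights for binary labels, using all instances.

    Distances and per-feature differences are scaled by each feature's range,
    the standard ReliefF normalization; a zero-range (constant) feature
    contributes nothing and gets weight 0.
    """
    n, d = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0.0] = 1.0
    Z = X / span
    w = np.zeros(d)
    for i in range(n):
        diff = np.abs(Z - Z[i])  # (n, d) scaled per-feature differences
        dist = diff.sum(axis=1)  # Manhattan distance, standard in ReliefF
        dist[i] = np.inf
        same = y == y[i]
        same[i] = False
        for mask, sign in ((same, -1.0), (~same, +1.0)):
            idx = np.where(mask)[0]
            if idx.size == 0:
                continue
            kk = min(k, idx.size)
            nearest = idx[np.argpartition(dist[idx], kk - 1)[:kk]]
            w += sign * diff[nearest].sum(axis=0) / kk
    return w / n


def rank_filter(X: np.ndarray, y: np.ndarray, method: str,
                config: SelectConfig = SelectConfig()) -> RankedFeatures:
    """Rank all features with one filter criterion.

    Ties are broken toward the lower feature ID, making every ranking
    deterministic.
    """
    method = method.upper()
    if method not in FILTER_METHODS:
        raise ValueError(f"unknown filter method {method!r}; "
                         f"choose from {FILTER_METHODS}")
    X = np.asarray(X, dtype=float)
    y = _check_binary(y)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per label")
    d = X.shape[1]

    if method == "RELIEF":
        w = _relief_weights(X, y, config.relief_k)
        # stable sort on (-weight, id): descending weight, lower ID first
        idx = np.lexsort((np.arange(d), -w))
        return RankedFeatures(method, tuple(int(i) + 1 for i in idx),
                              tuple(float(w[i]) for i in idx))

    codes = [discretize_equal_frequency(X[:, j], config.n_bins)
             for j in range(d)]
    rel = np.array([_mi_discrete(c, y) for c in codes])

    if method == "ENTROPY":
        idx = np.lexsort((np.arange(d), -rel))
        return RankedFeatures(method, tuple(int(i) + 1 for i in idx),
                              tuple(float(rel[i]) for i in idx))

    order0, scores = _greedy_rank(rel, codes, y, method, config.mifs_beta)
    return RankedFeatures(method, tuple(i + 1 for i in order0), tuple(scores))


def backward_eliminate(ranking: RankedFeatures, X: np.ndarray, y: np.ndarray,
                       model_spec: ModelSpec,
                       cv_spec: CVSpec = CVSpec()) -> SelectedSubset:
    """Wrapper stage: find the best top-k prefix of a filter ranking.

    Starts from all features and removes the lowest-priority remaining
    feature one at a time, scoring each candidate subset by stratified
    cross-validated accuracy; returns the maximizing k (ties -> smaller k).
    """
    X = np.asarray(X, dtype=float)
    y = _check_binary(y)
    d = X.shape[1]
    cv = StratifiedKFold(n_splits=cv_spec.folds, shuffle=True,
                         random_state=cv_spec.seed)
    acc_by_k: dict[int, float] = {}
    for k in range(d, 0, -1):
        cols = [fid - 1 for fid in ranking.order[:k]]
        est = build_estimator(model_spec, seed=cv_spec.seed)
        acc_by_k[k] = float(np.mean(
            cross_val_score(est, X[:, cols], y, cv=cv, scoring="accuracy")))
    # max accuracy; ties resolved toward the smaller subset
    best_k = min((k for k in acc_by_k
                  if acc_by_k[k] == max(acc_by_k.values())))
    return SelectedSubset(
        method=ranking.method,
        kept_feature_ids=tuple(ranking.order[:best_k]),
        k=best_k,
        cv_accuracy=acc_by_k[best_k],
        accuracy_by_k=acc_by_k,
    )
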