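"""Classical classifiers for the feature-engineered detection path.

Six model families are provided, mirroring the usual fine/coarse preset
distinction for decision trees and the standard kernelized and linear
baselines:

* ``fine_tree`` — Gini-split decision tree allowed many leaves (fine class
  distinctions; up to 100 splits by default);
* ``coarse_tree`` — the same with very few leaves (up to 4 splits);
* ``bagged_tree`` — bootstrap-aggregated Gini trees, majority vote;
* ``logistic`` — logistic regression on standardized features;
* ``linear_svm`` / ``quadratic_svm`` — support vector machines with a linear
  or degree-2 polynomial kernel on standardized features.

The closed-form pieces these models rest on — Gini impurity, the
log-odds -> odds -> probability chain of logistic regression, and the
maximum-margin hyperplane decision rule — are exposed as directly testable
functions.  Fitting is delegated to scikit-learn estimators behind this
surface; every fit is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "TrainedModel",
    "gini_impurity",
    "logit_probability",
    "linear_svm_margin_predict",
    "build_estimator",
    "train",
    "predict",
]

MODEL_KINDS = ("fine_tree", "coarse_tree", "logistic", "linear_svm",
               "quadratic_svm", "bagged_tree")

_DEFAULT_HYPER: dict[str, dict[str, Any]] = {
    "fine_tree": {"max_splits": 100},
    "coarse_tree": {"max_splits": 4},
    "logistic": {"C": 1.0},
    "linear_svm": {"C": 1.0},
    "quadratic_svm": {"C": 1.0, "degree": 2},
    "bagged_tree": {"n_learners": 30},
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier kind plus its (kind-specific) hyperparameters."""

    kind: str
    hyper: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; "
                             f"choose from {MODEL_KINDS}")
        merged = dict(_DEFAULT_HYPER[self.kind])
        unknown = set(self.hyper) - set(merged)
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.kind}: "
                             f"{sorted(unknown)}")
        merged.update(self.hyper)
        object.__setattr__(self, "hyper", merged)
        if self.kind in ("fine_tree", "coarse_tree") and merged["max_splits"] < 1:
            raise ValueError("max_splits must be >= 1")
        if self.kind == "bagged_tree" and merged["n_learners"] < 2:
            raise ValueError("bagging needs at least 2 learners")


@dataclass(frozen=True)
class TrainedModel:
    """A fitted classifier with its training metadata."""

    spec: ModelSpec
    estimator: Any = field(compare=False)
    seed: int
    n_train: int
    feature_ids: tuple[int, ...]


def gini_impurity(class_fractions) -> float:
    """Gini impurity ``1 - sum(p_i^2)`` of a node's class fractions.

    For two classes the value lies in [0, 0.5], maximized at a 50/50 node and
    zero exactly for a pure node.
    """
    p = np.asarray(class_fractions, dtype=float)
    if np.any(p < 0):
        raise ValueError("class fractions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"class fractions must sum to 1, got {p.sum()}")
    return float(1.0 - np.sum(p**2))


def logit_probability(coefficients, x) -> float:
    """Class-1 probability from logistic-regression coefficients.

    Composes the logistic chain: log-odds ``L = a0 + sum(a_i x_i)``, odds
    ``o = exp(L)``, probability ``p = o / (1 + o)``.
    """
    a = np.asarray(coefficients, dtype=float)
    x = np.asarray(x, dtype=float)
    if a.size != x.size + 1:
        raise ValueError(
            f"need one coefficient per feature plus an intercept; "
            f"got {a.size} coefficients for {x.size} features")
    log_odds = a[0] + float(np.dot(a[1:], x))
    odds = np.exp(log_odds)
    if np.isinf(odds):
        return 1.0
    return float(odds / (1.0 + odds))


def linear_svm_margin_predict(w, b, x) -> int:
    """Decision rule of a fitted maximum-margin hyperplane.

    Cases on or above the hyperplane ``w.x - b = 0`` belong to class 1,
    cases below it to class 0.
    """
    w = np.asarray(w, dtype=float)
    x = np.asarray(x, dtype=float)
    if w.shape != x.shape:
        raise ValueError("w and x must have the same length")
    return 1 if float(np.dot(w, x)) - b >= 0.0 else 0


def build_estimator(spec: ModelSpec, seed: int = 0):
    """Construct the (unfitted) scikit-learn estimator for a model spec.

    Margin/odds models get a standardization step fitted on the training
    fold; trees consume raw features.  ``max_splits`` bounds the number of
    internal binary splits, i.e. ``max_leaf_nodes = max_splits + 1``.
    """
    h = spec.hyper
    if spec.kind in ("fine_tree", "coarse_tree"):
        return DecisionTreeClassifier(
            criterion="gini", max_leaf_nodes=h["max_splits"] + 1,
            random_state=seed)
    if spec.kind == "bagged_tree":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(criterion="gini"),
            n_estimators=h["n_learners"], bootstrap=True, random_state=seed)
    if spec.kind == "logistic":
        clf = LogisticRegression(C=h["C"], max_iter=2000, random_state=seed)
    elif spec.kind == "linear_svm":
        clf = SVC(kernel="linear", C=h["C"], random_state=seed)
    else:  # quadratic_svm
        # inhomogeneous quadratic kernel (x.x' + 1)^2: includes the linear
        # terms, unlike the even-symmetric homogeneous form
        clf = SVC(kernel="poly", degree=h["degree"], coef0=1.0, C=h["C"],
                  random_state=seed)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train(spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int = 0,
          feature_ids: tuple[int, ...] | None = None) -> TrainedModel:
    """Fit one classifier on a feature matrix with binary labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per label")
    classes = np.unique(y)
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if classes.size < 2:
        raise ValueError("training requires both classes to be present")
    if feature_ids is None:
        feature_ids = tuple(range(1, X.shape[1] + 1))
    if len(feature_ids) != X.shape[1]:
        raise ValueError("feature_ids must match the number of columns")
    est = build_estimator(spec, seed=seed)
    est.fit(X, y)
    return TrainedModel(spec=spec, estimator=est, seed=seed,
                        n_train=X.shape[0], feature_ids=tuple(feature_ids))


_PERSIST_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    """Persist a fitted model to a versioned pickle file."""
    import pickle

    with open(path, "wb") as fh:
        pickle.dump({"format_version": _PERSIST_VERSION, "model": model}, fh)


def load_model(path) -> TrainedModel:
    """Load a model saved by :func:`save_model`."""
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _PERSIST_VERSION:
        raise ValueError(
            f"unsupported model file version {payload.get('format_version')}")
    return payload["model"]


def predict(model: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and class-1 scores in [0, 1] (usable for ROC).

    SVMs report a logistic squashing of the signed margin distance; the other
    models report their class-1 probability.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_ids):
        raise ValueError(
            f"expected {len(model.feature_ids)} feature columns, "
            f"got shape {X.shape}")
    if X.shape[0] == 0:
        return np.zeros(0, dtype=int), np.zeros(0)
    est = model.estimator
    labels = est.predict(X).astype(int)
    if hasattr(est, "predict_proba"):
        scores = est.predict_proba(X)[:, 1]
    else:
        margin = est.decision_function(X)
        scores = 1.0 / (1.0 + np.exp(-margin))
    return labels, np.clip(scores, 0.0, 1.0)
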