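"""Performance evaluation and end-to-end pipeline orchestration.

Reports the full confusion-matrix metric set for a binary placement detector
— accuracy, sensitivity, specificity, predictivity of positive test (PPT,
positive predictive value), predictivity of negative test (PNT, negative
predictive value) and F1 — together with ROC curves, AUC and normal-
approximation (Wald, z = 1.96) 95% confidence intervals per metric.

The positive class is *correct placement* (label 1); an inversion flag is
available for readers who treat "misplaced" as the positive finding.
Metric cells whose denominator is zero are reported as ``None`` with a
reason, never as 0.

``run_pipeline`` executes the whole study on synthetic cohorts: simulate ->
delineate/extract features -> filter + wrapper feature selection -> train the
six classical models, and in parallel feed the raw normalized beats to the
two deep networks; every model is scored on the same held-out subjects per
displacement condition.  Splits are subject-level (both placements of a
subject stay on one side) to avoid leakage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from . import models_dl, models_ml
from .features import FeatureConfig, FEATURE_NAMES, feature_matrix
from .models_ml import MODEL_KINDS, ModelSpec
from .preprocess import normalize
from .select import CVSpec, backward_eliminate, rank_filter
from .synth import Cohort, CohortConfig, beat_pair_tensor, generate_cohort

__all__ = [
    "EvalReport",
    "RunConfig",
    "confusion_metrics",
    "roc_auc",
    "wald_ci",
    "split_subjects",
    "run_pipeline",
    "comparison_table",
    "save_bundle",
]


def wald_ci(p_hat: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation CI for a proportion, clipped to [0, 1].

    ``p_hat +/- z * sqrt(p_hat (1 - p_hat) / n)``; the default constant 1.96
    gives the 95% interval.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError("p_hat must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n)
    return (max(0.0, p_hat - half), min(1.0, p_hat + half))


@dataclass(frozen=True)
class EvalReport:
    """Confusion-matrix metrics, AUC and 95% CIs for one model on one split.

    Undefined metrics (zero denominator) are ``None`` and listed with a
    reason under ``undefined``.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    n: int
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppt: float | None
    pnt: float | None
    f1: float | None
    auc: float | None
    ci95: dict[str, tuple[float, float] | None]
    undefined: dict[str, str]
    model_id: str = ""
    condition: str = ""
    roc_points: tuple | None = field(default=None, compare=False)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("roc_points")
        return d


def _safe_ratio(num: int, den: int, name: str,
                undefined: dict[str, str]) -> float | None:
    if den == 0:
        undefined[name] = f"denominator of {name} is zero"
        return None
    return num / den


def confusion_metrics(y_true, y_pred, scores=None, model_id: str = "",
                      condition: str = "", positive_correct: bool = True
                      ) -> EvalReport:
    """Score binary predictions; optionally add ROC/AUC from scores.

    With ``positive_correct`` (default) the positive class is label 1,
    correct placement; pass ``False`` to swap the roles of the two labels in
    sensitivity/specificity/PPT/PNT.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos = 1 if positive_correct else 0
    tp = int(np.sum((y_true == pos) & (y_pred == pos)))
    tn = int(np.sum((y_true != pos) & (y_pred != pos)))
    fp = int(np.sum((y_true != pos) & (y_pred == pos)))
    fn = int(np.sum((y_true == pos) & (y_pred != pos)))
    n = y_true.size

    undefined: dict[str, str] = {}
    accuracy = _safe_ratio(tp + tn, n, "accuracy", undefined)
    sensitivity = _safe_ratio(tp, tp + fn, "sensitivity", undefined)
    specificity = _safe_ratio(tn, tn + fp, "specificity", undefined)
    ppt = _safe_ratio(tp, tp + fp, "ppt", undefined)
    pnt = _safe_ratio(tn, tn + fn, "pnt", undefined)
    if ppt is None or sensitivity is None or ppt + sensitivity == 0:
        undefined.setdefault("f1", "PPT or sensitivity undefined or both zero")
        f1 = None
    else:
        f1 = 2.0 * ppt * sensitivity / (ppt + sensitivity)

    auc = None
    roc_points = None
    if scores is not None and np.unique(y_true).size == 2:
        scores_pos = np.asarray(scores, dtype=float)
        if not positive_correct:
            scores_pos = 1.0 - scores_pos
        curve, auc = roc_auc(scores_pos, (y_true == pos).astype(int))
        roc_points = curve

    metrics = {"accuracy": accuracy, "sensitivity": sensitivity,
               "specificity": specificity, "ppt": ppt, "pnt": pnt, "f1": f1}
    denoms = {"accuracy": n, "sensitivity": tp + fn, "specificity": tn + fp,
              "ppt": tp + fp, "pnt": tn + fn, "f1": n}
    ci95 = {name: (wald_ci(value, denoms[name]) if value is not None else None)
            for name, value in metrics.items()}

    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, n=n,
                      accuracy=accuracy, sensitivity=sensitivity,
                      specificity=specificity, ppt=ppt, pnt=pnt, f1=f1,
                      auc=auc, ci95=ci95, undefined=undefined,
                      model_id=model_id, condition=condition,
                      roc_points=roc_points)


def roc_auc(scores, y_true) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC curve points and AUC for class-1 scores.

    The AUC equals the probability that a uniformly chosen positive case
    scores above a uniformly chosen negative case, with ties counting 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true).astype(int)
    if np.unique(y_true).size < 2:
        raise ValueError("AUC is undefined with a single class present")
    fpr, tpr, _ = roc_curve(y_true, scores)
    return (fpr, tpr), float(roc_auc_score(y_true, scores))


def split_subjects(cohort: Cohort, fractions: tuple[float, float, float],
                   seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subject-level train/val/test split, stratified by subject class.

    Returns index arrays into ``cohort.pairs``; both placements of every
    subject land in the same part.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    by_subject: dict[str, list[int]] = {}
    subject_class: dict[str, str] = {}
    for i, pair in enumerate(cohort.pairs):
        by_subject.setdefault(pair.subject_id, []).append(i)
        subject_class[pair.subject_id] = pair.subject_class
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for cls in sorted(set(subject_class.values())):
        sids = sorted(s for s, c in subject_class.items() if c == cls)
        sids = [sids[i] for i in rng.permutation(len(sids))]
        n = len(sids)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        chunks = (sids[:n_train], sids[n_train:n_train + n_val],
                  sids[n_train + n_val:])
        for part, chunk in zip(parts, chunks):
            for sid in chunk:
                part.extend(by_subject[sid])
    for frac, part in zip(fractions, parts):
        if frac > 0 and not part:
            raise ValueError(
                "too few subjects to populate every split part; "
                f"got {len(subject_class)} subjects for fractions {fractions}")
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)


@dataclass(frozen=True)
class RunConfig:
    """Desk-scale configuration of one full pipeline run."""

    n_per_class: int = 50
    ics_levels: tuple[str, ...] = ("second", "third")
    effect_scale: float = 1.0
    noise_sd: float = 0.05
    baseline_drift_amp: float = 0.05
    seed: int = 0
    ml_models: tuple[str, ...] = MODEL_KINDS
    dl_models: tuple[str, ...] = ("CNN", "BLSTM")
    filter_method: str = "JMI"
    wrapper_model: str = "bagged_tree"
    cv_folds: int = 10
    split_fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    blstm_hidden: int = 24
    dl_epochs: int = 30
    dl_batch_size: int = 32
    dl_learning_rate: float = 1e-3


def _eval_ml(cohort: Cohort, df: pd.DataFrame, idx_train: np.ndarray,
             idx_test: np.ndarray, config: RunConfig, condition: str
             ) -> tuple[dict[str, EvalReport], dict]:
    X = df[list(FEATURE_NAMES)].to_numpy()
    y = df["label"].to_numpy()
    ranking = rank_filter(X[idx_train], y[idx_train], config.filter_method)
    subset = backward_eliminate(
        ranking, X[idx_train], y[idx_train],
        ModelSpec(config.wrapper_model),
        CVSpec(folds=config.cv_folds, seed=config.seed))
    cols = [fid - 1 for fid in subset.kept_feature_ids]
    reports = {}
    for kind in config.ml_models:
        model = models_ml.train(ModelSpec(kind), X[idx_train][:, cols],
                                y[idx_train], seed=config.seed,
                                feature_ids=subset.kept_feature_ids)
        labels, scores = models_ml.predict(model, X[idx_test][:, cols])
        reports[kind] = confusion_metrics(
            y[idx_test], labels, scores, model_id=kind, condition=condition)
    selection_info = {
        "method": ranking.method,
        "order": list(ranking.order),
        "k": subset.k,
        "kept_feature_ids": list(subset.kept_feature_ids),
        "cv_accuracy": subset.cv_accuracy,
    }
    return reports, selection_info


def _eval_dl(cohort: Cohort, idx_train: np.ndarray, idx_val: np.ndarray,
             idx_test: np.ndarray, config: RunConfig, condition: str
             ) -> dict[str, EvalReport]:
    # raw beats only: per-lead amplitude normalization, no feature vectors
    pairs = [
        dataclasses.replace(p, v1=normalize(p.v1), v2=normalize(p.v2),
                            ground_truth=None)
        for p in cohort.pairs
    ]
    X = beat_pair_tensor(pairs)
    y = cohort.labels
    train_cfg = models_dl.TrainConfig(
        epochs=config.dl_epochs, batch_size=config.dl_batch_size,
        learning_rate=config.dl_learning_rate)
    reports = {}
    for kind in config.dl_models:
        if kind == "CNN":
            spec = models_dl.default_cnn_spec()
        else:
            spec = models_dl.default_blstm_spec(hidden_units=config.blstm_hidden)
        net = models_dl.build_network(spec, input_length=X.shape[2],
                                      n_channels=2, seed=config.seed)
        net, _ = models_dl.train_network(
            net, X[idx_train], y[idx_train], train_cfg, seed=config.seed,
            validation=(X[idx_val], y[idx_val]))
        labels, scores = models_dl.predict_network(net, X[idx_test])
        reports[kind] = confusion_metrics(
            y[idx_test], labels, scores, model_id=kind, condition=condition)
    return reports


def run_pipeline(config: RunConfig = RunConfig()) -> dict:
    """Run the full study on synthetic cohorts for each displacement condition.

    Returns a JSON-serializable bundle with per-model, per-condition
    evaluation reports, the feature-selection outcome, and the configuration;
    fully reproducible from ``config``.
    """
    bundle: dict = {"config": dataclasses.asdict(config),
                    "reports": {}, "selection": {}}
    for ics in config.ics_levels:
        condition = f"{ics}_ICS"
        cohort_cfg = CohortConfig(
            n_per_class=config.n_per_class, ics_level=ics,
            effect_scale=config.effect_scale, noise_sd=config.noise_sd,
            baseline_drift_amp=config.baseline_drift_amp, seed=config.seed)
        cohort = generate_cohort(cohort_cfg)
        idx_train, idx_val, idx_test = split_subjects(
            cohort, config.split_fractions, seed=config.seed)
        df = feature_matrix(cohort, FeatureConfig())
        idx_fit = np.sort(np.concatenate([idx_train, idx_val]))
        ml_reports, selection = _eval_ml(
            cohort, df, idx_fit, idx_test, config, condition)
        dl_reports = _eval_dl(
            cohort, idx_train, idx_val, idx_test, config, condition)
        bundle["selection"][condition] = selection
        bundle["reports"][condition] = {
            name: rep.to_dict() for name, rep in {**ml_reports,
                                                  **dl_reports}.items()}
        bundle.setdefault("_roc", {})[condition] = {
            name: rep.roc_points for name, rep in {**ml_reports,
                                                   **dl_reports}.items()}
    return bundle


def comparison_table(bundle: dict) -> pd.DataFrame:
    """Model x condition accuracy table from a pipeline bundle."""
    rows = []
    for condition, reports in bundle["reports"].items():
        for model, rep in reports.items():
            rows.append({"model": model, "condition": condition,
                         "accuracy": rep["accuracy"], "auc": rep["auc"],
                         "sensitivity": rep["sensitivity"],
                         "specificity": rep["specificity"],
                         "f1": rep["f1"], "n": rep["n"]})
    return pd.DataFrame(rows).sort_values(
        ["condition", "accuracy"], ascending=[True, False]).reset_index(drop=True)


def save_bundle(bundle: dict, out_dir: str | Path) -> Path:
    """Write the metrics JSON, the comparison CSV and per-model ROC points."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    serializable = {k: v for k, v in bundle.items() if not k.startswith("_")}
    with open(out / "metrics.json", "w") as fh:
        json.dump(serializable, fh, indent=1, sort_keys=True)
    comparison_table(bundle).to_csv(out / "comparison.csv", index=False)
    import sklearn

    from . import __version__
    lines = [
        f"ecgplace {__version__}",
        f"numpy {np.__version__}, pandas {pd.__version__}, "
        f"scikit-learn {sklearn.__version__}",
        f"seed {bundle['config']['seed']}",
        f"conditions {sorted(bundle['reports'])}",
    ]
    (out / "log.txt").write_text("\n".join(lines) + "\n")
    for condition, curves in bundle.get("_roc", {}).items():
        for model, points in curves.items():
            if points is None:
                continue
            fpr, tpr = points
            pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
                out / f"roc_{model}_{condition}.csv", index=False)
    return out
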