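"""Cross-validation harnesses and classification metrics.

Two validation schemes are provided.  Stratified 5-fold cross-validation
splits at the sample level, so every subject contributes to both training
and test folds — an optimistic setting that measures within-cohort fit.
Leave-one-subject-out (LOSO) holds out every sample of one subject per
fold, measuring generalization to an unseen wearer; the gap between the
two quantifies how much subject identity leaks into the features.

Metrics: per-class recall and precision, macro F1, overall accuracy, the
multiclass Matthews correlation coefficient (the R_K multi-category
correlation, which reduces exactly to the familiar binary MCC on 2x2
tables), and the working-status summary — the unweighted mean of recall
and precision over the three working classes Re/Ty/Wr.

Fold confusions are summed into one aggregate table before computing the
headline metrics (micro-style aggregation); per-fold reports are retained
for distributional views.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import (
    EmptyMatrixError,
    LengthMismatchError,
    MissingWorkingClassError,
    SingleSubjectError,
    TooFewSamplesError,
    UnknownLabelError,
)
from .features import Dataset
from .models import ModelConfig, TrainedModel, train_classifier
from .streams import ACTIVITY_CLASSES, WORKING_CLASSES

TrainFn = Callable[[ModelConfig, Dataset], TrainedModel]


def confusion_from_predictions(
    truth: Sequence[str], predicted: Sequence[str], classes: Sequence[str] = ACTIVITY_CLASSES
) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    if len(truth) != len(predicted):
        raise LengthMismatchError(f"{len(truth)} truths vs {len(predicted)} predictions")
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(truth, predicted):
        if t not in index or p not in index:
            raise UnknownLabelError(f"label outside {tuple(classes)}: {t!r}/{p!r}")
        cm[index[t], index[p]] += 1
    return cm


def per_class_metrics(
    cm: np.ndarray, classes: Sequence[str] = ACTIVITY_CLASSES
) -> dict[str, object]:
    """Recall/precision per class, macro F1 and accuracy from a confusion matrix.

    A class with no true samples (undefined recall) or no predictions
    (undefined precision) is reported as ``None`` and excluded from the
    macro averages rather than counted as zero.
    """
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise EmptyMatrixError("confusion matrix holds no counts")
    diag = np.diag(cm).astype(float)
    row = cm.sum(axis=1).astype(float)
    col = cm.sum(axis=0).astype(float)
    recall = {c: (diag[i] / row[i] if row[i] > 0 else None) for i, c in enumerate(classes)}
    precision = {c: (diag[i] / col[i] if col[i] > 0 else None) for i, c in enumerate(classes)}
    f1 = {}
    for c in classes:
        r, p = recall[c], precision[c]
        f1[c] = None if (r is None or p is None or r + p == 0) else 2 * r * p / (r + p)
    defined_f1 = [v for v in f1.values() if v is not None]
    return {
        "recall": recall,
        "precision": precision,
        "f1": f1,
        "macro_f1": float(np.mean(defined_f1)) if defined_f1 else None,
        "accuracy": float(diag.sum() / total),
    }


def multiclass_mcc(cm: np.ndarray) -> float:
    """Matthews correlation via the R_K multi-category statistic.

    For a KxK confusion matrix with total s, trace c, true-class counts
    t_k and predicted-class counts p_k::

        MCC = (c*s - sum_k p_k t_k)
              / sqrt((s^2 - sum_k p_k^2) * (s^2 - sum_k t_k^2))

    On 2x2 tables this equals the textbook binary formula exactly.  When a
    denominator factor vanishes (all truths or all predictions in one
    class) the statistic is defined as 0.
    """
    cm = np.asarray(cm, dtype=float)
    s = cm.sum()
    if s == 0:
        raise EmptyMatrixError("confusion matrix holds no counts")
    c = np.trace(cm)
    t = cm.sum(axis=1)
    p = cm.sum(axis=0)
    cov = c * s - p @ t
    # single sqrt of the product keeps perfect diagonals at exactly 1.0
    denom = np.sqrt((s**2 - p @ p) * (s**2 - t @ t))
    return float(cov / denom) if denom > 0 else 0.0


@dataclass
class EvalReport:
    """Aggregate + per-fold evaluation results."""

    confusion: np.ndarray
    recall: dict[str, float | None]
    precision: dict[str, float | None]
    macro_f1: float | None
    accuracy: float
    mcc: float
    working_recall: float
    working_precision: float
    fold_ids: list[str]
    per_fold: list[dict] = field(default_factory=list)
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "classes": list(ACTIVITY_CLASSES),
            "recall": self.recall,
            "precision": self.precision,
            "macro_f1": self.macro_f1,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "working_recall": self.working_recall,
            "working_precision": self.working_precision,
            "fold_ids": self.fold_ids,
            "per_fold": self.per_fold,
            "seed": self.seed,
        }


def working_status_summary(metrics: dict[str, object]) -> tuple[float, float]:
    """Unweighted mean recall/precision over the working classes Re/Ty/Wr."""
    recalls, precisions = [], []
    for c in WORKING_CLASSES:
        r = metrics["recall"].get(c)
        p = metrics["precision"].get(c)
        if r is None or p is None:
            raise MissingWorkingClassError(f"metrics for working class {c!r} are undefined")
        recalls.append(r)
        precisions.append(p)
    return float(np.mean(recalls)), float(np.mean(precisions))


def _report_from_folds(
    folds: list[tuple[str, np.ndarray]], seed: int | None
) -> EvalReport:
    aggregate = np.sum([cm for _, cm in folds], axis=0)
    metrics = per_class_metrics(aggregate)
    w_rec, w_prec = working_status_summary(metrics)
    per_fold = []
    for fold_id, cm in folds:
        fm = per_class_metrics(cm)
        entry = {
            "fold": fold_id,
            "accuracy": fm["accuracy"],
            "mcc": multiclass_mcc(cm),
            "recall": fm["recall"],
            "precision": fm["precision"],
        }
        try:
            entry["working_recall"], entry["working_precision"] = working_status_summary(fm)
        except MissingWorkingClassError:
            entry["working_recall"] = entry["working_precision"] = None
        per_fold.append(entry)
    return EvalReport(
        confusion=aggregate,
        recall=metrics["recall"],
        precision=metrics["precision"],
        macro_f1=metrics["macro_f1"],
        accuracy=metrics["accuracy"],
        mcc=multiclass_mcc(aggregate),
        working_recall=w_rec,
        working_precision=w_prec,
        fold_ids=[fid for fid, _ in folds],
        per_fold=per_fold,
        seed=seed,
    )


def kfold_evaluate(
    config: ModelConfig,
    dataset: Dataset,
    k: int = 5,
    seed: int = 0,
    train_fn: TrainFn = train_classifier,
) -> EvalReport:
    """Stratified sample-level k-fold cross-validation.

    Folds are stratified by class and shuffled with ``seed``; subjects may
    span folds.  The aggregate confusion matrix is the sum over folds.
    """
    y = dataset.labels.astype(str)
    counts = {c: n for c, n in dataset.class_counts().items() if n > 0}
    thin = [c for c, n in counts.items() if n < k]
    if thin:
        raise TooFewSamplesError(f"classes {thin} have fewer than k={k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        model = train_fn(config, dataset.subset(train_idx))
        pred = model.predict_label_batch(dataset.X[test_idx])
        folds.append((f"fold{i + 1}", confusion_from_predictions(y[test_idx], pred)))
    return _report_from_folds(folds, seed)


def leave_one_subject_out_evaluate(
    config: ModelConfig,
    dataset: Dataset,
    train_fn: TrainFn = train_classifier,
) -> EvalReport:
    """One fold per subject; the fold's model never sees that subject."""
    subjects = dataset.subject_ids()
    if len(subjects) < 2:
        raise SingleSubjectError("leave-one-subject-out needs at least 2 subjects")
    folds = []
    for subject in subjects:
        test_mask = dataset.subjects == subject
        model = train_fn(config, dataset.subset(~test_mask))
        pred = model.predict_label_batch(dataset.X[test_mask])
        folds.append((str(subject), confusion_from_predictions(
            dataset.labels[test_mask].astype(str), pred)))
    return _report_from_folds(folds, config.seed)
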