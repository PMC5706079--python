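"""Evaluation metrics and resampling protocols.

Metrics: accuracy, sensitivity (true-positive rate), specificity
(true-negative rate), Matthews correlation coefficient (MCC), and the
threshold-free ranking metrics auROC and auPR.  Ratios with a zero
denominator are reported as 0 with a ``degenerate`` flag (MCC's denominator
in particular is undefined when any marginal is empty).

Protocols: stratified k-fold cross-validation (default k = 10, shuffled by
seed) and the jack-knife (leave-one-out) test.  Aggregate metrics are
computed from the pooled out-of-fold predictions — the canonical numbers —
and the per-fold means are emitted alongside, since the two conventions can
differ slightly.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import classify
from .classify import ClassifierSpec
from .exceptions import InvalidInputError, UndefinedMetricError
from .features import LabeledDataset


class Protocol(str, enum.Enum):
    KFOLD = "KFOLD"
    JACKKNIFE = "JACKKNIFE"
    HOLDOUT = "HOLDOUT"


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidInputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


@dataclass
class MetricBundle:
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    degenerate: bool = False


@dataclass
class EvaluationReport:
    protocol: Protocol
    per_fold: list[MetricBundle]
    aggregate: MetricBundle
    auroc: float
    aupr: float
    fold_assignments: dict[str, int]
    seed: int | None
    pooled_counts: ConfusionCounts
    fold_mean: MetricBundle | None = None
    degenerate_rounds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["protocol"] = self.protocol.value
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def confusion(labels, predictions) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from binary label and prediction vectors."""
    y = np.asarray(labels, dtype=np.int64)
    p = np.asarray(predictions, dtype=np.int64)
    if y.shape != p.shape or y.size < 1:
        raise InvalidInputError(
            f"labels ({y.shape}) and predictions ({p.shape}) must be equal-length, non-empty"
        )
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def _ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def metrics(cc: ConfusionCounts) -> MetricBundle:
    """Accuracy, sensitivity, specificity and MCC from confusion counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero
    denominator yields MCC = 0 with the degenerate flag set.
    """
    if cc.total == 0:
        raise InvalidInputError("cannot compute metrics on zero evaluated instances")
    acc = (cc.tp + cc.tn) / cc.total
    sens, d1 = _ratio(cc.tp, cc.tp + cc.fn)
    spec, d2 = _ratio(cc.tn, cc.tn + cc.fp)
    den = math.sqrt(
        float(cc.tp + cc.fp) * (cc.tp + cc.fn) * (cc.tn + cc.fp) * (cc.tn + cc.fn)
    )
    if den == 0:
        mcc, d3 = 0.0, True
    else:
        mcc, d3 = (cc.tp * cc.tn - cc.fp * cc.fn) / den, False
    return MetricBundle(acc, sens, spec, mcc, degenerate=d1 or d2 or d3)


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise UndefinedMetricError(
            "ranking metrics require both classes among the labels"
        )


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; ties count as half-concordant
    (the Mann-Whitney rank-statistic convention)."""
    y = np.asarray(labels, dtype=np.int64)
    _check_two_classes(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve via step-wise summation."""
    y = np.asarray(labels, dtype=np.int64)
    _check_two_classes(y)
    return float(average_precision_score(y, np.asarray(scores, dtype=np.float64)))


def _subset(dataset: LabeledDataset, idx: np.ndarray) -> LabeledDataset:
    return LabeledDataset(
        instance_ids=[dataset.instance_ids[i] for i in idx],
        features=dataset.features[idx],
        labels=dataset.labels[idx],
        feature_group=dataset.feature_group,
        origin=dataset.origin,
    )


def _run_rounds(
    dataset: LabeledDataset,
    spec: ClassifierSpec,
    splits: list[tuple[np.ndarray, np.ndarray]],
    protocol: Protocol,
    seed: int | None,
) -> EvaluationReport:
    n = dataset.n
    pooled_scores = np.empty(n, dtype=np.float64)
    pooled_preds = np.empty(n, dtype=np.int64)
    fold_assignments: dict[str, int] = {}
    per_fold: list[MetricBundle] = []
    degenerate_rounds: list[int] = []

    for fold, (train_idx, test_idx) in enumerate(splits):
        train_labels = dataset.labels[train_idx]
        if np.unique(train_labels).size < 2:
            # Degenerate round: fall back to the training majority class.
            degenerate_rounds.append(fold)
            majority = int(np.bincount(train_labels, minlength=2).argmax())
            pooled_preds[test_idx] = majority
            pooled_scores[test_idx] = spec.threshold if majority == 1 else spec.threshold - 1.0
        else:
            model = classify.train(_subset(dataset, train_idx), spec)
            scores = classify.decision_scores(model, dataset.features[test_idx])
            pooled_scores[test_idx] = scores
            pooled_preds[test_idx] = (scores >= spec.threshold).astype(np.int64)
        for i in test_idx:
            fold_assignments[dataset.instance_ids[i]] = fold
        if len(test_idx) > 0:
            per_fold.append(metrics(confusion(dataset.labels[test_idx], pooled_preds[test_idx])))

    pooled_cc = confusion(dataset.labels, pooled_preds)
    aggregate = metrics(pooled_cc)
    auroc = roc_auc(pooled_scores, dataset.labels)
    aupr = pr_auc(pooled_scores, dataset.labels)
    fold_mean = MetricBundle(
        accuracy=float(np.mean([b.accuracy for b in per_fold])),
        sensitivity=float(np.mean([b.sensitivity for b in per_fold])),
        specificity=float(np.mean([b.specificity for b in per_fold])),
        mcc=float(np.mean([b.mcc for b in per_fold])),
        degenerate=any(b.degenerate for b in per_fold),
    )
    return EvaluationReport(
        protocol=protocol,
        per_fold=per_fold,
        aggregate=aggregate,
        auroc=auroc,
        aupr=aupr,
        fold_assignments=fold_assignments,
        seed=seed,
        pooled_counts=pooled_cc,
        fold_mean=fold_mean,
        degenerate_rounds=degenerate_rounds,
    )


def kfold_cv(
    dataset: LabeledDataset, spec: ClassifierSpec, k: int = 10, seed: int = 0
) -> EvaluationReport:
    """Stratified k-fold cross-validation (each instance tested exactly once).

    Folds are shuffled by ``seed``; standardization and model fitting happen
    inside each training fold.  Requires at least k members per class.
    """
    counts = np.bincount(dataset.labels, minlength=2)
    if k < 2 or k > counts.min():
        raise InvalidInputError(
            f"k={k} must be between 2 and the smaller class size ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = [
        (tr, te) for tr, te in skf.split(dataset.features, dataset.labels)
    ]
    return _run_rounds(dataset, spec, splits, Protocol.KFOLD, seed)


def jackknife(dataset: LabeledDataset, spec: ClassifierSpec) -> EvaluationReport:
    """Leave-one-out test: n rounds, each holding out exactly one instance.

    Deterministic — there is no fold randomness.  Rounds whose training set
    collapses to a single class are flagged and scored by majority vote.
    """
    n = dataset.n
    if n < 3:
        raise InvalidInputError(f"jackknife requires n >= 3, got n={n}")
    all_idx = np.arange(n)
    splits = [(np.delete(all_idx, i), np.array([i])) for i in range(n)]
    return _run_rounds(dataset, spec, splits, Protocol.JACKKNIFE, seed=None)


def holdout(
    train_set: LabeledDataset, test_set: LabeledDataset, spec: ClassifierSpec
) -> EvaluationReport:
    """Train on one dataset, evaluate on an independent one."""
    if train_set.feature_group != test_set.feature_group:
        raise InvalidInputError("train and test feature groups differ")
    model = classify.train(train_set, spec)
    scores = classify.decision_scores(model, test_set.features)
    preds = (scores >= spec.threshold).astype(np.int64)
    cc = confusion(test_set.labels, preds)
    bundle = metrics(cc)
    return EvaluationReport(
        protocol=Protocol.HOLDOUT,
        per_fold=[bundle],
        aggregate=bundle,
        auroc=roc_auc(scores, test_set.labels),
        aupr=pr_auc(scores, test_set.labels),
        fold_assignments={i: 0 for i in test_set.instance_ids},
        seed=spec.seed,
        pooled_counts=cc,
        fold_mean=bundle,
    )


def roc_curve_points(scores, labels) -> np.ndarray:
    """(FPR, TPR) pairs for plotting; rows sorted by threshold sweep."""
    from sklearn.metrics import roc_curve as _roc

    fpr, tpr, _ = _roc(np.asarray(labels), np.asarray(scores))
    return np.column_stack([fpr, tpr])


def pr_curve_points(scores, labels) -> np.ndarray:
    """(recall, precision) pairs for plotting."""
    from sklearn.metrics import precision_recall_curve as _prc

    prec, rec, _ = _prc(np.asarray(labels), np.asarray(scores))
    return np.column_stack([rec, prec])
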