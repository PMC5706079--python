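"""Classifiers over profile-feature datasets.

The core predictor is a maximum-margin classifier (soft-margin SVM) with a
linear or RBF kernel; Random Forest and AdaBoost are provided as ensemble
comparators.  Training and prediction are thin, contract-checked wrappers
around scikit-learn estimators.

Defaults: C = 1.0 for both SVM kernels, RBF width by the "scale" rule
(gamma = 1 / (d * Var(X))), 100 estimators for the ensembles, feature
standardization ON for SVMs and OFF for the tree ensembles.  Standardization
is fitted inside the pipeline, hence on training folds only during
cross-validation — never on held-out data.

SVM scores are signed margins (decision-function values); ensemble scores are
positive-class probabilities.  A score exactly at the threshold (0 for
margins, 0.5 for probabilities) is assigned to the positive class.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import InvalidInputError, ModelFormatError, UntrainableError
from .features import FeatureGroup, FeatureVector, LabeledDataset, feature_names
from .profile_io import Origin

FORMAT_VERSION = "profgram-model-1"


class Algorithm(str, enum.Enum):
    SVM_LINEAR = "SVM_LINEAR"
    SVM_RBF = "SVM_RBF"
    RANDOM_FOREST = "RANDOM_FOREST"
    ADABOOST = "ADABOOST"


class Scaling(str, enum.Enum):
    NONE = "NONE"
    STANDARDIZE = "STANDARDIZE"


class ScoreKind(str, enum.Enum):
    MARGIN = "MARGIN"  # decision threshold 0
    PROBABILITY = "PROBABILITY"  # decision threshold 0.5


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm + hyperparameters; ``scaling=None`` picks the per-algorithm
    default (standardize for SVMs, none for tree ensembles)."""

    algorithm: Algorithm = Algorithm.SVM_LINEAR
    C: float = 1.0
    gamma: float | str = "scale"
    n_estimators: int = 100
    seed: int = 0
    scaling: Scaling | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "algorithm", Algorithm(self.algorithm))
        if self.scaling is not None:
            object.__setattr__(self, "scaling", Scaling(self.scaling))
        if self.C <= 0:
            raise InvalidInputError(f"C must be positive, got {self.C}")
        if isinstance(self.gamma, str):
            if self.gamma != "scale":
                raise InvalidInputError(f"gamma must be positive or 'scale', got {self.gamma!r}")
        elif self.gamma <= 0:
            raise InvalidInputError(f"gamma must be positive, got {self.gamma}")
        if self.n_estimators < 1:
            raise InvalidInputError("n_estimators must be a positive integer")

    @property
    def effective_scaling(self) -> Scaling:
        if self.scaling is not None:
            return self.scaling
        if self.algorithm in (Algorithm.SVM_LINEAR, Algorithm.SVM_RBF):
            return Scaling.STANDARDIZE
        return Scaling.NONE

    @property
    def score_kind(self) -> ScoreKind:
        if self.algorithm in (Algorithm.SVM_LINEAR, Algorithm.SVM_RBF):
            return ScoreKind.MARGIN
        return ScoreKind.PROBABILITY

    @property
    def threshold(self) -> float:
        return 0.0 if self.score_kind is ScoreKind.MARGIN else 0.5

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm.value,
            "C": self.C,
            "gamma": self.gamma,
            "n_estimators": self.n_estimators,
            "seed": self.seed,
            "scaling": self.effective_scaling.value,
        }


@dataclass
class TrainedModel:
    spec: ClassifierSpec
    feature_group: FeatureGroup
    origin: Origin
    estimator: Pipeline  # fitted
    training_fingerprint: str
    format_version: str = FORMAT_VERSION
    feature_columns: list[str] = field(default_factory=list)


@dataclass
class Prediction:
    instance_id: str
    label: int
    score: float
    score_kind: ScoreKind


def _build_estimator(spec: ClassifierSpec) -> Pipeline:
    alg = spec.algorithm
    if alg is Algorithm.SVM_LINEAR:
        clf = SVC(kernel="linear", C=spec.C, random_state=spec.seed)
    elif alg is Algorithm.SVM_RBF:
        clf = SVC(kernel="rbf", C=spec.C, gamma=spec.gamma, random_state=spec.seed)
    elif alg is Algorithm.RANDOM_FOREST:
        clf = RandomForestClassifier(n_estimators=spec.n_estimators, random_state=spec.seed)
    else:
        clf = AdaBoostClassifier(n_estimators=spec.n_estimators, random_state=spec.seed)
    steps = []
    if spec.effective_scaling is Scaling.STANDARDIZE:
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", clf))
    return Pipeline(steps)


def _fingerprint(dataset: LabeledDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.features).tobytes())
    h.update(np.ascontiguousarray(dataset.labels).tobytes())
    return h.hexdigest()


def train(dataset: LabeledDataset, spec: ClassifierSpec) -> TrainedModel:
    """Fit the specified classifier; deterministic given (dataset, spec, seed)."""
    classes = np.unique(dataset.labels)
    if classes.size < 2:
        raise UntrainableError(
            f"training set contains a single class ({classes.tolist()})"
        )
    est = _build_estimator(spec)
    est.fit(dataset.features, dataset.labels)
    return TrainedModel(
        spec=spec,
        feature_group=dataset.feature_group,
        origin=dataset.origin,
        estimator=est,
        training_fingerprint=_fingerprint(dataset),
        feature_columns=feature_names(dataset.feature_group),
    )


def decision_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Continuous scores: signed margins for SVMs, P(class 1) for ensembles."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != len(model.feature_columns):
        raise InvalidInputError(
            f"feature matrix has dimension {X.shape[1] if X.ndim == 2 else X.ndim}, "
            f"model {model.feature_group} expects {len(model.feature_columns)}"
        )
    if model.spec.score_kind is ScoreKind.MARGIN:
        return model.estimator.decision_function(X)
    return model.estimator.predict_proba(X)[:, 1]


def predict(
    model: TrainedModel, data: LabeledDataset | FeatureVector | Sequence[FeatureVector]
) -> list[Prediction]:
    """Predict labels + scores, one Prediction per instance, in input order.

    Scores at the threshold exactly are labelled positive.
    """
    if isinstance(data, FeatureVector):
        data = [data]
    if isinstance(data, LabeledDataset):
        if data.feature_group != model.feature_group:
            raise InvalidInputError(
                f"dataset feature group {data.feature_group.value} does not match "
                f"model feature group {model.feature_group.value}"
            )
        ids = list(data.instance_ids)
        X = data.features
    else:
        for v in data:
            if v.group != model.feature_group:
                raise InvalidInputError(
                    f"{v.instance_id}: feature group {v.group.value} does not match "
                    f"model feature group {model.feature_group.value}"
                )
        ids = [v.instance_id for v in data]
        X = np.stack([v.values for v in data])
    scores = decision_scores(model, X)
    thr = model.spec.threshold
    kind = model.spec.score_kind
    return [
        Prediction(i, int(s >= thr), float(s), kind) for i, s in zip(ids, scores)
    ]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize the model as a single-file archive with a format version."""
    payload = {
        "format_version": model.format_version,
        "spec": model.spec.to_dict(),
        "feature_group": model.feature_group.value,
        "origin": model.origin,
        "feature_columns": model.feature_columns,
        "training_fingerprint": model.training_fingerprint,
        "estimator": model.estimator,
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedModel:
    """Load a model archive; refuses corrupt files or mismatched versions."""
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise ModelFormatError(f"{path}: cannot read model file ({exc})") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFormatError(f"{path}: not a profgram model archive")
    if payload["format_version"] != FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: format version {payload['format_version']!r} "
            f"does not match {FORMAT_VERSION!r}"
        )
    spec_d = dict(payload["spec"])
    spec = ClassifierSpec(
        algorithm=spec_d["algorithm"],
        C=spec_d["C"],
        gamma=spec_d["gamma"],
        n_estimators=spec_d["n_estimators"],
        seed=spec_d["seed"],
        scaling=spec_d["scaling"],
    )
    return TrainedModel(
        spec=spec,
        feature_group=FeatureGroup(payload["feature_group"]),
        origin=payload["origin"],
        estimator=payload["estimator"],
        training_fingerprint=payload["training_fingerprint"],
        format_version=payload["format_version"],
        feature_columns=list(payload["feature_columns"]),
    )


def tune(
    dataset: LabeledDataset,
    spec: ClassifierSpec,
    k: int = 3,
    C_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0),
    gamma_grid: Sequence[float | str] = ("scale", 1e-4, 1e-3, 1e-2, 1e-1, 1.0),
) -> ClassifierSpec:
    """Optional inner-CV grid search over C (and gamma for the RBF kernel).

    Off by default everywhere; returns a new spec with the selected values so
    reported numbers stay reproducible.
    """
    if spec.algorithm not in (Algorithm.SVM_LINEAR, Algorithm.SVM_RBF):
        return spec
    grid: dict[str, list] = {"clf__C": list(C_grid)}
    if spec.algorithm is Algorithm.SVM_RBF:
        grid["clf__gamma"] = list(gamma_grid)
    search = GridSearchCV(_build_estimator(spec), grid, cv=k, scoring="accuracy")
    search.fit(dataset.features, dataset.labels)
    best = search.best_params_
    return replace(
        spec, C=best["clf__C"], gamma=best.get("clf__gamma", spec.gamma)
    )
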