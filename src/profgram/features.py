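"""Monogram and bigram features from profile matrices.

Given a profile H (L rows, 20 amino-acid columns of substitution
probabilities), the two feature families are

* monogram:  m(j)   = (1/L)     * sum_{i=1..L}   H[i, j]          (20 values)
* bigram:    b(j,k) = (1/(L-1)) * sum_{i=1..L-1} H[i, j]*H[i+1, k] (400 values)

i.e. the per-column composition and the adjacent-position pair products.
Bigram entries are ordered row-major: b(1,1), b(1,2), ..., b(1,20), b(2,1),
..., b(20,20).  The combined vector is monogram followed by bigram (420).

No scaling or standardization happens here; any scaling is an explicit choice
of the classifier pipeline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InconsistentInputError, InvalidInputError
from .profile_io import CANONICAL_ALPHABET, Origin, ProfileMatrix


class FeatureGroup(str, enum.Enum):
    MONOGRAM = "MONOGRAM"
    BIGRAM = "BIGRAM"
    COMBINED = "COMBINED"


#: Vector length per feature group.
GROUP_DIMENSIONS = {
    FeatureGroup.MONOGRAM: 20,
    FeatureGroup.BIGRAM: 400,
    FeatureGroup.COMBINED: 420,
}


@dataclass
class FeatureVector:
    instance_id: str
    group: FeatureGroup
    origin: Origin
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        expected = GROUP_DIMENSIONS[FeatureGroup(self.group)]
        if self.values.shape[0] != expected:
            raise InvalidInputError(
                f"{self.instance_id}: {self.group} vector must have length "
                f"{expected}, got {self.values.shape[0]}"
            )
        if not np.isfinite(self.values).all():
            raise InvalidInputError(f"{self.instance_id}: non-finite feature value")


@dataclass
class LabeledDataset:
    """Feature matrix + binary labels (1 = DNA-binding) + instance ids."""

    instance_ids: list[str]
    features: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) in {0, 1}
    feature_group: FeatureGroup
    origin: Origin

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = self.features.shape[0]
        if len(self.instance_ids) != n or self.labels.shape[0] != n:
            raise InvalidInputError("ids, features and labels must have equal length")
        expected = GROUP_DIMENSIONS[FeatureGroup(self.feature_group)]
        if self.features.ndim != 2 or self.features.shape[1] != expected:
            raise InvalidInputError(
                f"feature matrix must be n x {expected} for {self.feature_group}"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise InvalidInputError("labels must be binary (0/1)")

    @property
    def n(self) -> int:
        return self.features.shape[0]


def monogram(M: ProfileMatrix) -> FeatureVector:
    """Column means of the profile: a 20-dimensional composition summary."""
    if M.length < 1:
        raise InvalidInputError(f"{M.sequence_id}: empty profile")
    return FeatureVector(M.sequence_id, FeatureGroup.MONOGRAM, M.origin, M.values.mean(axis=0))


def bigram(M: ProfileMatrix) -> FeatureVector:
    """Normalized adjacent-position pair products: a 400-dimensional vector.

    Entry (j, k) is ``sum_i H[i,j] * H[i+1,k] / (L-1)`` over i = 1..L-1,
    flattened row-major.  Requires L >= 2.
    """
    L = M.length
    if L < 2:
        raise InvalidInputError(f"{M.sequence_id}: bigram requires L >= 2, got L={L}")
    B = M.values[:-1].T @ M.values[1:] / (L - 1)
    return FeatureVector(M.sequence_id, FeatureGroup.BIGRAM, M.origin, B.ravel(order="C"))


def combine(mono: FeatureVector, bi: FeatureVector) -> FeatureVector:
    """Concatenate monogram and bigram (monogram block first) into a 420-vector."""
    if mono.group != FeatureGroup.MONOGRAM or bi.group != FeatureGroup.BIGRAM:
        raise InconsistentInputError(
            f"combine expects (MONOGRAM, BIGRAM), got ({mono.group}, {bi.group})"
        )
    if mono.instance_id != bi.instance_id or mono.origin != bi.origin:
        raise InconsistentInputError(
            f"cannot combine {mono.instance_id}/{mono.origin} with "
            f"{bi.instance_id}/{bi.origin}"
        )
    return FeatureVector(
        mono.instance_id,
        FeatureGroup.COMBINED,
        mono.origin,
        np.concatenate([mono.values, bi.values]),
    )


def extract(M: ProfileMatrix, group: FeatureGroup | str) -> FeatureVector:
    """Compute the requested feature vector for one profile."""
    group = FeatureGroup(group)
    if group is FeatureGroup.MONOGRAM:
        return monogram(M)
    if group is FeatureGroup.BIGRAM:
        return bigram(M)
    return combine(monogram(M), bigram(M))


def featurize_dataset(
    profiles: Sequence[ProfileMatrix],
    labels: Sequence[int],
    group: FeatureGroup | str,
) -> LabeledDataset:
    """Build a LabeledDataset by featurizing profiles in input order."""
    group = FeatureGroup(group)
    if len(profiles) == 0:
        raise InvalidInputError("cannot featurize an empty profile collection")
    if len(profiles) != len(labels):
        raise InvalidInputError(
            f"{len(profiles)} profiles but {len(labels)} labels"
        )
    origins = {p.origin for p in profiles}
    if len(origins) != 1:
        raise InconsistentInputError(f"mixed profile origins: {sorted(origins)}")
    vectors = [extract(p, group) for p in profiles]
    return LabeledDataset(
        instance_ids=[p.sequence_id for p in profiles],
        features=np.stack([v.values for v in vectors]),
        labels=np.asarray(labels, dtype=np.int64),
        feature_group=group,
        origin=origins.pop(),
    )


def feature_names(group: FeatureGroup | str) -> list[str]:
    """Canonical column headers: m_A..m_Y, then b_A_A..b_Y_Y row-major."""
    group = FeatureGroup(group)
    mono_names = [f"m_{a}" for a in CANONICAL_ALPHABET]
    bi_names = [f"b_{a}_{b}" for a in CANONICAL_ALPHABET for b in CANONICAL_ALPHABET]
    if group is FeatureGroup.MONOGRAM:
        return mono_names
    if group is FeatureGroup.BIGRAM:
        return bi_names
    return mono_names + bi_names


def group_for_dimension(d: int) -> FeatureGroup:
    for g, dim in GROUP_DIMENSIONS.items():
        if dim == d:
            return g
    raise InvalidInputError(f"no feature group has dimension {d}")


def write_features_tsv(dataset: LabeledDataset, path: str | Path) -> None:
    """Write instance_id, label, then feature columns as TSV (17 sig. digits)."""
    df = pd.DataFrame(dataset.features, columns=feature_names(dataset.feature_group))
    df.insert(0, "label", dataset.labels)
    df.insert(0, "instance_id", dataset.instance_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_features_tsv(
    path: str | Path, origin: Origin = "HMM"
) -> LabeledDataset:
    """Read a feature TSV written by :func:`write_features_tsv`.

    The feature group is inferred from the number of feature columns.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "instance_id" not in df.columns or "label" not in df.columns:
        raise InvalidInputError(f"{path}: missing instance_id/label columns")
    feats = df.drop(columns=["instance_id", "label"])
    group = group_for_dimension(feats.shape[1])
    return LabeledDataset(
        instance_ids=df["instance_id"].astype(str).tolist(),
        features=feats.to_numpy(dtype=np.float64),
        labels=df["label"].to_numpy(),
        feature_group=group,
        origin=origin,
    )
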