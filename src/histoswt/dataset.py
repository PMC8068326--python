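"""Labeled datasets, stratified k-fold splitting and training-set assembly.

Histology grading datasets are small and class-imbalanced, so model assessment
uses stratified k-fold cross-validation: each class is shuffled with a seeded
generator and dealt round-robin across folds, keeping per-class fold sizes
within one of each other.  The round-robin starting fold is offset by the
class's rank so that the leftover samples of different classes land in
different folds rather than piling up in fold 0.

Only training folds are augmented (seven geometric variants per image); the
test fold is left untouched.  Every sample carries provenance (``source_id``,
``transform_tag``) so train/test leakage can be audited at the source level.
"""

from __future__ import annotations

import json
import os
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import augment_seven

__all__ = [
    "GRADES",
    "Sample",
    "LabeledDataset",
    "FoldAssignment",
    "stratified_kfold",
    "build_training_set",
    "build_test_set",
    "assert_no_leakage",
    "labels_to_csv",
    "labels_from_csv",
]

#: Histological grades: well (I), moderately (II) and poorly (III) differentiated.
GRADES = ("I", "II", "III")


@dataclass(frozen=True)
class Sample:
    """One labeled image with provenance."""

    sample_id: str
    image: np.ndarray
    grade: str
    transform_tag: str = "original"
    source_id: str | None = None

    @property
    def origin(self) -> str:
        """Identifier of the original image this sample derives from."""
        return self.source_id if self.source_id is not None else self.sample_id


@dataclass
class LabeledDataset:
    """A list of graded samples."""

    samples: list[Sample] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def class_counts(self) -> dict[str, int]:
        return dict(Counter(s.grade for s in self.samples))

    @property
    def grades(self) -> list[str]:
        return [s.grade for s in self.samples]

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.samples[i] for i in indices])


@dataclass
class FoldAssignment:
    """Sample-to-fold map of a stratified k-fold split."""

    k: int
    fold_of: dict[str, int]
    seed: int

    def fold_indices(self, dataset: LabeledDataset, fold: int) -> list[int]:
        if not (0 <= fold < self.k):
            raise IndexError(f"fold index {fold} out of range [0, {self.k})")
        return [i for i, s in enumerate(dataset.samples) if self.fold_of[s.sample_id] == fold]

    def to_json(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            json.dump({"k": self.k, "seed": self.seed, "fold_of": self.fold_of}, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "FoldAssignment":
        with open(os.fspath(path)) as fh:
            d = json.load(fh)
        return cls(k=d["k"], fold_of=d["fold_of"], seed=d["seed"])


def stratified_kfold(dataset: LabeledDataset, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified k-fold assignment: seeded within-class shuffle + round-robin.

    Per class, fold sizes differ by at most one; the class's leftover samples
    are rotated across folds by class rank.  Raises if any class has fewer
    than ``k`` members.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    classes = sorted(set(dataset.grades))
    for rank, grade in enumerate(classes):
        idx = [i for i, s in enumerate(dataset.samples) if s.grade == grade]
        if len(idx) < k:
            raise ValueError(
                f"class {grade!r} has only {len(idx)} samples, fewer than k={k}"
            )
        order = rng.permutation(len(idx))
        for pos, j in enumerate(order):
            fold_of[dataset.samples[idx[j]].sample_id] = (pos + rank) % k
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed)


def build_training_set(
    dataset: LabeledDataset, folds: FoldAssignment, test_fold: int
) -> LabeledDataset:
    """Originals of all non-test folds plus their seven augmentations each.

    The result has exactly 8x the training-partition size; augmented samples
    inherit the grade of their source.  The test fold is never touched.
    """
    if not (0 <= test_fold < folds.k):
        raise IndexError(f"fold index {test_fold} out of range [0, {folds.k})")
    out: list[Sample] = []
    for s in dataset.samples:
        if folds.fold_of[s.sample_id] == test_fold:
            continue
        out.append(s)
        for aug in augment_seven(s.image, source_id=s.sample_id):
            out.append(
                Sample(
                    sample_id=f"{s.sample_id}__{aug.transform_tag}",
                    image=aug.pixels,
                    grade=s.grade,
                    transform_tag=aug.transform_tag,
                    source_id=s.sample_id,
                )
            )
    return LabeledDataset(out)


def build_test_set(dataset: LabeledDataset, folds: FoldAssignment, test_fold: int) -> LabeledDataset:
    """The untouched (never augmented) samples of one fold."""
    return dataset.subset(folds.fold_indices(dataset, test_fold))


def assert_no_leakage(train: LabeledDataset, test: LabeledDataset) -> None:
    """Raise if any source image contributes to both train and test."""
    shared = {s.origin for s in train} & {s.origin for s in test}
    if shared:
        raise RuntimeError(f"train/test leakage via source ids: {sorted(shared)[:5]}")


def labels_to_csv(dataset: LabeledDataset, path: str | os.PathLike,
                  folds: FoldAssignment | None = None,
                  paths: dict[str, str] | None = None) -> pd.DataFrame:
    """Write the provenance-bearing labels table: sample_id,path,grade,fold,transform_tag,source_id."""
    rows = []
    for s in dataset.samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "path": (paths or {}).get(s.sample_id, ""),
                "grade": s.grade,
                "fold": folds.fold_of.get(s.sample_id, -1) if folds else -1,
                "transform_tag": s.transform_tag,
                "source_id": s.origin,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(os.fspath(path), index=False)
    return df


def labels_from_csv(path: str | os.PathLike, load_images: bool = True) -> LabeledDataset:
    """Read a labels CSV (schema as written by :func:`labels_to_csv`)."""
    from .image import load_image

    df = pd.read_csv(os.fspath(path), keep_default_na=False)
    samples = []
    for row in df.itertuples(index=False):
        img = load_image(row.path) if load_images and row.path else np.zeros((2, 2, 3))
        src = row.source_id if row.source_id and row.source_id != row.sample_id else None
        samples.append(
            Sample(
                sample_id=str(row.sample_id),
                image=img,
                grade=str(row.grade),
                transform_tag=str(row.transform_tag) or "original",
                source_id=src,
            )
        )
    return LabeledDataset(samples)
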