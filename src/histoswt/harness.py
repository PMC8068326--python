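"""Model contracts, reference models and cross-validated experiment drivers.

Deep backbones (Xception, ResNet, MobileNetv2 as classifiers; DeepLabv3+ as
segmenter) are treated as *external plugins* behind :class:`ModelContract`;
their two-stage fine-tuning schedule and atrous/stride settings are carried as
serializable configuration (:class:`TrainSchedule`, :class:`SegConfig`) but
never executed here.  Lightweight built-in reference models make every
pipeline path — enhancement, augmentation, stratified CV, scoring — runnable
in seconds on one CPU:

* the reference classifier maps each image to subband-energy and intensity
  quantile features and fits a regularized multinomial logistic model;
* the reference segmenter classifies pixels from local intensity and
  detail-magnitude features with a smoothing vote.

Both are deterministic: refitting on identical data reproduces identical
outputs, which the drivers rely on for replayable reports.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .dataset import (
    GRADES,
    LabeledDataset,
    FoldAssignment,
    assert_no_leakage,
    build_test_set,
    build_training_set,
    stratified_kfold,
)
from .image import luminance
from .metrics import MetricReport, aggregate_folds, auc_macro, auc_micro, confusion, segmentation_suite
from .swt import MappingParams, enhance, extract_ll, swt_decompose

__all__ = [
    "ModelContract",
    "TrainSchedule",
    "SegConfig",
    "ReferenceClassifier",
    "ReferenceSegmenter",
    "reference_classifier",
    "reference_segmenter",
    "run_classification_cv",
    "run_segmentation_eval",
    "LL_PREPROCESS",
]


@dataclass(frozen=True)
class TrainSchedule:
    """Two-stage fine-tuning schedule carried as plugin configuration.

    Stage 1 trains only the newly added classification head; stage 2 unfreezes
    the backbone at a tenfold smaller learning rate.
    """

    stage1_lr: float = 1e-3
    stage2_lr: float = 1e-4
    lr_decay: float = 1e-6
    stage1_trainable: str = "head_only"
    stage2_trainable: str = "backbone_except_head"

    def __post_init__(self) -> None:
        if not (0 < self.stage2_lr < self.stage1_lr):
            raise ValueError("require 0 < stage2_lr < stage1_lr")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


@dataclass(frozen=True)
class SegConfig:
    """Atrous-pyramid segmentation settings, serialized into plugin configs."""

    atrous_rates: tuple[int, int, int] = (12, 24, 36)
    output_stride: int = 8
    decoder_output_stride: int = 4
    backbone: str = "xception_65"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


class ModelContract:
    """Interface every pluggable model implements.

    Classifiers provide ``fit`` and ``predict_scores`` (rows are probability
    vectors); segmenters provide ``fit_pairs`` and ``predict_mask``.  The
    ``deterministic`` flag advertises bit-reproducible refits; ``descriptor``
    identifies the backbone in reports.
    """

    deterministic: bool = False
    descriptor: str = "abstract"

    def clone(self) -> "ModelContract":
        raise NotImplementedError

    def fit(self, train: LabeledDataset) -> "ModelContract":
        raise NotImplementedError

    def predict_scores(self, images) -> np.ndarray:
        raise NotImplementedError

    def fit_pairs(self, pairs) -> "ModelContract":
        raise NotImplementedError

    def predict_mask(self, image) -> np.ndarray:
        raise NotImplementedError


def _classifier_features(image: np.ndarray, wavelet: str) -> np.ndarray:
    """Per-image feature vector: subband energies, coefficient tails, quantiles."""
    lum = luminance(np.asarray(image, dtype=np.float64))
    bands = swt_decompose(lum, wavelet)
    feats = []
    for plane in (bands.lh, bands.hl, bands.hh):
        a = np.abs(plane)
        feats += [np.mean(plane**2), np.mean(a), np.quantile(a, 0.99), np.max(a)]
    feats += [bands.ll.mean(), bands.ll.std()]
    feats += list(np.quantile(lum, [0.05, 0.25, 0.5, 0.75, 0.95]))
    feats += [image[:, :, c].mean() for c in range(3)]
    return np.array(feats)


class ReferenceClassifier(ModelContract):
    """Subband-energy + quantile features with a regularized linear softmax fit."""

    deterministic = True

    def __init__(self, wavelet: str = "db2", C: float = 1.0):
        self.wavelet = wavelet
        self.C = C
        self.descriptor = f"reference-classifier({wavelet}, C={C})"
        self._pipe = None
        self._classes: list[str] = []

    def clone(self) -> "ReferenceClassifier":
        return ReferenceClassifier(self.wavelet, self.C)

    def _features(self, images) -> np.ndarray:
        return np.vstack([_classifier_features(img, self.wavelet) for img in images])

    def fit(self, train: LabeledDataset) -> "ReferenceClassifier":
        grades = sorted(set(train.grades))
        if len(grades) < 2:
            raise ValueError("training set contains a single class")
        self._classes = grades
        x = self._features([s.image for s in train])
        y = np.array([grades.index(g) for g in train.grades])
        self._pipe = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=self.C, max_iter=2000, tol=1e-8),
        )
        self._pipe.fit(x, y)
        return self

    def predict_scores(self, images) -> np.ndarray:
        if self._pipe is None:
            raise RuntimeError("fit before predict_scores")
        return self._pipe.predict_proba(self._features(images))

    @property
    def classes(self) -> list[str]:
        return self._classes


def _pixel_features(image: np.ndarray) -> np.ndarray:
    """Per-pixel feature stack: intensity, local mean/std, detail magnitudes."""
    lum = luminance(np.asarray(image, dtype=np.float64))
    bands = swt_decompose(lum, "haar")
    local_mean = ndimage.uniform_filter(lum, 5)
    local_sq = ndimage.uniform_filter(lum**2, 5)
    local_std = np.sqrt(np.maximum(local_sq - local_mean**2, 0.0))
    detail = np.abs(bands.lh) + np.abs(bands.hl) + np.abs(bands.hh)
    detail_s = ndimage.uniform_filter(detail, 5)
    h, w = lum.shape
    planes = [lum, local_mean, local_std, detail_s[:h, :w]]
    return np.stack([p.ravel() for p in planes], axis=1)


class ReferenceSegmenter(ModelContract):
    """Per-pixel logistic classifier on local features with a smoothing vote."""

    deterministic = True

    def __init__(self, C: float = 1.0, pixels_per_image: int = 1500, smooth: float = 1.5):
        self.C = C
        self.pixels_per_image = pixels_per_image
        self.smooth = smooth
        self.descriptor = f"reference-segmenter(C={C})"
        self._pipe = None

    def clone(self) -> "ReferenceSegmenter":
        return ReferenceSegmenter(self.C, self.pixels_per_image, self.smooth)

    def fit_pairs(self, pairs) -> "ReferenceSegmenter":
        xs, ys = [], []
        for i, (image, mask) in enumerate(pairs):
            feats = _pixel_features(image)
            labels = np.asarray(mask).ravel()
            # deterministic per-image subsample keeps training desk-scale
            rng = np.random.default_rng(i)
            take = rng.choice(len(labels), min(self.pixels_per_image, len(labels)),
                              replace=False)
            xs.append(feats[take])
            ys.append(labels[take])
        x = np.vstack(xs)
        y = np.concatenate(ys)
        if np.unique(y).size < 2:
            raise ValueError("training masks contain a single class")
        self._pipe = make_pipeline(
            StandardScaler(),
            LogisticRegression(C=self.C, max_iter=2000, tol=1e-8),
        )
        self._pipe.fit(x, y)
        return self

    def predict_mask(self, image) -> np.ndarray:
        if self._pipe is None:
            raise RuntimeError("fit_pairs before predict_mask")
        h, w = np.asarray(image).shape[:2]
        proba = self._pipe.predict_proba(_pixel_features(image))[:, 1].reshape(h, w)
        proba = ndimage.gaussian_filter(proba, self.smooth)
        return (proba >= 0.5).astype(np.int64)


def reference_classifier(wavelet: str = "db2") -> ReferenceClassifier:
    """Fresh built-in reference classifier contract."""
    return ReferenceClassifier(wavelet=wavelet)


def reference_segmenter() -> ReferenceSegmenter:
    """Fresh built-in reference segmenter contract."""
    return ReferenceSegmenter()


def _enhance_dataset(dataset: LabeledDataset, params: MappingParams) -> LabeledDataset:
    from .dataset import Sample

    return LabeledDataset(
        [
            Sample(s.sample_id, enhance(s.image, params), s.grade,
                   s.transform_tag, s.source_id)
            for s in dataset.samples
        ]
    )


def run_classification_cv(
    dataset: LabeledDataset,
    model: ModelContract,
    params: MappingParams | None = None,
    k: int = 5,
    seed: int = 0,
    folds: FoldAssignment | None = None,
) -> MetricReport:
    """Stratified k-fold grading experiment.

    Per fold: (optionally) enhance every image, augment the training partition
    only, fit a fresh model clone, and score the untouched test fold with
    macro- and micro-averaged one-vs-rest AUC.  A source-level leakage audit
    runs inside every fold.
    """
    if folds is None:
        folds = stratified_kfold(dataset, k=k, seed=seed)
    working = _enhance_dataset(dataset, params) if params is not None else dataset
    grades = sorted(set(working.grades))
    per_fold = []
    for fold in range(folds.k):
        train = build_training_set(working, folds, fold)
        test = build_test_set(working, folds, fold)
        assert_no_leakage(train, test)
        try:
            fitted = model.clone().fit(train)
            scores = fitted.predict_scores([s.image for s in test])
        except Exception as exc:  # noqa: BLE001 - annotate failing fold
            raise RuntimeError(f"classification failed in fold {fold}") from exc
        truth = np.array([grades.index(g) for g in test.grades])
        per_fold.append(
            {
                "auc_macro": auc_macro(truth, scores),
                "auc_micro": auc_micro(truth, scores),
            }
        )
    return aggregate_folds(per_fold)


#: Named LL-extraction preprocessing options for segmentation.
LL_PREPROCESS = {
    "none": None,
    "ll_haar": "haar",
    "ll_sym2": "sym2",
    "ll_db2": "db2",
    "ll_bior13": "bior1.3",
}


def run_segmentation_eval(
    pairs,
    segmenter: ModelContract,
    preprocess: str = "none",
    k: int = 5,
    seed: int = 0,
) -> MetricReport:
    """k-fold segmentation experiment over image/mask pairs.

    Per fold: optionally replace each image by its inverted-gray LL rendering,
    fit a fresh segmenter clone on the training pairs, predict test masks, and
    score pooled per-fold confusion counts with the segmentation suite.
    """
    if preprocess not in LL_PREPROCESS:
        raise ValueError(f"unknown preprocess {preprocess!r}; options: {sorted(LL_PREPROCESS)}")
    wavelet = LL_PREPROCESS[preprocess]
    if wavelet is not None:
        pairs = [(extract_ll(img, wavelet), mask) for img, mask in pairs]
    n = len(pairs)
    if n < k:
        raise ValueError(f"need at least k={k} pairs, got {n}")
    rng = np.random.default_rng(seed)
    fold_of = np.array([i % k for i in range(n)])[rng.permutation(n)]
    per_fold = []
    for fold in range(k):
        train = [pairs[i] for i in np.flatnonzero(fold_of != fold)]
        test = [pairs[i] for i in np.flatnonzero(fold_of == fold)]
        try:
            fitted = segmenter.clone().fit_pairs(train)
            preds = [fitted.predict_mask(img) for img, _ in test]
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"segmentation failed in fold {fold}") from exc
        cc = None
        for pred, (_, truth) in zip(preds, test):
            c = confusion(pred, truth, k=2)
            cc = c if cc is None else cc + c
        suite = segmentation_suite(cc)
        per_fold.append({name: suite[name] for name in
                         ("miou", "f1", "acc", "precision", "sensitivity", "specificity")})
    return aggregate_folds(per_fold)
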