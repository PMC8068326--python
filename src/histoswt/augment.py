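"""Geometric training-set augmentation.

Seven transforms per image, in a fixed canonical order: three anticlockwise
rotations, horizontal flip, horizontal flip followed by a 90-degree
anticlockwise rotation, vertical flip, and vertical flip followed by a
90-degree anticlockwise rotation.  Together with the identity these are the
eight elements of the square's symmetry group, so each transform permutes the
pixel grid and preserves per-channel intensity histograms exactly.

Conventions (documented because the underlying phrases are ambiguous):
"horizontal flip" mirrors left-right (across the vertical axis); in combined
transforms the flip is applied first, then the rotation.  Augmentation is for
training folds only — test samples are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TRANSFORM_TAGS", "AugmentedSample", "apply_transform", "augment_seven"]

#: Canonical order of the seven augmentation transforms.
TRANSFORM_TAGS = (
    "rot90",
    "rot180",
    "rot270",
    "hflip",
    "hflip_rot90",
    "vflip",
    "vflip_rot90",
)

_ALL_TAGS = TRANSFORM_TAGS + ("original",)


@dataclass(frozen=True)
class AugmentedSample:
    """An augmented image together with its provenance."""

    pixels: np.ndarray
    source_id: str
    transform_tag: str

    def __post_init__(self) -> None:
        if self.transform_tag not in _ALL_TAGS:
            raise ValueError(f"unknown transform_tag {self.transform_tag!r}")


def apply_transform(image: np.ndarray, tag: str) -> np.ndarray:
    """Apply one named transform; ``np.rot90`` rotates anticlockwise."""
    if tag == "original":
        return image.copy()
    if tag == "rot90":
        return np.rot90(image, 1).copy()
    if tag == "rot180":
        return np.rot90(image, 2).copy()
    if tag == "rot270":
        return np.rot90(image, 3).copy()
    if tag == "hflip":
        return image[:, ::-1].copy()
    if tag == "hflip_rot90":
        return np.rot90(image[:, ::-1], 1).copy()
    if tag == "vflip":
        return image[::-1].copy()
    if tag == "vflip_rot90":
        return np.rot90(image[::-1], 1).copy()
    raise ValueError(f"unknown transform_tag {tag!r}")


def augment_seven(image: np.ndarray, source_id: str = "unknown") -> list[AugmentedSample]:
    """The seven augmented variants of ``image``, in canonical order.

    The image must be square so that 90-degree rotations preserve its shape
    (labels and masks stay aligned).
    """
    image = np.asarray(image)
    if image.shape[0] != image.shape[1]:
        raise ValueError(
            f"augmentation requires a square image, got shape {image.shape[:2]}"
        )
    return [
        AugmentedSample(apply_transform(image, tag), source_id, tag)
        for tag in TRANSFORM_TAGS
    ]
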