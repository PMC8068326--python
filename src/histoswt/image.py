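"""Image loading, saving and validation.

All pipeline stages exchange RGB images as ``H x W x 3`` float64 arrays with
intensities in [0, 1].  Integer PNG/TIFF files (8- or 16-bit) are converted on
read and quantized back on write.
"""

from __future__ import annotations

import os

import numpy as np
import imageio.v3 as iio
import tifffile
from PIL import Image

__all__ = [
    "as_float01",
    "validate_image",
    "luminance",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
]

# Rec. 601 luma weights, the scikit-image rgb2gray convention
_LUMA = np.array([0.2125, 0.7154, 0.0721])

# palette for 2-class mask export: 0 = stroma (black), 1 = epithelium (red)
_MASK_PALETTE = [0, 0, 0, 255, 0, 0]


def as_float01(arr: np.ndarray) -> np.ndarray:
    """Convert an integer or float image array to float64 in [0, 1]."""
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    out = arr.astype(np.float64)
    if out.size and (out.min() < 0.0 or out.max() > 1.0):
        raise ValueError("float image intensities must lie in [0, 1]")
    return out


def validate_image(image: np.ndarray, name: str = "image") -> np.ndarray:
    """Check that ``image`` is a finite H x W x 3 float array in [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"{name} must have shape (H, W, 3), got {image.shape}")
    if not np.isfinite(image).all():
        raise ValueError(f"{name} contains non-finite values")
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError(f"{name} intensities must lie in [0, 1]")
    return image


def luminance(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance plane of an RGB image."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    return image @ _LUMA


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/TIFF image as H x W x 3 float in [0, 1]."""
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = as_float01(arr)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr


def save_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write an RGB float image as 8-bit PNG or 16-bit TIFF by extension."""
    image = validate_image(image)
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, np.round(image * 65535).astype(np.uint16))
    else:
        iio.imwrite(path, np.round(image * 255).astype(np.uint8))


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read an indexed-PNG label mask as an integer H x W array."""
    with Image.open(os.fspath(path)) as im:
        return np.asarray(im, dtype=np.int64)


def save_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a 2-class label mask as indexed PNG (0 black = stroma, 1 red = epithelium)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    im.putpalette(_MASK_PALETTE)
    im.save(os.fspath(path))
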