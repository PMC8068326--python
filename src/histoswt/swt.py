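"""One-level stationary wavelet transform (SWT) enhancement.

The enhancement used as classification preprocessing is the composition

    decompose -> map detail coefficients -> reconstruct

where the mapping is the cubic polynomial

    y = a*w**3 + b*w**2 + c*w + d

applied elementwise to the signed detail coefficients (LH, HL, HH) of each RGB
channel, while the approximation (LL) subband is left untouched.  Because the
transform is undecimated, every subband retains the input's spatial shape and
the enhancement is shift-invariant.

Segmentation preprocessing instead keeps only the low-frequency content: the
LL subband of the luminance image, min-max rescaled and rendered through an
inverted gray map (large coefficient -> dark).

Images are normalized to [0, 1] before decomposition, so with the ``norm=True``
(orthonormal-filter) convention the coefficients are order-unity and the small
polynomial constants act on a meaningful scale.  Boundary handling is periodic,
which makes reconstruction exact to machine precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt

from .image import luminance, validate_image

__all__ = [
    "SUPPORTED_WAVELETS",
    "MappingParams",
    "SubbandSet",
    "IDENTITY_PARAMS",
    "REFERENCE_TUNED_PARAMS",
    "swt_decompose",
    "map_coefficients",
    "swt_reconstruct",
    "enhance",
    "enhance_batch",
    "extract_ll",
    "detail_energy",
]

SUPPORTED_WAVELETS = ("haar", "sym2", "db2", "bior1.3")


@dataclass(frozen=True)
class MappingParams:
    """Constants of the cubic detail-coefficient mapping plus the wavelet name.

    Tuned values produced by the optimizer satisfy a, b, c in [0, 0.1] and
    d in [0.001, 1]; arbitrary finite values are accepted for direct use.
    """

    a: float
    b: float
    c: float
    d: float
    wavelet: str = "db2"

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"mapping constant {name} must be finite, got {v!r}")
        if self.wavelet not in SUPPORTED_WAVELETS:
            raise ValueError(
                f"unsupported wavelet {self.wavelet!r}; choose from {SUPPORTED_WAVELETS}"
            )

    def __call__(self, w: np.ndarray) -> np.ndarray:
        """Evaluate the cubic mapping elementwise (Horner form)."""
        w = np.asarray(w, dtype=np.float64)
        return ((self.a * w + self.b) * w + self.c) * w + self.d


#: Mapping that leaves every coefficient unchanged.
IDENTITY_PARAMS = MappingParams(a=0.0, b=0.0, c=1.0, d=0.0, wavelet="db2")

#: Best-known tuned constants for histology enhancement (db2 wavelet).
REFERENCE_TUNED_PARAMS = MappingParams(a=0.0091, b=0.0301, c=0.0086, d=0.3444, wavelet="db2")


@dataclass
class SubbandSet:
    """Per-channel one-level undecimated subband planes.

    ``ll`` holds the approximation coefficients; ``lh``, ``hl`` and ``hh`` the
    horizontal, vertical and diagonal detail coefficients.  All planes share
    the (possibly internally padded) spatial shape; ``original_shape`` records
    the pre-padding image shape so reconstruction can crop back.
    """

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray
    wavelet: str
    original_shape: tuple[int, int]
    level: int = 1
    boundary_mode: str = "periodization"

    def __post_init__(self) -> None:
        shapes = {self.ll.shape, self.lh.shape, self.hl.shape, self.hh.shape}
        if len(shapes) != 1:
            raise ValueError(f"subband planes disagree in shape: {sorted(shapes)}")
        if self.wavelet not in SUPPORTED_WAVELETS:
            raise ValueError(f"unsupported wavelet {self.wavelet!r}")
        if self.level != 1:
            raise ValueError("only one-level decomposition is supported")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ll.shape


def _pad_even(plane: np.ndarray) -> np.ndarray:
    """Pad odd spatial dimensions to even length by edge replication."""
    ph = plane.shape[0] % 2
    pw = plane.shape[1] % 2
    if ph or pw:
        plane = np.pad(plane, [(0, ph), (0, pw)] + [(0, 0)] * (plane.ndim - 2), mode="edge")
    return plane


def _swt2_planes(plane: np.ndarray, wavelet: str):
    with warnings.catch_warnings():
        # bior1.3 filters are biorthogonal, not orthogonal; reconstruction is
        # still exact under norm=True, pywt merely notes energy is not preserved
        warnings.simplefilter("ignore", UserWarning)
        (ll, (lh, hl, hh)), = pywt.swt2(plane, wavelet, level=1, norm=True)
    return ll, lh, hl, hh


def swt_decompose(image: np.ndarray, wavelet: str = "db2") -> SubbandSet:
    """One-level undecimated 2-D wavelet decomposition of each RGB channel.

    Parameters
    ----------
    image : ndarray, shape (H, W, 3) or (H, W)
        Intensities in [0, 1].  Odd dimensions are padded internally and the
        original shape is recorded for cropping after reconstruction.
    wavelet : {"haar", "sym2", "db2", "bior1.3"}

    Returns
    -------
    SubbandSet with planes shaped like the (padded) input.
    """
    if wavelet not in SUPPORTED_WAVELETS:
        raise ValueError(f"unsupported wavelet {wavelet!r}; choose from {SUPPORTED_WAVELETS}")
    image = np.asarray(image, dtype=np.float64)
    gray = image.ndim == 2
    if gray:
        image = image[:, :, None]
    original_shape = image.shape[:2]
    image = _pad_even(image)
    bands = [np.empty_like(image) for _ in range(4)]
    for ch in range(image.shape[2]):
        for band, plane in zip(bands, _swt2_planes(image[:, :, ch], wavelet)):
            band[:, :, ch] = plane
    if gray:
        bands = [b[:, :, 0] for b in bands]
    return SubbandSet(*bands, wavelet=wavelet, original_shape=original_shape)


def map_coefficients(bands: SubbandSet, params: MappingParams) -> SubbandSet:
    """Apply the cubic mapping to the detail subbands only.

    The LH, HL and HH planes are replaced by ``a*w**3 + b*w**2 + c*w + d``
    evaluated on the signed coefficients; the LL plane is returned unchanged
    (same array, bit-identical).
    """
    return replace(bands, lh=params(bands.lh), hl=params(bands.hl), hh=params(bands.hh))


def swt_reconstruct(bands: SubbandSet) -> np.ndarray:
    """Inverse undecimated transform; crops any internal padding, clips to [0, 1]."""
    ll = np.asarray(bands.ll, dtype=np.float64)
    gray = ll.ndim == 2
    planes = [bands.ll, bands.lh, bands.hl, bands.hh]
    if gray:
        planes = [p[:, :, None] for p in planes]
    ll, lh, hl, hh = planes
    out = np.empty_like(ll)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for ch in range(ll.shape[2]):
            coeffs = [(ll[:, :, ch], (lh[:, :, ch], hl[:, :, ch], hh[:, :, ch]))]
            out[:, :, ch] = pywt.iswt2(coeffs, bands.wavelet, norm=True)
    h, w = bands.original_shape
    out = out[:h, :w]
    if gray:
        out = out[:, :, 0]
    return np.clip(out, 0.0, 1.0)


def enhance(image: np.ndarray, params: MappingParams) -> np.ndarray:
    """Full enhancement: decompose, map detail coefficients, reconstruct."""
    image = validate_image(image)
    bands = swt_decompose(image, params.wavelet)
    return swt_reconstruct(map_coefficients(bands, params))


def enhance_batch(images, params: MappingParams) -> list:
    """Enhance a sequence of images, preserving order."""
    return [enhance(img, params) for img in images]


def extract_ll(image: np.ndarray, wavelet: str = "haar") -> np.ndarray:
    """Low-frequency (LL) rendering used as segmentation preprocessing.

    The image is converted to luminance, decomposed one level, and the LL
    plane is min-max rescaled and passed through an inverted gray map: the
    smallest coefficient renders white, the largest black.  A constant LL
    plane (zero dynamic range) renders uniform mid-gray.  The result is
    replicated to 3 channels and has the input's spatial shape.
    """
    image = validate_image(image)
    bands = swt_decompose(luminance(image), wavelet)
    h, w = bands.original_shape
    ll = bands.ll[:h, :w]
    span = ll.max() - ll.min()
    if span == 0.0:
        rendered = np.full_like(ll, 0.5)
    else:
        rendered = 1.0 - (ll - ll.min()) / span
    return np.repeat(rendered[:, :, None], 3, axis=2)


def detail_energy(image: np.ndarray, wavelet: str = "db2") -> float:
    """Total squared detail-coefficient energy of the luminance image."""
    bands = swt_decompose(luminance(np.asarray(image, dtype=np.float64)), wavelet)
    return float(np.sum(bands.lh**2) + np.sum(bands.hl**2) + np.sum(bands.hh**2))
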