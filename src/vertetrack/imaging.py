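"""Frame loading and the preprocessing chain.

The chain applied to each fluoroscopic frame, in order: contrast normalization
(linear stretch to the full 8-bit range), histogram equalization (classic
256-bin CDF remap), Canny edge detection, and threshold binarization. Edge maps
feed annotation snapping; binarized region maps are the default substrate for
template tracking.

All operations accept either an :class:`ImageFrame` or a bare 2-D uint8 array
and return the kind they were given (arrays make tiny worked examples and tests
convenient; the strict size invariant is enforced where real data enters, in
the loaders).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import feature as _skfeature
from skimage import filters as _skfilters

from .errors import ParameterError

__all__ = [
    "ImageFrame",
    "BinaryMap",
    "normalize_contrast",
    "equalize_histogram",
    "canny_edges",
    "binarize",
    "otsu_threshold",
    "load_frame",
    "load_frames",
]

log = logging.getLogger(__name__)

MIN_FRAME_SIDE = 32  # real frames must be at least this big on each side


@dataclass(frozen=True)
class ImageFrame:
    """One grayscale frame of the time-ordered sequence, intensities in [0, 255]."""

    pixels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 2:
            raise ParameterError(f"frame pixels must be 2-D, got shape {p.shape}")
        if p.dtype != np.uint8:
            raise ParameterError(f"frame pixels must be uint8, got {p.dtype}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BinaryMap:
    """A {0,1} map with the shape of its source frame."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 2:
            raise ParameterError(f"binary map must be 2-D, got shape {p.shape}")
        if p.dtype != np.uint8:
            raise ParameterError(f"binary map must be uint8, got {p.dtype}")
        # cheap exactness check: max of a {0,1} array is <= 1
        if p.size and int(p.max()) > 1:
            raise ParameterError("binary map contains values other than 0/1")


def _pix(img) -> np.ndarray:
    return img.pixels if isinstance(img, (ImageFrame, BinaryMap)) else np.asarray(img)


def _like(src, arr: np.ndarray):
    if isinstance(src, ImageFrame):
        return ImageFrame(arr, src.frame_index)
    return arr


def normalize_contrast(frame):
    """Linear contrast stretch so the minimum maps to 0 and the maximum to 255.

    The stretch is computed in float and truncated back to uint8. A constant
    image cannot be stretched and is returned unchanged with a logged warning.
    """
    p = _pix(frame)
    lo, hi = int(p.min()), int(p.max())
    if hi == lo:
        log.warning("normalize_contrast: constant image, returned unchanged")
        return _like(frame, p.copy())
    # multiply before dividing: (v - lo) * 255 is exact in float64, so the
    # endpoints land on exactly 0.0 and 255.0 before truncation
    out = ((p.astype(np.float64) - lo) * 255.0 / (hi - lo)).astype(np.uint8)
    return _like(frame, out)


def equalize_histogram(frame):
    """Classic 256-bin histogram equalization by CDF remapping.

    ``mapped(v) = round(255 * (cdf(v) - cdf_min) / (N - cdf_min))`` where ``N``
    is the pixel count and ``cdf_min`` the first nonzero CDF value. Monotone in
    the input intensity. A constant image is its own fixed point and is
    returned unchanged.
    """
    p = _pix(frame)
    hist = np.bincount(p.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    cdf_min = int(cdf[np.nonzero(hist)[0][0]])
    n = p.size
    if cdf_min == n:  # single intensity level
        return _like(frame, p.copy())
    lut = np.floor((cdf - cdf_min) * (255.0 / (n - cdf_min)) + 0.5)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return _like(frame, lut[p])


def canny_edges(frame, low: float = 50.0, high: float = 150.0, *, sigma: float = 1.4) -> BinaryMap:
    """Canny edge detection; 1-pixels are thin non-maximum-suppressed edges.

    ``low`` and ``high`` are the hysteresis thresholds on the Sobel gradient
    magnitude of the Gaussian-smoothed image, on the 0–255 intensity scale.
    """
    if not (0 <= low < high <= 255):
        raise ParameterError(f"require 0 <= low < high <= 255, got low={low}, high={high}")
    p = _pix(frame).astype(np.float64)
    # anchor at the minimum: gradients are unchanged, but a global brightness
    # offset then leaves the float computation (and tie-breaks) bit-identical
    p -= p.min()
    edges = _skfeature.canny(p, sigma=sigma, low_threshold=low, high_threshold=high)
    return BinaryMap(edges.astype(np.uint8))


def binarize(frame, threshold: float) -> BinaryMap:
    """Threshold to a {0,1} map: pixel = 1 iff intensity >= threshold."""
    if not (0 <= threshold <= 255):
        raise ParameterError(f"threshold must be in [0, 255], got {threshold}")
    p = _pix(frame)
    return BinaryMap((p >= threshold).astype(np.uint8))


def otsu_threshold(frame) -> float:
    """Otsu's threshold, expressed for the ``>=`` rule of :func:`binarize`.

    scikit-image's Otsu value ``t`` classifies foreground as ``intensity > t``;
    the returned value is the smallest intensity present in the frame that is
    strictly above ``t``, so ``binarize(frame, otsu_threshold(frame))`` selects
    exactly Otsu's foreground class. A constant image yields its single value
    (everything is foreground).
    """
    p = _pix(frame)
    vals = np.unique(p)
    if vals.size == 1:
        return float(vals[0])
    t = _skfilters.threshold_otsu(p)
    higher = vals[vals > t]
    return float(higher[0]) if higher.size else float(vals[-1])


_FRAME_SUFFIXES = {".png", ".tif", ".tiff"}


def _to_uint8_gray(arr: np.ndarray, path) -> np.ndarray:
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        if np.all(arr[..., 0] == arr[..., 1]) and np.all(arr[..., 1] == arr[..., 2]):
            arr = arr[..., 0]
        else:
            log.info("%s: color image converted to luminance", path)
            arr = np.asarray(
                0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
            )
            arr = np.floor(arr + 0.5)
    if arr.dtype == np.uint16:
        log.info("%s: 16-bit input linearly rescaled to 8-bit", path)
        arr = np.floor(arr.astype(np.float64) * (255.0 / 65535.0) + 0.5)
    return np.clip(arr, 0, 255).astype(np.uint8)


def load_frame(path, frame_index: int = 0) -> ImageFrame:
    """Load one PNG/TIFF grayscale frame; enforces the minimum frame size."""
    import imageio.v3 as iio

    arr = _to_uint8_gray(np.asarray(iio.imread(path)), path)
    if arr.ndim != 2 or min(arr.shape) < MIN_FRAME_SIDE:
        raise ParameterError(
            f"{path}: frames must be 2-D and at least {MIN_FRAME_SIDE} px per side, "
            f"got shape {arr.shape}"
        )
    return ImageFrame(arr, frame_index)


def _index_key(p: Path):
    m = re.findall(r"\d+", p.stem)
    return (int(m[-1]) if m else 0, p.name)


def load_frames(directory) -> list[ImageFrame]:
    """Load all PNG/TIFF frames in a directory, ordered by filename index."""
    d = Path(directory)
    paths = sorted(
        (p for p in d.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES),
        key=_index_key,
    )
    if not paths:
        raise ParameterError(f"no PNG/TIFF frames found in {d}")
    return [load_frame(p, i) for i, p in enumerate(paths)]
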