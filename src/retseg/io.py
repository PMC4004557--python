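"""Reading fundus photographs and deriving the working gray image.

Fundus photographs arrive as 1- or 3-channel rasters (TIFF/PNG/JPEG/GIF) at
arbitrary bit depth.  Internally everything is float64 in [0, 1]; the green
channel is the analysis channel because it carries the best vessel/background
contrast in colour fundus photography.  Vessels are *dark* in the green
channel, so the black top-hat (closing minus image) renders them bright for
the downstream ridge enhancement and entropy thresholding, which both assume
bright vessels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import imageio.v3 as iio
from scipy import ndimage as ndi
from skimage import morphology, filters
from skimage.morphology import disk

log = logging.getLogger(__name__)

__all__ = [
    "ColorFundusImage",
    "GrayImage",
    "FovMask",
    "read_fundus",
    "write_image",
    "write_mask",
    "extract_green",
    "tophat_preprocess",
    "compute_fov_mask",
]


@dataclass(frozen=True)
class ColorFundusImage:
    """H×W×3 colour fundus photograph with values in [0, 1]."""

    pixels: np.ndarray
    source_path: str = "<memory>"

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError(f"expected H×W×3 pixels, got shape {p.shape}")
        if p.shape[0] < 32 or p.shape[1] < 32:
            raise ValueError(f"image too small: {p.shape[:2]} (need ≥ 32×32)")
        if not np.isfinite(p).all():
            raise ValueError("non-finite pixel values")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValueError("pixel values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class GrayImage:
    """Single-channel intensity grid in [0, 1]."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 2:
            raise ValueError(f"expected 2-D pixels, got shape {p.shape}")
        if not np.isfinite(p).all():
            raise ValueError("non-finite pixel values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class FovMask:
    """Boolean field-of-view mask (True = inside the illuminated disc)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 2 or p.dtype != bool:
            raise ValueError("FOV mask must be a 2-D boolean array")
        frac = p.mean()
        if frac < 0.01:
            raise ValueError(f"FOV covers only {frac:.1%} of the frame")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer raster by its dtype maximum; pass floats through."""
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / float(info.max)
    out = arr.astype(np.float64)
    return np.clip(out, 0.0, 1.0)


def read_fundus(path: str) -> ColorFundusImage:
    """Read a raster image as a 3-channel fundus photograph in [0, 1].

    Grayscale inputs are replicated across the three channels; an alpha
    channel, if present, is dropped.  Integer depths are rescaled by the
    maximum representable value of their dtype.
    """
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path!r}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    elif arr.ndim == 3 and arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    else:
        raise ValueError(f"unsupported image layout {arr.shape} in {path!r}")
    return ColorFundusImage(pixels=_to_unit_float(arr), source_path=str(path))


def write_image(path: str, pixels: np.ndarray) -> None:
    """Write a float image in [0, 1] as an 8-bit raster (16-bit for .tif)."""
    pixels = np.asarray(pixels, dtype=np.float64)
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        iio.imwrite(p, np.round(pixels * 65535).astype(np.uint16))
    else:
        iio.imwrite(p, np.round(pixels * 255).astype(np.uint8))


def write_mask(path: str, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit black/white PNG."""
    iio.imwrite(str(path), (np.asarray(mask, bool) * np.uint8(255)))


def extract_green(img: ColorFundusImage) -> GrayImage:
    """Return the green channel (index 1) unchanged."""
    return GrayImage(pixels=img.pixels[:, :, 1].copy())


def extract_luma(img: ColorFundusImage) -> GrayImage:
    """Rec.601 luminance — alternative channel for the reflex binarization."""
    p = img.pixels
    return GrayImage(0.299 * p[:, :, 0] + 0.587 * p[:, :, 1] + 0.114 * p[:, :, 2])


def tophat_preprocess(gray: GrayImage, radius: int = 30) -> GrayImage:
    """Black top-hat contrast preprocessing: vessels become bright.

    Computes closing(gray, disk(radius)) − gray and rescales the result to
    [0, 1] by its maximum.  Dark curvilinear structures narrower than the
    disc (vessels in the green channel) come out bright on a near-zero
    background; the illumination gradient, being smooth at the disc scale,
    is cancelled by the closing residue.

    Parameters
    ----------
    gray : GrayImage
    radius : int
        Disc structuring-element radius in pixels, in [10, 60].
    """
    if not (10 <= radius <= 60):
        raise ValueError(f"top-hat radius {radius} outside [10, 60]")
    h, w = gray.shape
    if radius > min(h, w) // 2:
        raise ValueError(f"radius {radius} too large for a {h}×{w} image")
    closed = morphology.closing(gray.pixels, disk(radius))
    th = closed - gray.pixels
    m = th.max()
    if m > 0:
        th = th / m
    return GrayImage(np.clip(th, 0.0, 1.0))


def _line_selem(length: int, angle_deg: float) -> np.ndarray:
    """Binary line structuring element of a given length and angle."""
    theta = np.deg2rad(angle_deg)
    half = (length - 1) / 2.0
    n = max(length, 3)
    size = int(np.ceil(length)) | 1
    se = np.zeros((size, size), dtype=bool)
    c = size // 2
    for t in np.linspace(-half, half, 4 * n):
        r = int(round(c - t * np.sin(theta)))
        q = int(round(c + t * np.cos(theta)))
        if 0 <= r < size and 0 <= q < size:
            se[r, q] = True
    return se


def compute_fov_mask(gray: GrayImage, sobel_threshold: float | str = "auto") -> FovMask:
    """Field-of-view mask by Sobel edge detection plus directional closing.

    The Sobel gradient magnitude is thresholded (Otsu by default), the edge
    map is closed with 12 line elements of length 3 at 15° steps, holes are
    filled, and the largest filled component is kept as the FOV.  A blank
    image (no edges) yields an all-true mask with a warning.
    """
    grad = filters.sobel(gray.pixels)
    gmax = grad.max()
    if gmax <= 0:
        log.warning("blank image: no FOV boundary found, returning full-frame mask")
        return FovMask(np.ones(gray.shape, dtype=bool))
    thr = filters.threshold_otsu(grad) if sobel_threshold == "auto" else float(sobel_threshold)
    edges = grad > thr
    for k in range(12):
        edges = morphology.closing(edges, _line_selem(3, 15.0 * k))
    filled = ndi.binary_fill_holes(edges)
    labels, n = ndi.label(filled)
    if n == 0:
        log.warning("no connected FOV component found, returning full-frame mask")
        return FovMask(np.ones(gray.shape, dtype=bool))
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return FovMask(labels == keep)
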