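"""Fibrillar structure detection in reflection-microscopy images.

The detection chain mirrors the classic reflection-confocal recipe for
unstained collagen I gels:

1. background removal — subtract a disk-mean filtered copy (radius 10 px);
2. a rolling-ball style local threshold on the *squared* signal — a pixel is
   foreground when its squared intensity exceeds the local mean squared
   intensity by more than 0.5 local standard deviations (circular 5-px
   neighborhood);
3. binary cleanup — drop isolated pixels, then a 3x3 morphological closing;
4. connected components with more than 20 pixels and equivalent-ellipse
   eccentricity >= 0.9 are reported as fibers (anything rounder or smaller
   is speckle, cell debris or noise, not a fiber).

All local filters use reflective padding so stitched-image borders do not
produce spurious fibers.  Convolutions run through ``scipy.signal.fftconvolve``
so full-well images (tens of megapixels) stay tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal
from skimage import measure

from ._moments import labeled_region_stats

__all__ = [
    "Fiber",
    "ExtractionParams",
    "subtract_background",
    "rollingball_mask",
    "clean_binary",
    "label_fibers",
    "extract_fibers",
]


@dataclass(frozen=True)
class Fiber:
    """One detected fibrillar segment.

    centroid_px : (x, y) in image coordinates, origin at the top-left pixel
        center, x along columns, y along rows (increasing downward).
    angle_deg : axis orientation in [0, 180), measured from +x toward +y.
    pixel_count : component size; always > the min-pixel threshold.
    eccentricity : equivalent-ellipse eccentricity in [0, 1]; >= threshold.
    """

    centroid_px: tuple[float, float]
    angle_deg: float
    pixel_count: int
    eccentricity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.angle_deg < 180.0):
            raise ValueError(f"angle_deg must be in [0, 180), got {self.angle_deg}")
        if not (0.0 <= self.eccentricity <= 1.0):
            raise ValueError("eccentricity must be in [0, 1]")


@dataclass(frozen=True)
class ExtractionParams:
    """Tunable parameters of the fiber-detection chain (defaults above)."""

    background_radius_px: int = 10
    local_window_px: int = 5
    local_threshold_sd: float = 0.5
    min_pixels: int = 20           # strict >
    min_eccentricity: float = 0.9  # inclusive >=
    neighborhood: str = "disk"     # "disk" or "square" local window
    clip_negative: bool = True     # treat subtracted image as non-negative intensity

    def __post_init__(self) -> None:
        if self.background_radius_px <= 0 or self.local_window_px <= 0:
            raise ValueError("filter radii must be positive")
        if self.min_pixels <= 0 or self.local_threshold_sd <= 0:
            raise ValueError("thresholds must be positive")
        if not (0.0 <= self.min_eccentricity <= 1.0):
            raise ValueError("min_eccentricity must be in [0, 1]")


def _disk_kernel(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (xx**2 + yy**2 <= radius**2).astype(np.float64)


def _local_mean(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Mean filter with reflective padding, via FFT convolution."""
    pad = kernel.shape[0] // 2
    padded = np.pad(image, pad, mode="reflect")
    out = signal.fftconvolve(padded, kernel / kernel.sum(), mode="same")
    return out[pad:-pad, pad:-pad] if pad else out


def _as_float(image: np.ndarray) -> np.ndarray:
    """Float view of the image; float32 input stays float32 (large stitched
    wells run the filter chain twice as fast in single precision)."""
    image = np.asarray(image)
    if image.dtype not in (np.float32, np.float64):
        image = image.astype(np.float64)
    return image


def subtract_background(image: np.ndarray, radius_px: int = 10) -> np.ndarray:
    """Subtract a disk-mean-filtered background estimate from the image.

    Returns ``image - diskmean(image)``; the result may be negative.  A
    constant image maps to (numerically) zero everywhere.
    """
    image = _as_float(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got ndim={image.ndim}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    kernel = _disk_kernel(radius_px).astype(image.dtype)
    return image - _local_mean(image, kernel)


def rollingball_mask(image: np.ndarray, params: ExtractionParams | None = None) -> np.ndarray:
    """Local threshold on squared intensity: the fibrillar foreground mask.

    A pixel is foreground iff ``image**2`` strictly exceeds the local mean of
    the squared intensity plus ``local_threshold_sd`` local standard
    deviations, where locality is the circular (default) neighborhood of
    radius ``local_window_px``.  The local std uses population (n)
    normalization.  On a constant image the local std is zero and the strict
    inequality leaves the mask empty.

    With ``clip_negative`` (default) negative input values are set to zero
    first: reflection intensity is non-negative, and integer-image
    subtraction saturates at zero, so the negative halo that disk-mean
    background subtraction leaves around bright structures must not register
    as signal when squared.
    """
    params = params or ExtractionParams()
    image = _as_float(image)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if params.clip_negative:
        image = np.maximum(image, 0.0)
    # amplitude floor: values below 1e-8 of the dynamic range are background,
    # not signal — an adaptive threshold must not chase numerical dust
    peak = float(np.abs(image).max())
    if peak > 0:
        image = np.where(np.abs(image) < 1e-8 * peak, 0.0, image)
    sq = image * image
    if params.neighborhood == "disk":
        kernel = _disk_kernel(params.local_window_px)
    elif params.neighborhood == "square":
        w = 2 * params.local_window_px + 1
        kernel = np.ones((w, w))
    else:
        raise ValueError(f"unknown neighborhood {params.neighborhood!r}")
    kernel = kernel.astype(image.dtype)
    mean = _local_mean(sq, kernel)
    mean2 = _local_mean(sq * sq, kernel)
    std = np.sqrt(np.maximum(mean2 - mean * mean, 0.0))
    floor = (1e-8 * peak) ** 2  # keeps FFT round-off in empty areas out of the mask
    return (sq > mean + params.local_threshold_sd * std) & (sq > floor)


def clean_binary(mask: np.ndarray) -> np.ndarray:
    """Remove 8-connectivity-isolated pixels, then close with a 3x3 square."""
    mask = np.asarray(mask, dtype=bool)
    neighbors = ndimage.convolve(
        mask.astype(np.uint8), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], np.uint8),
        mode="constant",
    )
    kept = mask & (neighbors > 0)
    structure = np.ones((3, 3), bool)
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(kept, structure), structure, border_value=1
    )
    return closed


def label_fibers(mask: np.ndarray, params: ExtractionParams | None = None) -> list[Fiber]:
    """Connected components passing the size and eccentricity gates.

    8-connected components with ``pixel_count > min_pixels`` and
    ``eccentricity >= min_eccentricity`` become :class:`Fiber` records; an
    empty mask yields an empty list.
    """
    params = params or ExtractionParams()
    labels, n = measure.label(np.asarray(mask, bool), connectivity=2, return_num=True)
    if n == 0:
        return []
    stats = labeled_region_stats(labels, n)
    keep = (stats["area"] > params.min_pixels) & (
        stats["eccentricity"] >= params.min_eccentricity
    )
    fibers = [
        Fiber(
            centroid_px=(float(stats["centroid_x"][i]), float(stats["centroid_y"][i])),
            angle_deg=float(stats["angle_deg"][i]),
            pixel_count=int(stats["area"][i]),
            eccentricity=float(stats["eccentricity"][i]),
        )
        for i in np.nonzero(keep)[0]
    ]
    for f in fibers:  # contract: no emitted fiber may violate the gates
        assert f.pixel_count > params.min_pixels and f.eccentricity >= params.min_eccentricity
    return fibers


def extract_fibers(image: np.ndarray, params: ExtractionParams | None = None) -> list[Fiber]:
    """Full chain: background subtraction -> local threshold -> cleanup -> label.

    A 3D input is treated as a z-series: each plane is processed
    independently and the detected fibers pooled (fiber coordinates are
    in-plane; a confocal slice resolves only the fibers near its focal z).
    """
    params = params or ExtractionParams()
    image = np.asarray(image)
    if image.ndim == 3:
        out: list[Fiber] = []
        for plane in image:
            out.extend(extract_fibers(plane, params))
        return out
    bg = subtract_background(image, params.background_radius_px)
    mask = rollingball_mask(bg, params)
    return label_fibers(clean_binary(mask), params)
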