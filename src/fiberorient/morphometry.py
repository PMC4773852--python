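"""Tumor-spheroid segmentation from DIC-like images and nuclei counting.

Segmentation proceeds in three steps that mirror how spheroids actually look
in DIC: (1) the image is normalized by a large-kernel median filter to flatten
uneven illumination; (2) the dense spheroid core — much darker than the gel —
is thresholded at 2 SD below the mean of a blurred copy, keeping the
component nearest the image center; (3) the migration zone, which shows up
as texture (edges) rather than darkness, is captured with Canny edges that
are closed against the core, yielding the combined final-spheroid mask.

The "radius" of a spheroid is its equivalent-circle radius,
``pixel_size * sqrt(area / pi)`` of the combined mask (a configurable
alternative is the maximum centroid-to-boundary distance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, morphology, segmentation
from skimage.filters import rank

from ._moments import axis_angle_deg, ellipse_shape, region_moments

__all__ = [
    "SpheroidMask",
    "normalize_dic",
    "segment_core",
    "segment_full_spheroid",
    "segment_spheroid",
    "expansion_ratio",
    "count_nuclei",
]


@dataclass(frozen=True)
class SpheroidMask:
    """Segmented spheroid (core + migration zone) with morphometrics."""

    mask: np.ndarray
    center_px: tuple[float, float]
    radius_um: float
    major_axis_px: float
    minor_axis_px: float
    major_angle_deg: float
    pixel_size_um: float

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def mask_morphometrics(mask: np.ndarray, pixel_size_um: float) -> SpheroidMask:
    """Equivalent-circle radius and principal axes of a binary mask."""
    mask = np.asarray(mask, bool)
    centroid, mxx, myy, mxy, area = region_moments(mask)
    major, minor, _ = ellipse_shape(mxx, myy, mxy)
    return SpheroidMask(
        mask=mask,
        center_px=(float(centroid[0]), float(centroid[1])),
        radius_um=float(pixel_size_um * np.sqrt(area / np.pi)),
        major_axis_px=major,
        minor_axis_px=minor,
        major_angle_deg=axis_angle_deg(mxx, myy, mxy),
        pixel_size_um=pixel_size_um,
    )


def normalize_dic(image: np.ndarray, median_radius_px: int = 50) -> np.ndarray:
    """Divide the image by its large-kernel median-filtered copy.

    The median filter estimates the background illumination field; division
    flattens it.  Zero-background pixels are guarded so the output is finite
    everywhere.  Raises on an all-zero image.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if not np.any(image):
        raise ValueError("all-zero image cannot be normalized")
    # sliding-histogram rank median (8-bit quantized) — a 100-px brute-force
    # median on a stitched well would be prohibitively slow, and the
    # background illumination field does not need more than 8-bit depth
    lo, hi = float(image.min()), float(image.max())
    if hi > lo:
        quant = np.round((image - lo) / (hi - lo) * 255.0).astype(np.uint8)
        med = rank.median(quant, footprint=morphology.disk(median_radius_px))
        background = med.astype(np.float64) / 255.0 * (hi - lo) + lo
    else:
        background = np.full_like(image, lo)
    floor = max(np.abs(background[background != 0]).min() if np.any(background) else 1.0, 1e-12)
    safe = np.where(np.abs(background) > 1e-12, background, floor)
    out = image / safe
    assert np.all(np.isfinite(out))
    return out


def segment_core(normalized: np.ndarray, blur_sigma_px: float = 4.0) -> np.ndarray:
    """Dark-core mask: blur, threshold at mean - 2 SD, keep the central blob.

    Raises when nothing lies 2 SD below the mean (e.g. a uniform image).
    "Central" means the connected component whose centroid is nearest the
    image center.
    """
    normalized = np.asarray(normalized, dtype=np.float64)
    blurred = ndimage.gaussian_filter(normalized, blur_sigma_px)
    thresh = blurred.mean() - 2.0 * blurred.std()
    dark = blurred < thresh
    if not dark.any():
        raise ValueError("no pixels 2 SD below the mean: empty core")
    labels, n = ndimage.label(dark)
    h, w = normalized.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    centroids = ndimage.center_of_mass(dark, labels, range(1, n + 1))
    best = int(np.argmin([np.hypot(*(np.asarray(c) - center)) for c in centroids])) + 1
    core = labels == best
    return ndimage.binary_fill_holes(core)


def segment_full_spheroid(
    normalized: np.ndarray,
    core_mask: np.ndarray,
    dilation_radius_px: int = 15,
    pixel_size_um: float = 0.67,
    canny_sigma_px: float = 2.0,
) -> SpheroidMask:
    """Combine the core with the Canny-edge migration zone into one mask.

    Edges are dilated by ``dilation_radius_px`` to bridge the sparse texture
    of migrating cells, united with the core, hole-filled, then eroded by
    the same radius (a closing against the core) so the mask boundary tracks
    the outermost detected cells rather than the dilation footprint.  Only
    the component containing the core survives; morphometrics are computed
    from the result.
    """
    core_mask = np.asarray(core_mask, bool)
    if not core_mask.any():
        raise ValueError("empty core mask")
    edges = feature.canny(np.asarray(normalized, dtype=np.float64), sigma=canny_sigma_px)
    selem = morphology.disk(dilation_radius_px).astype(bool)
    if dilation_radius_px > 0:
        grown = ndimage.binary_dilation(edges, structure=selem)
    else:
        grown = edges
    combined = ndimage.binary_fill_holes(grown | core_mask)
    if dilation_radius_px > 0:
        combined = ndimage.binary_erosion(combined, structure=selem, border_value=0)
    combined |= core_mask
    combined = ndimage.binary_fill_holes(combined)
    # keep the component overlapping the core (discard stray background edges)
    labels, n = ndimage.label(combined)
    core_labels = np.unique(labels[core_mask])
    core_labels = core_labels[core_labels > 0]
    keep = np.isin(labels, core_labels)
    return mask_morphometrics(keep, pixel_size_um)


def segment_spheroid(
    image: np.ndarray,
    pixel_size_um: float = 0.67,
    median_radius_px: int = 50,
    blur_sigma_px: float = 4.0,
    dilation_radius_px: int = 15,
    canny_sigma_px: float = 2.0,
) -> SpheroidMask:
    """Full DIC chain: normalize -> core -> combined spheroid mask."""
    norm = normalize_dic(image, median_radius_px)
    core = segment_core(norm, blur_sigma_px)
    return segment_full_spheroid(
        norm, core, dilation_radius_px, pixel_size_um, canny_sigma_px
    )


def expansion_ratio(mask_t48: SpheroidMask, mask_t0: SpheroidMask) -> float:
    """Final radius over initial radius (e.g. 48 h post-injection vs 0 h)."""
    if mask_t0.radius_um <= 0:
        raise ValueError("initial radius must be positive")
    return mask_t48.radius_um / mask_t0.radius_um


def count_nuclei(
    zstack: np.ndarray,
    blur_sigma_px: float = 2.0,
    min_distance_px: int = 5,
    min_size_px: int = 9,
) -> int:
    """Count nuclei in a fluorescence z-stack.

    Planes are sum-projected, low-pass filtered, and thresholded at
    mean + 2 SD; touching objects are split by a watershed on the distance
    transform seeded at local maxima at least ``min_distance_px`` apart.
    Specks below ``min_size_px`` are ignored.
    """
    zstack = np.asarray(zstack, dtype=np.float64)
    if zstack.ndim == 2:
        zstack = zstack[None]
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("expected a stack of >= 1 plane")
    projected = zstack.sum(axis=0)
    smooth = ndimage.gaussian_filter(projected, blur_sigma_px)
    foreground = smooth > smooth.mean() + 2.0 * smooth.std()
    if not foreground.any():
        return 0
    lab, nlab = ndimage.label(foreground)
    sizes = np.bincount(lab.ravel())
    foreground = sizes[lab] >= min_size_px
    foreground &= lab > 0
    if not foreground.any():
        return 0
    distance = ndimage.distance_transform_edt(foreground)
    coords = feature.peak_local_max(
        distance, min_distance=min_distance_px, labels=foreground, exclude_border=False
    )
    markers = np.zeros_like(foreground, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = segmentation.watershed(-distance, markers, mask=foreground)
    counts = np.bincount(labels.ravel())[1:]
    return int(np.count_nonzero(counts >= min_size_px))
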