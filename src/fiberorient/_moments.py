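"""Second-moment (equivalent-ellipse) statistics for labeled binary regions.

All angles in this package follow a single convention: degrees in [0, 180),
measured from the image +x axis (columns) toward +y (rows, increasing
downward), coordinates are 0-based pixel centers. The axis of a region is
defined by the principal eigenvector of the central second-moment
(covariance) matrix of its pixel set, identical to the equivalent-ellipse
semantics of ``skimage.measure.regionprops`` (no per-pixel area correction,
so a 1-px-wide line has eccentricity exactly 1).
"""

from __future__ import annotations

import numpy as np


def axis_angle_deg(mxx: float, myy: float, mxy: float) -> float:
    """Major-axis angle in [0, 180) from central second moments.

    ``mxx``/``myy``/``mxy`` are the (per-area) central moments over x=columns
    and y=rows.  Degenerate (isotropic) regions return 0.
    """
    ang = 0.5 * np.degrees(np.arctan2(2.0 * mxy, mxx - myy))
    return float(np.mod(ang, 180.0))


def ellipse_shape(mxx: float, myy: float, mxy: float) -> tuple[float, float, float]:
    """(major_axis_length, minor_axis_length, eccentricity) from moments.

    Axis lengths use the regionprops normalization (4 * sqrt(eigenvalue)).
    """
    tr = 0.5 * (mxx + myy)
    det = np.sqrt(max((0.5 * (mxx - myy)) ** 2 + mxy**2, 0.0))
    lam_max = max(tr + det, 0.0)
    lam_min = max(tr - det, 0.0)
    major = 4.0 * np.sqrt(lam_max)
    minor = 4.0 * np.sqrt(lam_min)
    if lam_max <= 0.0:
        ecc = 0.0
    else:
        ecc = float(np.sqrt(1.0 - lam_min / lam_max))
    return float(major), float(minor), ecc


def region_moments(mask: np.ndarray) -> tuple[np.ndarray, float, float, float, int]:
    """Centroid (x, y), central moments (mxx, myy, mxy) and area of one mask."""
    ys, xs = np.nonzero(mask)
    n = xs.size
    if n == 0:
        raise ValueError("empty mask has no moments")
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    mxx = float(np.dot(dx, dx) / n)
    myy = float(np.dot(dy, dy) / n)
    mxy = float(np.dot(dx, dy) / n)
    return np.array([cx, cy]), mxx, myy, mxy, int(n)


def labeled_region_stats(labels: np.ndarray, n_labels: int) -> dict[str, np.ndarray]:
    """Vectorized per-label area, centroid, axis angle and eccentricity.

    Equivalent to looping ``regionprops`` over components but computed with
    ``np.bincount`` so that images with tens of thousands of fibers stay
    cheap.  Label 0 (background) is excluded; arrays are indexed by
    ``label - 1``.
    """
    ys, xs = np.nonzero(labels)
    lab = labels[ys, xs]
    area = np.bincount(lab, minlength=n_labels + 1)[1:].astype(np.int64)
    sx = np.bincount(lab, weights=xs, minlength=n_labels + 1)[1:]
    sy = np.bincount(lab, weights=ys, minlength=n_labels + 1)[1:]
    sxx = np.bincount(lab, weights=xs * xs.astype(np.float64), minlength=n_labels + 1)[1:]
    syy = np.bincount(lab, weights=ys * ys.astype(np.float64), minlength=n_labels + 1)[1:]
    sxy = np.bincount(lab, weights=xs * ys.astype(np.float64), minlength=n_labels + 1)[1:]
    a = np.maximum(area, 1).astype(np.float64)
    cx, cy = sx / a, sy / a
    mxx = sxx / a - cx**2
    myy = syy / a - cy**2
    mxy = sxy / a - cx * cy
    ang = np.mod(0.5 * np.degrees(np.arctan2(2.0 * mxy, mxx - myy)), 180.0)
    tr = 0.5 * (mxx + myy)
    det = np.sqrt(np.maximum((0.5 * (mxx - myy)) ** 2 + mxy**2, 0.0))
    lam_max = np.maximum(tr + det, 0.0)
    lam_min = np.maximum(tr - det, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ecc = np.sqrt(1.0 - np.where(lam_max > 0, lam_min / lam_max, 1.0))
    ecc = np.where(lam_max > 0, ecc, 0.0)
    return {
        "area": area,
        "centroid_x": cx,
        "centroid_y": cy,
        "angle_deg": ang,
        "eccentricity": ecc,
    }


def acute_angle_between_deg(angle_a_deg: float, angle_b_deg: float) -> float:
    """Acute angle in [0, 90] between two undirected axes given in degrees."""
    d = np.mod(angle_a_deg - angle_b_deg, 180.0)
    return float(min(d, 180.0 - d))
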