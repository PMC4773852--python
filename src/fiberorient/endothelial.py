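"""Endothelial spheroid response scoring: direction, elongation, orientation.

An endothelial spheroid that senses the tumor elongates and points its long
axis at it.  Three scalars quantify that response from the spheroid's binary
mask and the tumor center:

* ``direction`` = (90 - alpha) / 90, where alpha is the acute angle (deg)
  between the mask's long axis and the vector from the mask centroid to the
  tumor center — 1 when pointing at the tumor, 0 when perpendicular;
* ``elongation`` = equivalent-ellipse major / minor axis ratio (>= 1);
* ``orientation`` = direction * elongation, the combined response score.

Near-circular masks (elongation < 1.05) have a poorly defined long axis;
their direction is still reported but flagged ``low_confidence``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from ._moments import acute_angle_between_deg, axis_angle_deg, ellipse_shape, region_moments

__all__ = [
    "EndothelialScore",
    "mask_principal_axes",
    "direction_parameter",
    "elongation",
    "orientation_score",
    "score_mask",
    "correlate_with_collagen",
]

LOW_CONFIDENCE_ELONGATION = 1.05


@dataclass(frozen=True)
class EndothelialScore:
    """Direction/elongation/orientation of one endothelial spheroid."""

    direction: float
    elongation: float
    orientation: float
    angle_to_tumor_deg: float
    distance_to_tumor_um: float
    low_confidence: bool = False

    def __post_init__(self) -> None:
        assert 0.0 <= self.direction <= 1.0
        assert self.elongation >= 1.0
        assert 0.0 <= self.orientation <= self.elongation
        assert abs(self.direction - (90.0 - self.angle_to_tumor_deg) / 90.0) < 1e-9
        assert abs(self.orientation - self.direction * self.elongation) < 1e-9


def mask_principal_axes(mask: np.ndarray) -> tuple[float, float, float]:
    """(major_length_px, minor_length_px, major_angle_deg) of a binary mask.

    Axes come from the central second moments (equivalent ellipse); raises
    on masks of fewer than 2 pixels, whose axes are undefined.
    """
    mask = np.asarray(mask, bool)
    if mask.sum() < 2:
        raise ValueError("mask must contain >= 2 pixels")
    _, mxx, myy, mxy, _ = region_moments(mask)
    major, minor, _ = ellipse_shape(mxx, myy, mxy)
    return major, minor, axis_angle_deg(mxx, myy, mxy)


def elongation(mask: np.ndarray) -> float:
    """Long-axis over short-axis ratio of the mask's equivalent ellipse."""
    major, minor, _ = mask_principal_axes(mask)
    if minor <= 0:
        raise ValueError("degenerate mask: zero minor axis")
    return major / minor


def direction_parameter(mask: np.ndarray, tumor_center_px: Sequence[float]) -> float:
    """(90 - alpha)/90 for alpha = acute angle between long axis and tumor vector."""
    mask = np.asarray(mask, bool)
    centroid, mxx, myy, mxy, _ = region_moments(mask)
    d = np.asarray(tumor_center_px, dtype=float) - centroid
    if np.hypot(*d) == 0:
        raise ValueError("mask centroid coincides with tumor center")
    axis_deg = axis_angle_deg(mxx, myy, mxy)
    alpha = acute_angle_between_deg(axis_deg, np.degrees(np.arctan2(d[1], d[0])))
    return (90.0 - alpha) / 90.0


def orientation_score(
    direction: "float | EndothelialScore", elongation_value: float | None = None
) -> float:
    """Combined response score: direction times elongation.

    Accepts either the two scalars or an :class:`EndothelialScore`.
    """
    if isinstance(direction, EndothelialScore):
        return direction.direction * direction.elongation
    if elongation_value is None:
        raise TypeError("elongation_value required when passing scalars")
    return direction * elongation_value


def score_mask(
    mask: np.ndarray,
    tumor_center_px: Sequence[float],
    pixel_size_um: float = 0.67,
) -> EndothelialScore:
    """All three scores for one endothelial mask against a tumor center."""
    mask = np.asarray(mask, bool)
    centroid, mxx, myy, mxy, _ = region_moments(mask)
    d = np.asarray(tumor_center_px, dtype=float) - centroid
    dist = float(np.hypot(*d))
    if dist == 0:
        raise ValueError("mask centroid coincides with tumor center")
    major, minor, axis_deg = mask_principal_axes(mask)
    if minor <= 0:
        raise ValueError("degenerate mask: zero minor axis")
    elong = major / minor
    alpha = acute_angle_between_deg(axis_deg, np.degrees(np.arctan2(d[1], d[0])))
    direction = (90.0 - alpha) / 90.0
    return EndothelialScore(
        direction=direction,
        elongation=elong,
        orientation=direction * elong,
        angle_to_tumor_deg=alpha,
        distance_to_tumor_um=dist * pixel_size_um,
        low_confidence=elong < LOW_CONFIDENCE_ELONGATION,
    )


def correlate_with_collagen(
    collagen_orientation: Sequence[float], scores: Sequence[float]
) -> tuple[float, float, tuple[float, float]]:
    """Pearson r, p-value and (slope, intercept) of score vs collagen orientation."""
    x = np.asarray(collagen_orientation, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return float(r), float(p), (float(slope), float(intercept))
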