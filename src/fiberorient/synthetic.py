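"""Ground-truthed synthetic scenes for every stage of the pipeline.

The collagen analysis was designed for reflection-confocal images of 1 mg/mL
rat-tail collagen around microprinted tumor spheroids; no such images ship
with this package, so each analysis stage comes with a generator that
emulates the statistical structure the stage assumes and returns the ground
truth alongside:

* fiber fields whose orientations carry a radial bias decaying
  exponentially with distance from the spheroid edge (and their rendered
  reflection-style images);
* DIC-like spheroid phantoms: dark core, textured migration rim, smooth
  uneven background;
* nuclei z-stacks of Gaussian blobs with a known count;
* elliptical endothelial-spheroid masks at controlled angle and elongation.

Generative law for the fiber orientation bias: each fiber is exactly radial
(plus optional angular wobble) with probability ``w0 * exp(-d / lambda)``
(``d`` = distance from fiber centroid to the spheroid edge), otherwise its
axis is uniform on [0, 180).  The expected orientation parameter is then::

    E[cos^2](d) = 0.5 + 0.5 * w0 * exp(-d / lambda)

i.e. the analysis' plateau-at-0.5 exponential with Y0 = 0.5 + 0.5*w0 and
L0 = lambda, so parameter recovery can be verified against exact truth.
All generators are deterministic given their seed (one stream per scene).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import draw

__all__ = [
    "FiberFieldParams",
    "GroundTruthFiber",
    "generate_fiber_field",
    "render_reflection_image",
    "generate_spheroid_phantom",
    "generate_nuclei_stack",
    "generate_endothelial_mask",
    "write_scene",
]


@dataclass(frozen=True)
class GroundTruthFiber:
    """Truth record for one simulated fiber (centroid px, axis deg, length px)."""

    centroid_px: tuple[float, float]
    angle_deg: float
    length_px: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.angle_deg < 180.0):
            raise ValueError("angle_deg must be in [0, 180)")


@dataclass(frozen=True)
class FiberFieldParams:
    """Parameters of a synthetic radially-biased fiber field.

    Defaults describe a scene at the scale of the real assay: 0.67 um/px,
    a ~116 um spheroid, straight fibers of ~30 px (~20 um) length.  Density
    and length for 1 mg/mL collagen are not documented anywhere we know of;
    these are plausible placeholders, not calibrated values.
    """

    image_size_px: tuple[int, int] = (2048, 2048)  # (height, width)
    pixel_size_um: float = 0.67
    tumor_center_px: tuple[float, float] = (1024.0, 1024.0)  # (x, y)
    tumor_radius_um: float = 116.0
    n_fibers: int = 5000
    fiber_length_px: tuple[float, float] = (30.0, 8.0)  # mean, sd
    fiber_width_px: float = 2.0
    radial_bias_w0: float = 0.8
    decay_length_um: float = 500.0
    angular_noise_deg: float = 0.0
    background_noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.radial_bias_w0 <= 1.0):
            raise ValueError("radial_bias_w0 must be in [0, 1]")
        if self.decay_length_um <= 0:
            raise ValueError("decay_length_um must be > 0")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def tumor_radius_px(self) -> float:
        return self.tumor_radius_um / self.pixel_size_um


def generate_fiber_field(params: FiberFieldParams) -> list[GroundTruthFiber]:
    """Sample a radially-biased fiber field; deterministic given the seed.

    Centroids are uniform over the image excluding the tumor disk.  Each
    fiber is radial (with N(0, angular_noise) wobble) with probability
    ``w0 * exp(-d / lambda)``, else uniformly oriented.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size_px
    cx, cy = params.tumor_center_px
    r_px = params.tumor_radius_px
    out: list[GroundTruthFiber] = []
    xs = np.empty(0)
    ys = np.empty(0)
    while xs.size < params.n_fibers:  # rejection-sample outside the tumor disk
        need = params.n_fibers - xs.size
        x = rng.uniform(0, w, size=max(need * 2, 16))
        y = rng.uniform(0, h, size=x.size)
        keep = np.hypot(x - cx, y - cy) > r_px
        xs = np.concatenate([xs, x[keep]])
        ys = np.concatenate([ys, y[keep]])
    xs, ys = xs[: params.n_fibers], ys[: params.n_fibers]
    dist_um = (np.hypot(xs - cx, ys - cy) - r_px) * params.pixel_size_um
    p_radial = params.radial_bias_w0 * np.exp(-np.maximum(dist_um, 0.0) / params.decay_length_um)
    radial = rng.uniform(size=params.n_fibers) < p_radial
    radial_deg = np.degrees(np.arctan2(ys - cy, xs - cx))
    wobble = rng.normal(0.0, params.angular_noise_deg, size=params.n_fibers)
    uniform_deg = rng.uniform(0.0, 180.0, size=params.n_fibers)
    angles = np.where(radial, np.mod(radial_deg + wobble, 180.0), uniform_deg)
    mean_len, sd_len = params.fiber_length_px
    lengths = np.maximum(rng.normal(mean_len, sd_len, size=params.n_fibers), 3.0)
    return [
        GroundTruthFiber((float(xs[i]), float(ys[i])), float(angles[i]), float(lengths[i]))
        for i in range(params.n_fibers)
    ]


def expected_profile(params: FiberFieldParams, distance_um: np.ndarray) -> np.ndarray:
    """Closed-form E[cos^2](d) = 0.5 + 0.5*w0*exp(-d/lambda) (zero wobble)."""
    return 0.5 + 0.5 * params.radial_bias_w0 * np.exp(
        -np.asarray(distance_um, dtype=float) / params.decay_length_um
    )


def render_reflection_image(
    fibers: list[GroundTruthFiber],
    params: FiberFieldParams,
    blur_sigma_px: float = 0.7,
    noise_seed: int | None = None,
) -> np.ndarray:
    """Render fibers as bright, evenly lit segments on a dark background.

    Each fiber is drawn as a filled rectangle of width ``fiber_width_px``
    (collagen fibers image as uniformly bright, um-wide lines in reflection
    confocal, not as sub-pixel hairlines).  Optional Gaussian blur emulates
    the optical PSF; additive Gaussian noise with ``background_noise_sigma``
    emulates detector noise.  The image is rescaled to [0, 1] (an empty,
    noiseless scene stays all-zero).
    """
    h, w = params.image_size_px
    img = np.zeros((h, w), dtype=np.float64)
    half_w = 0.5 * params.fiber_width_px
    for f in fibers:
        ang = np.radians(f.angle_deg)
        ux, uy = np.cos(ang), np.sin(ang)        # along-axis unit vector
        px, py = -uy, ux                         # across-axis unit vector
        cx, cy = f.centroid_px
        hl = 0.5 * f.length_px
        corners_x = np.array([cx - hl * ux - half_w * px, cx + hl * ux - half_w * px,
                              cx + hl * ux + half_w * px, cx - hl * ux + half_w * px])
        corners_y = np.array([cy - hl * uy - half_w * py, cy + hl * uy - half_w * py,
                              cy + hl * uy + half_w * py, cy - hl * uy + half_w * py])
        rr, cc = draw.polygon(corners_y, corners_x, shape=(h, w))  # clips at borders
        img[rr, cc] = 1.0
    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px)
    if params.background_noise_sigma > 0:
        rng = np.random.default_rng(params.seed + 1 if noise_seed is None else noise_seed)
        img = img + rng.normal(0.0, params.background_noise_sigma, size=img.shape)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    else:
        img = np.zeros_like(img)
    return img


def render_reflection_stack(
    fibers: list[GroundTruthFiber],
    params: FiberFieldParams,
    n_slices: int,
    blur_sigma_px: float = 0.0,
) -> np.ndarray:
    """Render fibers as a shallow confocal z-series of ``n_slices`` planes.

    A 1.5-mm collagen gel is three-dimensional: fibers sit at different
    depths and a reflection-confocal plane resolves only those near its
    focal z.  Slamming tens of thousands of fibers into a single 2D plane
    produces overlap no real acquisition would show, so dense scenes are
    rendered as a z-series with each fiber assigned to one plane (uniformly,
    from the scene's seeded stream).  Returns an (n_slices, H, W) array;
    downstream extraction runs per plane and pools the detected fibers.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    rng = np.random.default_rng(params.seed + 2)
    assignment = rng.integers(0, n_slices, size=len(fibers))
    planes = []
    for s in range(n_slices):
        subset = [f for f, a in zip(fibers, assignment) if a == s]
        planes.append(
            render_reflection_image(
                subset, params, blur_sigma_px=blur_sigma_px, noise_seed=params.seed + 3 + s
            )
        )
    return np.stack(planes) if planes else np.zeros((0,) + tuple(params.image_size_px))


def generate_spheroid_phantom(
    center_px: tuple[float, float] = (256.0, 256.0),
    core_radius_px: float = 75.0,
    rim_width_px: float = 30.0,
    image_size_px: tuple[int, int] = (512, 512),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """DIC-like spheroid phantom: dark core + textured migration rim.

    Returns ``(image, true_mask)`` where the mask is the disk of radius
    ``core_radius_px + rim_width_px`` (core only if the rim width is 0).
    Background is a smooth uneven illumination field, emulating DIC shading.
    """
    if core_radius_px <= 0:
        raise ValueError("core_radius_px must be > 0")
    rng = np.random.default_rng(seed)
    h, w = image_size_px
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = center_px
    r = np.hypot(xx - cx, yy - cy)
    # smooth uneven background around 0.5 intensity
    illum = ndimage.gaussian_filter(rng.normal(size=(h, w)), 60)
    illum = 0.5 + 0.15 * illum / max(np.abs(illum).max(), 1e-12)
    img = illum.copy()
    img[r <= core_radius_px] *= 0.25  # dark core
    if rim_width_px > 0:
        rim = (r > core_radius_px) & (r <= core_radius_px + rim_width_px)
        # speckled migrating cells: dense dark/bright granules over the rim
        texture = rng.uniform(size=(h, w)) < 0.35
        granules = ndimage.gaussian_filter((texture & rim).astype(float), 1.0)
        img = np.where(rim, img * (1.0 - 1.4 * np.clip(granules, 0, 0.5)), img)
    img += rng.normal(0.0, 0.01, size=(h, w))
    img = np.clip(img, 1e-4, None)
    true_mask = r <= core_radius_px + rim_width_px
    return img, true_mask


def generate_nuclei_stack(
    n_nuclei: int,
    image_size_px: tuple[int, int] = (256, 256),
    z_planes: int = 5,
    blob_sigma_px: float = 3.0,
    min_separation_px: float | None = None,
    noise_sigma: float = 0.01,
    seed: int = 0,
    centers_px: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Z-stack of Gaussian nuclear blobs; returns (stack, true count).

    Centers are sampled with a configurable minimum separation (default
    4 * blob_sigma, at which downstream counting is exact); pass explicit
    ``centers_px`` (N x 2, x/y) to place touching pairs deliberately.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = image_size_px
    if centers_px is None:
        if min_separation_px is None:
            min_separation_px = 4.0 * blob_sigma_px
        pts: list[tuple[float, float]] = []
        margin = 4 * blob_sigma_px
        attempts = 0
        while len(pts) < n_nuclei:
            attempts += 1
            if attempts > 100000:
                raise RuntimeError("could not place nuclei with requested separation")
            x = rng.uniform(margin, w - margin)
            y = rng.uniform(margin, h - margin)
            if all(np.hypot(x - p[0], y - p[1]) >= min_separation_px for p in pts):
                pts.append((x, y))
        centers_px = np.asarray(pts, dtype=float).reshape(-1, 2)
    else:
        centers_px = np.asarray(centers_px, dtype=float).reshape(-1, 2)
        n_nuclei = centers_px.shape[0]
    stack = np.zeros((z_planes, h, w), dtype=np.float64)
    zs = rng.integers(0, z_planes, size=n_nuclei)
    yy, xx = np.mgrid[0:h, 0:w]
    for (x, y), z in zip(centers_px, zs):
        blob = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * blob_sigma_px**2))
        stack[z] += blob
    if noise_sigma > 0:
        stack += rng.normal(0.0, noise_sigma, size=stack.shape)
    return stack, int(n_nuclei)


def generate_endothelial_mask(
    angle_deg: float,
    elongation: float,
    image_size_px: tuple[int, int] = (256, 256),
    area_px: float = 2000.0,
    center_px: tuple[float, float] | None = None,
) -> np.ndarray:
    """Filled ellipse with major axis at ``angle_deg`` and axis ratio ``elongation``.

    The angle follows the package convention (degrees from +x toward +y,
    i.e. downward-positive).  Semi-axes are set so the ellipse area equals
    ``area_px``.
    """
    if elongation < 1:
        raise ValueError("elongation must be >= 1")
    h, w = image_size_px
    if center_px is None:
        center_px = ((w - 1) / 2.0, (h - 1) / 2.0)
    cx, cy = center_px
    b = np.sqrt(area_px / (np.pi * elongation))  # semi-minor
    a = elongation * b                            # semi-major
    yy, xx = np.mgrid[0:h, 0:w]
    th = np.radians(angle_deg)
    u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
    v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def write_scene(
    out_dir: str | Path,
    params: FiberFieldParams,
    fibers: list[GroundTruthFiber],
    image: np.ndarray,
    name: str = "fiber_field",
) -> dict[str, Path]:
    """Persist a rendered scene: 16-bit TIFF, truth CSV, JSON parameter sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = out_dir / f"{name}.tif"
    tifffile.imwrite(tif, np.clip(image * 65535, 0, 65535).astype(np.uint16))
    csv = out_dir / f"{name}_truth.csv"
    pd.DataFrame(
        {
            "centroid_x_px": [f.centroid_px[0] for f in fibers],
            "centroid_y_px": [f.centroid_px[1] for f in fibers],
            "angle_deg": [f.angle_deg for f in fibers],
            "length_px": [f.length_px for f in fibers],
        }
    ).to_csv(csv, index=False)
    meta = out_dir / f"{name}_params.json"
    meta.write_text(json.dumps(asdict(params), indent=2))
    return {"image": tif, "truth": csv, "params": meta}
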