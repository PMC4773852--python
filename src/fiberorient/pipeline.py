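"""Per-well orchestration: images in, tables and a JSON summary out.

A *well* is one microprinted experiment: a tumor spheroid in a collagen gel,
imaged by DIC at injection (t0) and 48 h later (t48), reflection microscopy
of the collagen network, optionally a nuclei z-stack and endothelial
spheroid masks at known injection sites.  :func:`run_well` runs every stage
the supplied images allow, records per-stage failures without aborting the
rest, and writes fibers/bins/injections CSV tables plus a JSON summary.

Stages are pure calls into the analysis modules — every report value can be
re-derived by calling those functions directly on the same inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import morphometry
from .endothelial import score_mask
from .extraction import ExtractionParams, extract_fibers
from .orientation import (
    ExponentialFit,
    FitFailure,
    RadialOrientationModel,
    RadialOrientationResults,
    classify_oriented,
    compare_groups,
)

logger = logging.getLogger("fiberorient")

__all__ = ["WellConfig", "WellReport", "run_well", "compare_regions", "write_report"]


@dataclass
class WellConfig:
    """Configuration of one well; load from YAML/JSON with :meth:`from_file`."""

    pixel_size_um: float = 0.67
    reflection_image: str | None = None
    dic_t0: str | None = None
    dic_t48: str | None = None
    nuclei_stack: str | None = None
    tumor_center_px: tuple[float, float] | None = None  # manual override
    tumor_radius_um: float | None = None                # manual override
    injections: list[dict[str, Any]] = field(default_factory=list)
    bin_width_um: float = 67.0
    fit_window_min_um: float = 100.0
    seed: int = 0
    extraction: dict[str, Any] = field(default_factory=dict)
    segmentation: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "WellConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        cfg = cls(**data)
        for key in ("reflection_image", "dic_t0", "dic_t48", "nuclei_stack"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p}")
        return cfg


@dataclass
class WellReport:
    """Everything measured for one well, plus the parameters that produced it."""

    config: WellConfig
    radius_t0_um: float | None = None
    radius_t48_um: float | None = None
    expansion_ratio: float | None = None
    tumor_center_px: tuple[float, float] | None = None
    tumor_radius_um: float | None = None
    fibers: pd.DataFrame | None = None
    results: RadialOrientationResults | None = None
    orientation_extent_um: float | None = None
    nuclei_count: int | None = None
    injections: pd.DataFrame | None = None
    errors: dict[str, str] = field(default_factory=dict)

    def summary_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "parameters": {
                "pixel_size_um": self.config.pixel_size_um,
                "bin_width_um": self.config.bin_width_um,
                "fit_window_min_um": self.config.fit_window_min_um,
                "seed": self.config.seed,
                "extraction": dict(self.config.extraction),
                "segmentation": dict(self.config.segmentation),
            },
            "radius_t0_um": self.radius_t0_um,
            "radius_t48_um": self.radius_t48_um,
            "expansion_ratio": self.expansion_ratio,
            "tumor_center_px": list(self.tumor_center_px) if self.tumor_center_px else None,
            "tumor_radius_um": self.tumor_radius_um,
            "n_fibers": None if self.fibers is None else int(len(self.fibers)),
            "nuclei_count": self.nuclei_count,
            "orientation_extent_um": self.orientation_extent_um,
            "errors": dict(sorted(self.errors.items())),
        }
        if self.results is not None and self.results.converged:
            f = self.results.fit
            out["fit"] = {
                "Y0": f.Y0,
                "L0_um": f.L0,
                "ci95_Y0": f.ci95_Y0,
                "ci95_L0_um": f.ci95_L0,
                "integrated_orientation_um": f.integrated_orientation,
            }
        elif self.results is not None:
            out["fit"] = {"failure": self.results.fit.reason}
        else:
            out["fit"] = None
        return out


def _read_image(path: str) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


def run_well(config: WellConfig) -> WellReport:
    """Run every stage the config's images allow; failures are per-stage.

    Segmentation of the t48 DIC image provides the tumor center and radius
    unless the config overrides them manually; the reflection image feeds
    fiber extraction and the orientation fit; injection entries are scored
    against the fitted profile (and their masks scored for endothelial
    response when given).
    """
    report = WellReport(config=config)
    seg_kwargs = dict(config.segmentation)

    mask_t0 = mask_t48 = None
    if config.dic_t0:
        try:
            mask_t0 = morphometry.segment_spheroid(
                _read_image(config.dic_t0), config.pixel_size_um, **seg_kwargs
            )
            report.radius_t0_um = mask_t0.radius_um
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            report.errors["segment_t0"] = str(exc)
            logger.warning("t0 segmentation failed: %s", exc)
    if config.dic_t48:
        try:
            mask_t48 = morphometry.segment_spheroid(
                _read_image(config.dic_t48), config.pixel_size_um, **seg_kwargs
            )
            report.radius_t48_um = mask_t48.radius_um
        except Exception as exc:  # noqa: BLE001
            report.errors["segment_t48"] = str(exc)
            logger.warning("t48 segmentation failed: %s", exc)
    if mask_t0 is not None and mask_t48 is not None:
        report.expansion_ratio = morphometry.expansion_ratio(mask_t48, mask_t0)

    center = config.tumor_center_px or (mask_t48.center_px if mask_t48 else None)
    radius = config.tumor_radius_um
    if radius is None and mask_t48 is not None:
        radius = mask_t48.radius_um
    report.tumor_center_px = tuple(center) if center is not None else None
    report.tumor_radius_um = radius

    if config.nuclei_stack:
        try:
            report.nuclei_count = morphometry.count_nuclei(_read_image(config.nuclei_stack))
        except Exception as exc:  # noqa: BLE001
            report.errors["count_nuclei"] = str(exc)

    if config.reflection_image:
        if center is None or radius is None:
            report.errors["orientation"] = (
                "tumor center/radius unavailable (no DIC segmentation or manual override)"
            )
        else:
            try:
                params = ExtractionParams(**config.extraction)
                fibers = extract_fibers(_read_image(config.reflection_image), params)
                model = RadialOrientationModel.from_fibers(
                    fibers, center, radius, config.pixel_size_um
                )
                report.fibers = model.fibers.assign(
                    cos2=model.cos2_, distance_um=model.distance_um_
                )
                report.results = model.fit(
                    bin_width_um=config.bin_width_um,
                    fit_window_min_um=config.fit_window_min_um,
                )
                if report.results.converged:
                    report.orientation_extent_um = report.results.orientation_extent()
            except Exception as exc:  # noqa: BLE001
                report.errors["orientation"] = str(exc)
                logger.warning("fiber/orientation stage failed: %s", exc)
    else:
        logger.info("no reflection image: fiber stages skipped")

    if config.injections and center is not None:
        rows = []
        collagen_at_sites: list[float] = []
        for i, inj in enumerate(config.injections):
            row: dict[str, Any] = {"injection": i, "x_px": inj["x_px"], "y_px": inj["y_px"]}
            d_um = (
                float(np.hypot(inj["x_px"] - center[0], inj["y_px"] - center[1]))
                * config.pixel_size_um
            )
            if radius is not None:
                d_um -= radius
            row["distance_to_edge_um"] = d_um
            if report.results is not None and report.results.converged:
                row["collagen_orientation"] = float(report.results.predict(max(d_um, 0.0)))
                collagen_at_sites.append(row["collagen_orientation"])
            if inj.get("mask"):
                try:
                    mask = np.asarray(tifffile.imread(inj["mask"])) > 0
                    # the mask is a crop in its own frame: place the tumor
                    # relative to the injection site, anchored at the centroid
                    ys, xs = np.nonzero(mask)
                    tumor_in_mask = (
                        xs.mean() + (center[0] - inj["x_px"]),
                        ys.mean() + (center[1] - inj["y_px"]),
                    )
                    score = score_mask(mask, tumor_in_mask, config.pixel_size_um)
                    row.update(
                        direction=score.direction,
                        elongation=score.elongation,
                        orientation=score.orientation,
                        low_confidence=score.low_confidence,
                    )
                except Exception as exc:  # noqa: BLE001
                    report.errors[f"injection_{i}"] = str(exc)
            rows.append(row)
        df = pd.DataFrame(rows)
        # oriented/random class: threshold = mean + 1 SD over all injection sites
        if len(collagen_at_sites) >= 2:
            df["collagen_class"] = [
                classify_oriented(v, collagen_at_sites) if np.isfinite(v) else None
                for v in df.get("collagen_orientation", pd.Series(dtype=float))
            ]
        report.injections = df
    return report


def write_report(report: WellReport, out_dir: str | Path) -> dict[str, Path]:
    """Write fibers/bins/injections CSVs and the JSON summary; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if report.fibers is not None:
        paths["fibers"] = out_dir / "fibers.csv"
        report.fibers.to_csv(paths["fibers"], index=False, float_format="%.6g")
    if report.results is not None:
        paths["bins"] = out_dir / "bins.csv"
        report.results.profile.to_frame().to_csv(paths["bins"], index=False, float_format="%.6g")
    if report.injections is not None:
        paths["injections"] = out_dir / "injections.csv"
        report.injections.to_csv(paths["injections"], index=False, float_format="%.6g")
    paths["summary"] = out_dir / "summary.json"
    paths["summary"].write_text(json.dumps(report.summary_dict(), indent=2, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# region comparison (the laser-severing analysis branch)


def _region_mask(
    fibers: pd.DataFrame, region: dict[str, Any], center: Sequence[float], pixel_size_um: float
) -> np.ndarray:
    x = fibers["centroid_x_px"].to_numpy()
    y = fibers["centroid_y_px"].to_numpy()
    kind = region.get("type", "rect")
    if kind == "rect":
        return (
            (x >= region["x0_px"]) & (x < region["x1_px"])
            & (y >= region["y0_px"]) & (y < region["y1_px"])
        )
    if kind == "sector":
        dx, dy = x - center[0], y - center[1]
        r_um = np.hypot(dx, dy) * pixel_size_um
        ang = np.mod(np.degrees(np.arctan2(dy, dx)), 360.0)
        a0, a1 = region["angle0_deg"] % 360.0, region["angle1_deg"] % 360.0
        in_ang = (ang >= a0) & (ang < a1) if a0 <= a1 else (ang >= a0) | (ang < a1)
        return (r_um >= region["r0_um"]) & (r_um < region["r1_um"]) & in_ang
    raise ValueError(f"unknown region type {kind!r}")


def compare_regions(
    fibers: pd.DataFrame,
    region_a: dict[str, Any],
    region_b: dict[str, Any],
    tumor_center_px: Sequence[float],
    tumor_radius_um: float,
    pixel_size_um: float = 0.67,
    bin_width_um: float = 67.0,
    fit_window_min_um: float = 100.0,
) -> dict[str, Any]:
    """Compare collagen orientation between two regions of the same well.

    Used for the severed-vs-connected analysis: each region (rectangle or
    annular sector) gets its own profile and, where enough bins exist, its
    own exponential fit; the per-fiber orientation distributions are
    compared with a two-sided rank-sum test.  Raises if either region holds
    no fibers.
    """
    out: dict[str, Any] = {"regions": {}}
    samples = {}
    for name, region in (("a", region_a), ("b", region_b)):
        sel = _region_mask(fibers, region, tumor_center_px, pixel_size_um)
        sub = fibers.loc[sel]
        if sub.empty:
            raise ValueError(f"region {name} contains no fibers")
        model = RadialOrientationModel(
            sub, tumor_center_px, tumor_radius_um, pixel_size_um
        )
        res = model.fit(bin_width_um=bin_width_um, fit_window_min_um=fit_window_min_um)
        entry: dict[str, Any] = {
            "n_fibers": int(len(sub)),
            "mean_cos2": float(model.cos2_.mean()),
        }
        if res.converged:
            entry["Y0"] = res.Y0
            entry["L0_um"] = res.L0
            entry["integrated_orientation_um"] = res.integrated_orientation
        else:
            entry["fit_failure"] = res.fit.reason
        out["regions"][name] = entry
        samples[name] = model.cos2_
    stat, p = compare_groups(samples["a"], samples["b"], mode="distribution")
    out["mannwhitney_U"] = stat
    out["p_value"] = p
    return out
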