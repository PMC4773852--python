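"""Radial collagen-orientation statistic, distance profile, and decay fit.

For every detected fiber the orientation parameter is ``cos^2`` of the acute
angle between the fiber axis and the radial vector from the tumor-spheroid
center to the fiber centroid: 1 means radially aligned toward the tumor, 0
tangential, and 0.5 is the expectation for uniformly random orientations.

Fibers are binned by their distance to the tumor *edge* (centroid distance
minus spheroid radius), by default in 67 um bins (100 px at 0.67 um/px), and
the binned means are summarized by a two-parameter single exponential that
plateaus at the random baseline::

    y(x) = 0.5 + (Y0 - 0.5) * exp(-x / L0)        for x > 100 um

``Y0`` is the extrapolated orientation at the spheroid edge and ``L0`` the
decay length in um.  The area between the fitted curve and the 0.5 baseline,
``(Y0 - 0.5) * L0``, is the *integrated orientation* — a single scalar for
how far and how strongly a tumor has re-oriented its matrix.  The
*orientation extent* is the largest distance at which the lower 95%
confidence bound of the fitted curve still exceeds 0.5, i.e. where the
alignment is statistically distinguishable from random.

The module follows the statsmodels idiom: build a
:class:`RadialOrientationModel` from a fiber table plus the tumor geometry,
call :meth:`~RadialOrientationModel.fit`, and read estimates, confidence
intervals and diagnostics off the returned :class:`RadialOrientationResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .extraction import Fiber

__all__ = [
    "OrientationProfile",
    "ExponentialFit",
    "FitFailure",
    "fiber_orientation_parameter",
    "fiber_distance_to_edge",
    "orientation_parameters",
    "distances_to_edge_um",
    "bin_profile",
    "fit_exponential",
    "integrated_orientation",
    "orientation_extent",
    "classify_oriented",
    "compare_groups",
    "RadialOrientationModel",
    "RadialOrientationResults",
]

DEFAULT_BIN_WIDTH_UM = 67.0
DEFAULT_FIT_WINDOW_MIN_UM = 100.0


# ---------------------------------------------------------------------------
# per-fiber statistics


def orientation_parameters(
    centroids_px: np.ndarray, angles_deg: np.ndarray, tumor_center_px: Sequence[float]
) -> np.ndarray:
    """Vectorized cos^2 orientation parameter for many fibers at once."""
    centroids_px = np.atleast_2d(np.asarray(centroids_px, dtype=np.float64))
    d = centroids_px - np.asarray(tumor_center_px, dtype=np.float64)
    r = np.hypot(d[:, 0], d[:, 1])
    if np.any(r == 0):
        raise ValueError("fiber centroid coincides with tumor center: radial direction undefined")
    radial_deg = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
    delta = np.radians(np.asarray(angles_deg, dtype=np.float64) - radial_deg)
    return np.cos(delta) ** 2  # cos^2 is invariant under 180-deg axis flips


def fiber_orientation_parameter(fiber: Fiber, tumor_center_px: Sequence[float]) -> float:
    """cos^2 of the angle between one fiber's axis and its radial vector."""
    return float(
        orientation_parameters(
            np.asarray([fiber.centroid_px]), np.asarray([fiber.angle_deg]), tumor_center_px
        )[0]
    )


def distances_to_edge_um(
    centroids_px: np.ndarray,
    tumor_center_px: Sequence[float],
    tumor_radius_um: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Distance from each fiber centroid to the tumor-spheroid edge, in um."""
    if tumor_radius_um < 0:
        raise ValueError("tumor_radius_um must be >= 0")
    centroids_px = np.atleast_2d(np.asarray(centroids_px, dtype=np.float64))
    d = centroids_px - np.asarray(tumor_center_px, dtype=np.float64)
    return np.hypot(d[:, 0], d[:, 1]) * pixel_size_um - tumor_radius_um


def fiber_distance_to_edge(
    fiber: Fiber,
    tumor_center_px: Sequence[float],
    tumor_radius_um: float,
    pixel_size_um: float,
) -> float:
    """Edge distance of a single fiber; negative means inside the spheroid mask."""
    return float(
        distances_to_edge_um(
            np.asarray([fiber.centroid_px]), tumor_center_px, tumor_radius_um, pixel_size_um
        )[0]
    )


# ---------------------------------------------------------------------------
# distance-binned profile


@dataclass(frozen=True)
class OrientationProfile:
    """Distance-binned mean orientation parameter with dispersion and counts.

    ``mean_cos2`` / ``sd_cos2`` are NaN in bins with no fibers; populated
    bins always have means in [0, 1].
    """

    bin_edges_um: np.ndarray
    mean_cos2: np.ndarray
    sd_cos2: np.ndarray
    n_fibers: np.ndarray

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_um": self.bin_edges_um[:-1],
                "bin_hi_um": self.bin_edges_um[1:],
                "bin_center_um": self.bin_centers_um,
                "mean_cos2": self.mean_cos2,
                "sd_cos2": self.sd_cos2,
                "n_fibers": self.n_fibers,
            }
        )


def bin_profile(
    fibers: Iterable[Fiber] | pd.DataFrame,
    tumor_center_px: Sequence[float],
    tumor_radius_um: float,
    pixel_size_um: float,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    max_distance_um: float | None = None,
) -> OrientationProfile:
    """Bin per-fiber orientation parameters by edge distance.

    Bins are half-open ``[lo, hi)`` anchored at the spheroid edge (x = 0);
    fibers with negative edge distance (inside the mask) are excluded.
    Raises if no eligible fiber remains.
    """
    if isinstance(fibers, pd.DataFrame):
        cents = fibers[["centroid_x_px", "centroid_y_px"]].to_numpy(dtype=np.float64)
        angs = fibers["angle_deg"].to_numpy(dtype=np.float64)
    else:
        fibers = list(fibers)
        cents = np.asarray([f.centroid_px for f in fibers], dtype=np.float64).reshape(-1, 2)
        angs = np.asarray([f.angle_deg for f in fibers], dtype=np.float64)
    if cents.shape[0] == 0:
        raise ValueError("no fibers supplied")
    dist = distances_to_edge_um(cents, tumor_center_px, tumor_radius_um, pixel_size_um)
    cos2 = orientation_parameters(cents, angs, tumor_center_px)
    ok = dist >= 0
    if max_distance_um is not None:
        ok &= dist < max_distance_um
    if not np.any(ok):
        raise ValueError("no fibers outside the spheroid: empty profile")
    dist, cos2 = dist[ok], cos2[ok]
    n_bins = int(np.floor(dist.max() / bin_width_um)) + 1
    edges = np.arange(n_bins + 1, dtype=np.float64) * bin_width_um
    idx = np.minimum((dist / bin_width_um).astype(np.intp), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    s1 = np.bincount(idx, weights=cos2, minlength=n_bins)
    s2 = np.bincount(idx, weights=cos2 * cos2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, s1 / np.maximum(counts, 1), np.nan)
        var = s2 / np.maximum(counts, 1) - mean**2
        sd = np.where(counts > 1, np.sqrt(np.maximum(var, 0.0) * counts / np.maximum(counts - 1, 1)), np.nan)
    return OrientationProfile(edges, mean, sd, counts)


# ---------------------------------------------------------------------------
# exponential plateau fit


@dataclass(frozen=True)
class ExponentialFit:
    """Two-parameter exponential plateauing at 0.5 fitted to a profile.

    ``integrated_orientation`` is exactly ``(Y0 - 0.5) * L0`` (um): the area
    between the fitted curve and the random baseline.  Confidence half-widths
    are 95%, from the fit covariance (delta method, Student t with
    ``n_bins_fit - 2`` dof).
    """

    Y0: float
    L0: float
    ci95_Y0: float
    ci95_L0: float
    fit_window_min_um: float
    n_bins_fit: int
    cov: np.ndarray

    def __post_init__(self) -> None:
        if not self.L0 > 0:
            raise ValueError("decay length L0 must be positive")

    @property
    def integrated_orientation(self) -> float:
        return (self.Y0 - 0.5) * self.L0

    @property
    def integrated_orientation_se(self) -> float:
        """Delta-method standard error of (Y0 - 0.5) * L0 from the fit covariance."""
        grad = np.array([self.L0, self.Y0 - 0.5])
        return float(np.sqrt(max(grad @ self.cov @ grad, 0.0)))

    def predict(self, x_um: np.ndarray | float) -> np.ndarray | float:
        return 0.5 + (self.Y0 - 0.5) * np.exp(-np.asarray(x_um, dtype=np.float64) / self.L0)

    def conf_band(self, x_um: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) 95% confidence band of the fitted curve (delta method)."""
        x = np.asarray(x_um, dtype=np.float64)
        e = np.exp(-x / self.L0)
        jac = np.stack([e, (self.Y0 - 0.5) * e * x / self.L0**2], axis=-1)
        var = np.einsum("...i,ij,...j->...", jac, self.cov, jac)
        dof = max(self.n_bins_fit - 2, 1)
        half = stats.t.ppf(0.975, dof) * np.sqrt(np.maximum(var, 0.0))
        y = self.predict(x)
        return y - half, y + half


@dataclass(frozen=True)
class FitFailure:
    """Explicit fit-failure marker (too few bins or no convergence)."""

    reason: str

    def __bool__(self) -> bool:  # allows `if fit:` guards
        return False


def fit_exponential(
    profile: OrientationProfile,
    fit_window_min_um: float = DEFAULT_FIT_WINDOW_MIN_UM,
    weighted: bool = False,
) -> ExponentialFit | FitFailure:
    """Least-squares fit of ``y = 0.5 + (Y0 - 0.5) exp(-x/L0)`` to bin means.

    Only bins whose centers lie beyond ``fit_window_min_um`` (default 100 um,
    excluding the crowded near-edge zone) enter the fit.  ``weighted=True``
    weights bins by 1/SE of the bin mean; the default is unweighted.  Bounds:
    Y0 in [0, 1], L0 in (0, 10 * max distance]; initialized at the first
    usable bin mean and half the profile span.
    """
    x_all = profile.bin_centers_um
    use = (profile.n_fibers > 0) & (x_all > fit_window_min_um)
    if use.sum() < 3:
        return FitFailure(f"only {int(use.sum())} populated bins beyond {fit_window_min_um} um")
    x, y = x_all[use], profile.mean_cos2[use]
    sigma = None
    if weighted:
        se = profile.sd_cos2[use] / np.sqrt(profile.n_fibers[use])
        sigma = np.where(np.isfinite(se) & (se > 0), se, np.nanmax(se[se > 0]) if np.any(se > 0) else 1.0)
    span = float(x.max() - x.min())
    bounds = ([0.0, 1e-9], [1.0, 10.0 * float(x.max())])
    # initialize the edge level from the first few usable bins (a single
    # noisy bin can park the solver in the degenerate steep-decay basin)
    y0_init = float(np.clip(np.mean(y[: min(3, len(y))]), 0.0, 1.0))
    starts = [
        (y0_init, max(span / 2.0, 1.0)),
        (y0_init, max(span / 6.0, 1.0)),
        (0.5 + 0.5 * (y0_init - 0.5), max(span, 1.0)),
    ]

    def model(xv: np.ndarray, y0: float, l0: float) -> np.ndarray:
        return 0.5 + (y0 - 0.5) * np.exp(-xv / l0)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    last_err: Exception | None = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                model, x, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, optimize.OptimizeWarning) as exc:
            last_err = exc
            continue
        resid = y - model(x, *popt)
        if sigma is not None:
            resid = resid / sigma
        ssr = float(np.dot(resid, resid))
        if best is None or ssr < best[0] - 1e-12:
            best = (ssr, popt, pcov)
    if best is None:
        return FitFailure(f"exponential fit did not converge: {last_err}")
    _, popt, pcov = best
    dof = max(len(x) - 2, 1)
    tcrit = stats.t.ppf(0.975, dof)
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    return ExponentialFit(
        Y0=float(popt[0]),
        L0=float(popt[1]),
        ci95_Y0=float(tcrit * se[0]),
        ci95_L0=float(tcrit * se[1]),
        fit_window_min_um=fit_window_min_um,
        n_bins_fit=len(x),
        cov=np.asarray(pcov, dtype=np.float64),
    )


def integrated_orientation(fit: ExponentialFit) -> float:
    """Area between the fitted curve and the 0.5 baseline: (Y0 - 0.5) * L0, um."""
    return fit.integrated_orientation


def orientation_extent(
    profile: OrientationProfile, fit: ExponentialFit | FitFailure
) -> float:
    """Largest distance (um) where the fitted curve is confidently above random.

    Scans the fitted range for the largest x at which the lower 95%
    confidence bound of ``y(x)`` exceeds 0.5; 0 if it never does.  Capped at
    the far edge of the last populated bin (no extrapolation beyond data).
    """
    if isinstance(fit, FitFailure):
        raise ValueError(f"cannot compute extent from a failed fit: {fit.reason}")
    populated = np.nonzero(profile.n_fibers > 0)[0]
    x_max = float(profile.bin_edges_um[populated[-1] + 1])
    if fit.Y0 <= 0.5:
        return 0.0
    grid = np.linspace(0.0, x_max, 4096)
    lower, _ = fit.conf_band(grid)
    above = lower > 0.5
    if not above.any():
        return 0.0
    last = int(np.nonzero(above)[0][-1])
    if last == len(grid) - 1:
        return x_max
    # refine the crossing between the last above-threshold grid point and the next
    f = lambda x: fit.conf_band(np.asarray([x]))[0][0] - 0.5
    return float(optimize.brentq(f, grid[last], grid[last + 1]))


# ---------------------------------------------------------------------------
# group-level statistics


def classify_oriented(value: float, reference_values: Sequence[float]) -> str:
    """'oriented' iff value exceeds mean + 1 SD of the reference measurements."""
    ref = np.asarray(reference_values, dtype=np.float64)
    if ref.size < 2 or not np.all(np.isfinite(ref)):
        raise ValueError("need >= 2 finite reference values")
    threshold = ref.mean() + ref.std(ddof=1)
    return "oriented" if value > threshold else "random"


def compare_groups(
    sample_a: Sequence[float], sample_b: Sequence[float], mode: str
) -> tuple[float, float]:
    """Two-group comparison: rank-sum for distributions, t-test for integrals.

    mode='distribution' -> two-sided Mann-Whitney U; mode='integrated' ->
    two-sided unpaired t-test.  Returns (statistic, p-value).
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    if mode == "distribution":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif mode == "integrated":
        res = stats.ttest_ind(a, b, equal_var=True)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'distribution' or 'integrated'")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# model / results


class RadialOrientationModel:
    """Radial collagen-orientation decay model for one tumor spheroid.

    Parameters
    ----------
    fibers : DataFrame with columns centroid_x_px, centroid_y_px, angle_deg
        (e.g. from :func:`fiberorient.extraction.extract_fibers` via
        :meth:`from_fibers`, or a ground-truth table).
    tumor_center_px : (x, y) center of the tumor spheroid in pixels.
    tumor_radius_um : spheroid radius (edge distances are measured from it).
    pixel_size_um : image scale, default 0.67 um/px.
    """

    def __init__(
        self,
        fibers: pd.DataFrame,
        tumor_center_px: Sequence[float],
        tumor_radius_um: float,
        pixel_size_um: float = 0.67,
    ) -> None:
        required = {"centroid_x_px", "centroid_y_px", "angle_deg"}
        missing = required - set(fibers.columns)
        if missing:
            raise ValueError(f"fiber table missing columns: {sorted(missing)}")
        if pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.fibers = fibers.reset_index(drop=True)
        self.tumor_center_px = np.asarray(tumor_center_px, dtype=np.float64)
        self.tumor_radius_um = float(tumor_radius_um)
        self.pixel_size_um = float(pixel_size_um)
        cents = self.fibers[["centroid_x_px", "centroid_y_px"]].to_numpy()
        self.cos2_ = orientation_parameters(
            cents, self.fibers["angle_deg"].to_numpy(), self.tumor_center_px
        )
        self.distance_um_ = distances_to_edge_um(
            cents, self.tumor_center_px, self.tumor_radius_um, self.pixel_size_um
        )

    @classmethod
    def from_fibers(
        cls,
        fibers: Iterable[Fiber],
        tumor_center_px: Sequence[float],
        tumor_radius_um: float,
        pixel_size_um: float = 0.67,
    ) -> "RadialOrientationModel":
        df = pd.DataFrame(
            {
                "centroid_x_px": [f.centroid_px[0] for f in fibers],
                "centroid_y_px": [f.centroid_px[1] for f in fibers],
                "angle_deg": [f.angle_deg for f in fibers],
            }
        )
        return cls(df, tumor_center_px, tumor_radius_um, pixel_size_um)

    @classmethod
    def from_dataframe(
        cls,
        fibers: pd.DataFrame,
        tumor_center_px: Sequence[float],
        tumor_radius_um: float,
        pixel_size_um: float = 0.67,
    ) -> "RadialOrientationModel":
        return cls(fibers, tumor_center_px, tumor_radius_um, pixel_size_um)

    def fit(
        self,
        bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
        fit_window_min_um: float = DEFAULT_FIT_WINDOW_MIN_UM,
        weighted: bool = False,
        max_distance_um: float | None = None,
    ) -> "RadialOrientationResults":
        profile = bin_profile(
            self.fibers,
            self.tumor_center_px,
            self.tumor_radius_um,
            self.pixel_size_um,
            bin_width_um=bin_width_um,
            max_distance_um=max_distance_um,
        )
        fit = fit_exponential(profile, fit_window_min_um=fit_window_min_um, weighted=weighted)
        return RadialOrientationResults(self, profile, fit)


class RadialOrientationResults:
    """Fitted radial-orientation decay: estimates, CIs, extent, summary."""

    def __init__(
        self,
        model: RadialOrientationModel,
        profile: OrientationProfile,
        fit: ExponentialFit | FitFailure,
    ) -> None:
        self.model = model
        self.profile = profile
        self.fit = fit

    @property
    def converged(self) -> bool:
        return isinstance(self.fit, ExponentialFit)

    def _require_fit(self) -> ExponentialFit:
        if isinstance(self.fit, FitFailure):
            raise ValueError(f"fit failed: {self.fit.reason}")
        return self.fit

    @property
    def Y0(self) -> float:
        return self._require_fit().Y0

    @property
    def L0(self) -> float:
        return self._require_fit().L0

    @property
    def ci95_Y0(self) -> float:
        return self._require_fit().ci95_Y0

    @property
    def ci95_L0(self) -> float:
        return self._require_fit().ci95_L0

    @property
    def integrated_orientation(self) -> float:
        return self._require_fit().integrated_orientation

    def predict(self, x_um: np.ndarray | float) -> np.ndarray | float:
        return self._require_fit().predict(x_um)

    def orientation_extent(self) -> float:
        return orientation_extent(self.profile, self._require_fit())

    def summary(self) -> str:
        lines = ["Radial collagen orientation fit", "=" * 44]
        lines.append(f"fibers used          {int(self.profile.n_fibers.sum()):>12d}")
        lines.append(f"populated bins       {int((self.profile.n_fibers > 0).sum()):>12d}")
        if isinstance(self.fit, FitFailure):
            lines.append(f"fit status            FAILED: {self.fit.reason}")
            return "\n".join(lines)
        f = self.fit
        lines += [
            f"Y0 (edge orientation) {f.Y0:>11.4f} +/- {f.ci95_Y0:.4f} (95% CI)",
            f"L0 (decay length, um) {f.L0:>11.1f} +/- {f.ci95_L0:.1f} (95% CI)",
            f"integrated orientation (um) {f.integrated_orientation:>11.1f}",
            f"orientation extent (um)     {self.orientation_extent():>11.1f}",
            f"fit window x > {f.fit_window_min_um:.0f} um on {f.n_bins_fit} bins",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Profile points with the fitted curve and its 95% band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.profile
        ok = p.n_fibers > 0
        se = p.sd_cos2[ok] / np.sqrt(p.n_fibers[ok])
        ax.errorbar(p.bin_centers_um[ok], p.mean_cos2[ok], yerr=se, fmt="o", ms=3, label="bins")
        if isinstance(self.fit, ExponentialFit):
            xg = np.linspace(0, p.bin_edges_um[-1], 400)
            lo, hi = self.fit.conf_band(xg)
            ax.plot(xg, self.fit.predict(xg), "-", label="exponential fit")
            ax.fill_between(xg, lo, hi, alpha=0.2, label="95% band")
        ax.axhline(0.5, color="gray", ls="--", lw=1)
        ax.set_xlabel("distance from spheroid edge (um)")
        ax.set_ylabel("orientation parameter $\\cos^2\\theta$")
        ax.legend()
        return ax
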