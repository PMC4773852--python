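"""Tests for the radial orientation statistic, profile, and exponential fit."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from fiberorient.extraction import Fiber
from fiberorient.orientation import (
    ExponentialFit,
    FitFailure,
    OrientationProfile,
    RadialOrientationModel,
    bin_profile,
    classify_oriented,
    compare_groups,
    distances_to_edge_um,
    fiber_distance_to_edge,
    fiber_orientation_parameter,
    fit_exponential,
    integrated_orientation,
    orientation_extent,
    orientation_parameters,
)


def _fiber(x, y, angle):
    return Fiber(centroid_px=(x, y), angle_deg=angle, pixel_count=25, eccentricity=0.95)


class TestOrientationParameter:
    def test_radial_fiber_scores_one(self):
        assert fiber_orientation_parameter(_fiber(300.0, 0.0, 0.0), (0, 0)) == pytest.approx(1.0)

    def test_tangential_fiber_scores_zero(self):
        assert fiber_orientation_parameter(_fiber(300.0, 0.0, 90.0), (0, 0)) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_45_degrees_scores_half(self):
        assert fiber_orientation_parameter(_fiber(300.0, 0.0, 45.0), (0, 0)) == pytest.approx(0.5)

    def test_invariant_under_axis_flip_and_scene_rotation(self, rng):
        for _ in range(50):
            x, y = rng.uniform(-400, 400, 2)
            if np.hypot(x, y) < 1:
                continue
            ang = rng.uniform(0, 180)
            base = fiber_orientation_parameter(_fiber(x, y, ang), (0, 0))
            flipped = fiber_orientation_parameter(_fiber(x, y, (ang + 180) % 360 % 180), (0, 0))
            assert base == pytest.approx(flipped)
            # rotate the whole scene about the tumor center
            phi = rng.uniform(0, 360)
            c, s = np.cos(np.radians(phi)), np.sin(np.radians(phi))
            xr, yr = c * x - s * y, s * x + c * y
            rotated = fiber_orientation_parameter(
                _fiber(xr, yr, (ang + phi) % 180), (0, 0)
            )
            assert base == pytest.approx(rotated, abs=1e-9)

    def test_coincident_centroid_raises(self):
        with pytest.raises(ValueError):
            fiber_orientation_parameter(_fiber(0.0, 0.0, 10.0), (0, 0))

    def test_uniform_orientations_average_to_half(self):
        rng = np.random.default_rng(0)
        n = 100_000
        r = rng.uniform(200, 3000, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        cents = np.stack([r * np.cos(phi), r * np.sin(phi)], axis=1)
        angles = rng.uniform(0, 180, n)
        cos2 = orientation_parameters(cents, angles, (0, 0))
        assert cos2.mean() == pytest.approx(0.5, abs=0.005)


class TestDistances:
    def test_simple_arithmetic(self):
        f = _fiber(200.0, 0.0, 0.0)
        assert fiber_distance_to_edge(f, (0, 0), 116.0, 1.0) == pytest.approx(84.0)

    def test_edge_fiber_distance_zero(self):
        f = _fiber(100.0, 0.0, 0.0)
        assert fiber_distance_to_edge(f, (0, 0), 100.0, 1.0) == pytest.approx(0.0)

    def test_inside_fiber_negative_and_excluded_from_profile(self):
        inside = _fiber(50.0, 0.0, 0.0)
        outside = _fiber(400.0, 0.0, 0.0)
        assert fiber_distance_to_edge(inside, (0, 0), 100.0, 1.0) < 0
        profile = bin_profile([inside, outside], (0, 0), 100.0, 1.0)
        assert profile.n_fibers.sum() == 1


class TestBinProfile:
    def test_hand_built_six_fiber_profile(self):
        """Bin means equal hand-computed cos^2 values exactly.

        Tumor at origin, radius 0, pixel size 1, bin width 67 um.
        Fibers on the +x axis: angles 0 (cos2=1), 60 (0.25), 90 (0) at
        distance 30 -> bin 0 mean = (1 + 0.25 + 0)/3 = 5/12.
        At distance 100 (bin 1): angles 45 (0.5), 30 (0.75) -> mean 0.625.
        At distance 150 (bin 2): angle 0 -> mean 1.
        """
        fibers = [
            _fiber(30.0, 0.0, 0.0),
            _fiber(30.0, 0.0, 60.0),
            _fiber(30.0, 0.0, 90.0),
            _fiber(100.0, 0.0, 45.0),
            _fiber(100.0, 0.0, 30.0),
            _fiber(150.0, 0.0, 0.0),
        ]
        p = bin_profile(fibers, (0, 0), 0.0, 1.0)
        assert p.n_fibers.tolist() == [3, 2, 1]
        assert p.mean_cos2[0] == pytest.approx(5 / 12)
        assert p.mean_cos2[1] == pytest.approx(0.625)
        assert p.mean_cos2[2] == pytest.approx(1.0)

    def test_all_radial_field_all_bins_one(self, rng):
        r = rng.uniform(50, 800, 500)
        phi = rng.uniform(0, 2 * np.pi, 500)
        fibers = [
            _fiber(ri * np.cos(p), ri * np.sin(p), np.degrees(p) % 180)
            for ri, p in zip(r, phi)
        ]
        prof = bin_profile(fibers, (0, 0), 10.0, 1.0)
        ok = prof.n_fibers > 0
        assert np.allclose(prof.mean_cos2[ok], 1.0, atol=1e-9)

    def test_no_eligible_fibers_raises(self):
        with pytest.raises(ValueError):
            bin_profile([_fiber(10.0, 0.0, 0.0)], (0, 0), 100.0, 1.0)


def _profile_from_curve(y0, l0, n_bins=40, bin_w=67.0, n_per_bin=1000):
    edges = np.arange(n_bins + 1) * bin_w
    centers = 0.5 * (edges[:-1] + edges[1:])
    means = 0.5 + (y0 - 0.5) * np.exp(-centers / l0)
    return OrientationProfile(
        bin_edges_um=edges,
        mean_cos2=means,
        sd_cos2=np.full(n_bins, 0.05),
        n_fibers=np.full(n_bins, n_per_bin),
    )


class TestExponentialFit:
    def test_noiseless_profile_recovered_exactly(self):
        prof = _profile_from_curve(0.9, 500.0)
        fit = fit_exponential(prof)
        assert isinstance(fit, ExponentialFit)
        assert fit.Y0 == pytest.approx(0.9, abs=1e-6)
        assert fit.L0 == pytest.approx(500.0, rel=1e-5)

    def test_flat_profile_gives_half_and_zero_integral(self):
        prof = _profile_from_curve(0.5, 500.0)
        fit = fit_exponential(prof)
        assert isinstance(fit, ExponentialFit)
        assert fit.Y0 == pytest.approx(0.5, abs=0.02)
        assert abs(fit.integrated_orientation) < 1.0

    def test_too_few_bins_is_explicit_failure(self):
        prof = _profile_from_curve(0.9, 500.0, n_bins=2)
        fit = fit_exponential(prof)
        assert isinstance(fit, FitFailure)
        assert not fit

    def test_integrated_orientation_closed_form_and_quadrature(self):
        fit = ExponentialFit(Y0=0.93, L0=412.0, ci95_Y0=0.01, ci95_L0=20.0,
                             fit_window_min_um=100.0, n_bins_fit=20, cov=np.eye(2) * 1e-6)
        assert integrated_orientation(fit) == pytest.approx((0.93 - 0.5) * 412.0)
        quad, _ = integrate.quad(lambda x: fit.predict(x) - 0.5, 0, np.inf)
        assert integrated_orientation(fit) == pytest.approx(quad, rel=1e-6)
        trivial = ExponentialFit(Y0=1.0, L0=100.0, ci95_Y0=0, ci95_L0=0,
                                 fit_window_min_um=100.0, n_bins_fit=5, cov=np.zeros((2, 2)))
        assert trivial.integrated_orientation == pytest.approx(50.0)

    def test_l0_must_be_positive(self):
        with pytest.raises(ValueError):
            ExponentialFit(Y0=0.9, L0=0.0, ci95_Y0=0, ci95_L0=0,
                           fit_window_min_um=100.0, n_bins_fit=5, cov=np.zeros((2, 2)))


class TestOrientationExtent:
    def test_flat_profile_extent_zero(self):
        prof = _profile_from_curve(0.5, 500.0)
        fit = fit_exponential(prof)
        assert orientation_extent(prof, fit) == 0.0

    def test_strong_noiseless_profile_extends_to_last_bin(self):
        prof = _profile_from_curve(0.95, 2000.0)
        fit = fit_exponential(prof)
        assert orientation_extent(prof, fit) == pytest.approx(prof.bin_edges_um[-1])

    def test_extent_monotone_in_radial_bias(self):
        """Stronger fields stay confidently above random out to larger radii."""
        from fiberorient.synthetic import FiberFieldParams, generate_fiber_field

        extents = []
        for w0 in (0.25, 0.5, 0.75):
            p = FiberFieldParams(image_size_px=(2000, 2000), pixel_size_um=2.0,
                                 tumor_center_px=(1000.0, 1000.0), tumor_radius_um=300.0,
                                 n_fibers=15000, radial_bias_w0=w0, decay_length_um=500.0,
                                 seed=21)
            model = RadialOrientationModel.from_fibers(
                generate_fiber_field(p), (1000, 1000), 300.0, 2.0
            )
            res = model.fit()
            extents.append(res.orientation_extent())
        assert extents[0] < extents[1] < extents[2]


class TestClassifyOriented:
    def test_value_at_mean_is_random(self):
        assert classify_oriented(0.6, [0.5, 0.6, 0.7]) == "random"

    def test_two_sd_above_is_oriented(self):
        ref = [0.5, 0.55, 0.6, 0.65, 0.7]
        thr = np.mean(ref) + np.std(ref, ddof=1)
        assert classify_oriented(thr + np.std(ref, ddof=1), ref) == "oriented"

    def test_threshold_matches_hand_arithmetic(self):
        ref = [0.50, 0.55, 0.60, 0.70, 0.40]  # mean 0.55, sd 0.1118...
        sd = np.std(ref, ddof=1)
        assert classify_oriented(0.55 + sd + 1e-9, ref) == "oriented"
        assert classify_oriented(0.55 + sd - 1e-9, ref) == "random"

    def test_degenerate_reference_raises(self):
        with pytest.raises(ValueError):
            classify_oriented(0.5, [0.4])


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        a = [0.1, 0.2, 0.3, 0.4, 0.5]
        _, p = compare_groups(a, a, mode="distribution")
        assert p > 0.99

    def test_u_statistic_matches_exhaustive_enumeration(self):
        """Mann-Whitney p-value vs brute-force null over all 4-vs-4 splits."""
        a = [1.2, 3.4, 0.5, 2.2]
        b = [4.1, 5.0, 3.9, 4.4]
        u_obs, p = compare_groups(a, b, mode="distribution")

        def u_stat(x, y):
            return sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
                1 for xi in x for yi in y if xi == yi
            )

        pooled = a + b
        null = []
        for comb in itertools.combinations(range(8), 4):
            x = [pooled[i] for i in comb]
            y = [pooled[i] for i in range(8) if i not in comb]
            null.append(u_stat(x, y))
        null = np.array(null)
        n1 = n2 = 4
        mu = n1 * n2 / 2
        p_exact = np.mean(np.abs(null - mu) >= abs(u_stat(a, b) - mu))
        assert u_obs == pytest.approx(u_stat(a, b))
        assert p == pytest.approx(p_exact, abs=1e-9)

    def test_t_statistic_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.5, 3.5, 4.5, 5.5])
        t, p = compare_groups(a, b, mode="integrated")
        sp2 = ((a.var(ddof=1) * 3) + (b.var(ddof=1) * 3)) / 6
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert t == pytest.approx(t_hand)

    def test_insufficient_observations_raise(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0], mode="distribution")


class TestModelResults:
    def test_from_dataframe_and_summary(self):
        rng = np.random.default_rng(3)
        n = 5000
        r = rng.uniform(200, 2000, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        df = pd.DataFrame(
            {
                "centroid_x_px": r * np.cos(phi),
                "centroid_y_px": r * np.sin(phi),
                "angle_deg": rng.uniform(0, 180, n),
            }
        )
        model = RadialOrientationModel.from_dataframe(df, (0, 0), 100.0, 1.0)
        res = model.fit()
        assert res.converged
        assert abs(res.Y0 - 0.5) < 0.05
        text = res.summary()
        assert "Y0" in text and "decay length" in text

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            RadialOrientationModel(pd.DataFrame({"x": [1]}), (0, 0), 10.0)
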