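"""Tests for DIC spheroid segmentation, radius measurement, nuclei counting."""

import numpy as np
import pytest

from fiberorient.morphometry import (
    count_nuclei,
    expansion_ratio,
    mask_morphometrics,
    normalize_dic,
    segment_core,
    segment_full_spheroid,
    segment_spheroid,
)
from fiberorient.synthetic import generate_nuclei_stack, generate_spheroid_phantom


class TestNormalizeDic:
    def test_constant_image_maps_to_ones(self):
        out = normalize_dic(np.full((64, 64), 7.0), median_radius_px=5)
        assert np.allclose(out, 1.0, atol=0.01)

    def test_illumination_gradient_removed(self, rng):
        yy, xx = np.mgrid[:128, :128]
        illumination = 1.0 + 0.8 * xx / 127.0  # strong left-right shading
        texture = 1.0 + 0.02 * rng.standard_normal((128, 128))
        img = illumination * texture
        out = normalize_dic(img, median_radius_px=30)
        # the shading dominates the raw std; normalization removes it
        assert img.std() / out.std() >= 5.0

    def test_zero_background_pixels_guarded(self):
        img = np.ones((64, 64))
        img[:10] = 0.0
        out = normalize_dic(img, median_radius_px=5)
        assert np.all(np.isfinite(out))

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError):
            normalize_dic(np.zeros((32, 32)))


class TestSegmentCore:
    def test_uniform_image_has_no_core(self):
        with pytest.raises(ValueError):
            segment_core(np.ones((64, 64)))

    def test_dark_disk_recovered_with_good_iou(self):
        img, _ = generate_spheroid_phantom(core_radius_px=60, rim_width_px=0,
                                           image_size_px=(300, 300),
                                           center_px=(150.0, 150.0), seed=2)
        core = segment_core(normalize_dic(img))
        yy, xx = np.mgrid[:300, :300]
        truth = np.hypot(xx - 150, yy - 150) <= 60
        iou = (core & truth).sum() / (core | truth).sum()
        assert iou >= 0.8

    def test_central_component_kept_among_dark_blobs(self):
        img = np.ones((200, 200))
        yy, xx = np.mgrid[:200, :200]
        img[np.hypot(xx - 100, yy - 100) <= 20] = 0.0  # central
        img[np.hypot(xx - 30, yy - 30) <= 15] = 0.0    # corner decoy
        core = segment_core(img, blur_sigma_px=2.0)
        assert core[100, 100] and not core[30, 30]


class TestFullSpheroid:
    @pytest.mark.parametrize("core,rim", [(75, 30), (150, 20)])
    def test_phantom_radius_within_10_percent(self, core, rim):
        img, truth = generate_spheroid_phantom(core_radius_px=core, rim_width_px=rim, seed=1)
        sm = segment_spheroid(img, pixel_size_um=1.0)
        r_true = np.sqrt(truth.sum() / np.pi)
        assert sm.radius_um == pytest.approx(r_true, rel=0.10)

    def test_rimless_phantom_radius_close_to_core(self):
        img, _ = generate_spheroid_phantom(core_radius_px=80, rim_width_px=0, seed=3)
        sm = segment_spheroid(img, pixel_size_um=1.0)
        assert sm.radius_um == pytest.approx(80.0, rel=0.10)

    def test_perfect_disk_radius_definition(self):
        yy, xx = np.mgrid[:200, :200]
        disk = np.hypot(xx - 100, yy - 100) <= 55
        sm = mask_morphometrics(disk, pixel_size_um=0.5)
        assert sm.radius_um == pytest.approx(0.5 * np.sqrt(disk.sum() / np.pi))

    def test_empty_core_propagates(self):
        with pytest.raises(ValueError):
            segment_full_spheroid(np.ones((64, 64)), np.zeros((64, 64), bool))

    def test_translation_invariance_of_radius(self):
        a, _ = generate_spheroid_phantom(center_px=(256.0, 256.0), core_radius_px=80,
                                         rim_width_px=25, seed=5)
        b, _ = generate_spheroid_phantom(center_px=(200.0, 290.0), core_radius_px=80,
                                         rim_width_px=25, seed=5)
        ra = segment_spheroid(a, pixel_size_um=1.0).radius_um
        rb = segment_spheroid(b, pixel_size_um=1.0).radius_um
        assert rb == pytest.approx(ra, rel=0.02)

    def test_segmentation_is_deterministic(self):
        img, _ = generate_spheroid_phantom(seed=8)
        m1 = segment_spheroid(img, pixel_size_um=1.0)
        m2 = segment_spheroid(img, pixel_size_um=1.0)
        assert np.array_equal(m1.mask, m2.mask)


class TestExpansionRatio:
    def test_identical_masks_ratio_one(self):
        yy, xx = np.mgrid[:100, :100]
        disk = np.hypot(xx - 50, yy - 50) <= 30
        sm = mask_morphometrics(disk, 1.0)
        assert expansion_ratio(sm, sm) == pytest.approx(1.0)

    def test_reported_experiment_scale(self):
        """116 um -> 527 um growth corresponds to a ~4.54-fold expansion."""
        yy, xx = np.mgrid[:600, :600]
        small = np.hypot(xx - 300, yy - 300) <= 116 / 2
        large = np.hypot(xx - 300, yy - 300) <= 527 / 2
        r = expansion_ratio(mask_morphometrics(large, 2.0), mask_morphometrics(small, 2.0))
        assert r == pytest.approx(527 / 116, rel=0.02)

    def test_phantom_pair_threefold_growth(self):
        a, ta = generate_spheroid_phantom(core_radius_px=50, rim_width_px=0, seed=4)
        b, tb = generate_spheroid_phantom(core_radius_px=150, rim_width_px=0, seed=4)
        ra = segment_spheroid(a, pixel_size_um=1.0)
        rb = segment_spheroid(b, pixel_size_um=1.0)
        assert expansion_ratio(rb, ra) == pytest.approx(3.0, rel=0.10)

    def test_zero_initial_radius_rejected(self):
        yy, xx = np.mgrid[:50, :50]
        disk = np.hypot(xx - 25, yy - 25) <= 10
        sm = mask_morphometrics(disk, 1.0)
        degenerate = sm.__class__(mask=sm.mask, center_px=sm.center_px, radius_um=0.0,
                                  major_axis_px=1, minor_axis_px=1, major_angle_deg=0,
                                  pixel_size_um=1.0)
        with pytest.raises(ValueError):
            expansion_ratio(sm, degenerate)


class TestCountNuclei:
    def test_blank_stack_counts_zero(self):
        stack, _ = generate_nuclei_stack(0, noise_sigma=0.0, seed=1)
        assert count_nuclei(stack) == 0

    @pytest.mark.parametrize("n", [5, 50])
    def test_separated_nuclei_counted_exactly(self, n):
        stack, truth = generate_nuclei_stack(n, seed=6)
        assert count_nuclei(stack) == truth == n

    def test_touching_pair_split_by_watershed(self):
        centers = np.array([[100.0, 100.0], [100.0, 109.0]])  # 3 sigma apart
        stack, _ = generate_nuclei_stack(2, centers_px=centers, seed=3)
        assert count_nuclei(stack) == 2

    def test_counting_monotone_in_truth(self):
        counts = [count_nuclei(generate_nuclei_stack(n, seed=9)[0]) for n in (5, 15, 30)]
        assert counts == sorted(counts)
        assert counts == [5, 15, 30]  # separation >= 4 sigma => exact

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            count_nuclei(np.zeros((0, 10, 10)))
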