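"""Segmentation, dual-channel counting, and profile extraction."""

import math

import numpy as np
import pytest
from skimage.draw import disk

from ebmorph.containers import ZStack
from ebmorph.imaging import (count_edu_fraction, diametral_profile,
                             measure_pattern_radii, segment_nuclei, zaxis_profile)
from ebmorph.synthetic import (SectionSpec, StackSpec, gen_marker_section,
                               gen_nuclei_stack)


def plane_with_disks(centers, radius_px, size=300):
    img = np.zeros((size, size), np.float32)
    for c in centers:
        rr, cc = disk(c, radius_px, shape=(size, size))
        img[rr, cc] = 0.8
    return img


class TestSegmentNuclei:
    def test_disjoint_disks_counted_exactly(self):
        """50 well-separated disks of ~100 µm² each -> 50 objects."""
        rad = math.sqrt(100 / math.pi)  # px at 1 µm/px
        centers = [(30 + 24 * i, 30 + 24 * j) for i in range(10) for j in range(5)]
        img = plane_with_disks(centers, rad, size=300)
        objs = segment_nuclei(img, pixel_size_um=1.0)
        assert len(objs) == 50

    def test_area_filter_inclusive_at_both_bounds(self):
        """Filter set exactly to the measured areas of the middle two disks."""
        radii = [2.0, 3.0, 9.0, 12.0]
        centers = [(40, 40), (40, 120), (120, 40), (120, 120)]
        img = plane_with_disks([], 1, size=160)
        measured = []
        for c, r in zip(centers, radii):
            rr, cc = disk(c, r)
            img[rr, cc] = 0.8
            measured.append(len(rr))  # px == µm² at 1 µm/px
        lo, hi = sorted(measured)[1:3]
        objs = segment_nuclei(img, pixel_size_um=1.0, area_range_um2=(lo, hi))
        assert sorted(objs.areas_um2) == pytest.approx([lo, hi])

    def test_touching_disks_split_by_watershed(self):
        """Dumbbell of two equal just-touching disks -> 2 objects."""
        rad = 8.0
        img = plane_with_disks([(100, 100), (100, 100 + 2 * int(rad))], rad, size=200)
        objs = segment_nuclei(img, pixel_size_um=1.0, area_range_um2=(15, 350))
        assert len(objs) == 2

    def test_blank_plane_yields_empty_result(self):
        objs = segment_nuclei(np.zeros((50, 50)), pixel_size_um=1.0)
        assert len(objs) == 0

    def test_nonpositive_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            segment_nuclei(np.zeros((10, 10)), pixel_size_um=0.0)

    def test_exact_recovery_on_planted_stacks(self):
        """Non-overlapping in-range nuclei: exact counts on >= 95% of seeds."""
        exact = 0
        for seed in range(10):
            spec = StackSpec(eb_radius_um=80, n_nuclei=60, pixel_size_um=1.0,
                             nucleus_area_range_um2=(40, 120), n_planes=1, seed=seed)
            stack, gt = gen_nuclei_stack(spec)
            n = len(segment_nuclei(stack.channel(0)[0], 1.0))
            exact += n == gt.n_total(plane=0)
        assert exact >= 9


class TestCountEdu:
    def test_planted_thirty_percent_recovered_exactly(self, small_stack):
        stack, gt = small_stack
        res = count_edu_fraction(stack)
        assert res.n_planes_used == stack.n_planes
        assert res.stack_percent == pytest.approx(30.0, abs=1.0)

    def test_stack_mean_is_mean_of_plane_percentages(self, small_stack):
        res = count_edu_fraction(small_stack[0])
        assert res.stack_percent == pytest.approx(np.mean(res.per_plane_percent))

    def test_empty_edu_channel_gives_zero_percent(self):
        spec = StackSpec(eb_radius_um=60, n_nuclei=20, labeled_fraction=0.0,
                         pixel_size_um=1.0, n_planes=2, seed=1)
        stack, _ = gen_nuclei_stack(spec)
        assert count_edu_fraction(stack).stack_percent == 0.0

    def test_blank_planes_excluded_from_mean(self):
        spec = StackSpec(eb_radius_um=60, n_nuclei=20, labeled_fraction=0.5,
                         pixel_size_um=1.0, n_planes=2, noise_sd=0.0, seed=1)
        stack, _ = gen_nuclei_stack(spec)
        data = np.concatenate([stack.data, np.zeros_like(stack.data[:, :1])], axis=1)
        res = count_edu_fraction(ZStack(data, 1.0))
        assert res.n_planes_used == 2

    def test_entirely_blank_stack_rejected(self):
        with pytest.raises(ValueError):
            count_edu_fraction(ZStack(np.zeros((2, 2, 40, 40)), 1.0))

    def test_estimator_unbiased_on_uniform_stacks(self):
        """|mean estimate - planted %| <= 2 points over 20 seeds."""
        est = []
        for seed in range(20):
            spec = StackSpec(eb_radius_um=80, n_nuclei=60, labeled_fraction=0.4,
                             nucleus_area_range_um2=(40, 120), pixel_size_um=1.0,
                             n_planes=2, seed=seed)
            stack, _ = gen_nuclei_stack(spec)
            est.append(count_edu_fraction(stack).stack_percent)
        assert abs(np.mean(est) - 40.0) <= 2.0


class TestDiametralProfile:
    def test_uniform_disk_gives_flat_profile(self):
        from ebmorph.containers import SectionImage
        img = np.zeros((2, 200, 200), np.float32)
        rr, cc = disk((100, 100), 80)
        img[:, rr, cc] = 0.7
        prof = diametral_profile(SectionImage(img, 1.0))
        inner = slice(5, -5)  # skip the edge-interpolation ramp
        for vals in prof.intensities.values():
            assert np.ptp(vals[inner]) < 0.05

    def test_profile_spans_the_diameter(self, archetype_section):
        prof = diametral_profile(archetype_section)
        total = archetype_section.ground_truth["total_diameter_um"]
        assert prof.positions_um[-1] == pytest.approx(total, abs=2.5)

    def test_marker_section_shape(self, archetype_section):
        """Gata4 peaks at both ends, Oct4 maximum interior, central trough."""
        prof = diametral_profile(archetype_section)
        g = prof.intensities["gata4"]
        o = prof.intensities["oct4"]
        n = len(g)
        edge_w = max(5, n // 12)
        assert g[:edge_w].max() > 0.5 and g[-edge_w:].max() > 0.5
        assert g[n // 3:2 * n // 3].max() < 0.2
        assert o[n // 4:3 * n // 4].max() > 0.5
        centre = slice(n // 2 - 10, n // 2 + 10)
        assert o[centre].mean() < 0.2  # cavity trough

    def test_center_outside_mask_rejected(self, archetype_section):
        with pytest.raises(ValueError):
            diametral_profile(archetype_section, center=(2.0, 2.0))


class TestZAxisProfile:
    def test_constant_stack_constant_profile(self):
        stack = ZStack(np.full((2, 4, 200, 200), 0.5, np.float32), 1.0)
        prof = zaxis_profile(stack)
        assert np.allclose(prof["nuclei"], 0.5)

    def test_background_roi_is_zero(self):
        stack = ZStack(np.zeros((2, 3, 200, 200), np.float32), 1.0)
        assert np.allclose(zaxis_profile(stack)["edu"], 0.0)

    def test_plane_proportional_intensity_gives_linear_profile(self):
        data = np.zeros((2, 5, 150, 150), np.float32)
        for p in range(5):
            data[:, p] = p
        prof = zaxis_profile(ZStack(data, 1.0))
        assert np.allclose(prof["nuclei"], np.arange(5))

    def test_roi_outside_bounds_rejected(self):
        stack = ZStack(np.zeros((2, 2, 80, 80), np.float32), 1.0)
        with pytest.raises(ValueError):
            zaxis_profile(stack, roi_size_um=(100.0, 100.0))


class TestPatternRadii:
    def test_noiseless_radii_recovered_within_1px(self, archetype_section):
        gt = archetype_section.ground_truth
        cav, epi, tot = measure_pattern_radii(archetype_section)
        px = archetype_section.pixel_size_um
        assert cav == pytest.approx(gt["cavity_diameter_um"], abs=2 * px)
        assert epi == pytest.approx(
            gt["total_diameter_um"] - 2 * gt["exen_thickness_um"], abs=2 * px)
        assert tot == pytest.approx(gt["total_diameter_um"], abs=2 * px)

    def test_zero_cavity_flagged_as_zero(self):
        spec = SectionSpec(total_diameter_um=300, cavity_diameter_um=0.0,
                           exen_thickness_um=30, boundary_jitter_px=0, noise_sd=0,
                           seed=0)
        cav, _, _ = measure_pattern_radii(gen_marker_section(spec))
        assert cav == 0.0

    def test_planted_cavity_ratio_0646_measures_27_percent(self):
        spec = SectionSpec(total_diameter_um=600, cavity_diameter_um=0.646 * 600,
                           exen_thickness_um=0.0, boundary_jitter_px=0, noise_sd=0,
                           seed=0)
        cav, _, tot = measure_pattern_radii(gen_marker_section(spec))
        assert (cav / tot) ** 3 == pytest.approx(0.2696, abs=0.01)
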