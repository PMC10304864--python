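"""Plate-image pipeline: calibration, background, thresholds, particles."""

import math

import numpy as np
import pytest

from phage_evo import plaque_imaging as pi, synthetic_data as sd

# the renderer's plaque-lawn contrast after background subtraction is ~150,
# so recovery studies run the printed pipeline with a window matched to the
# synthetic optics (see the methods note)
SYNTH_CONFIG = pi.PipelineConfig(threshold_lower=100.0)


def render_disk_mask(radius_px, pad=4):
    size = 2 * (radius_px + pad) + 1
    yy, xx = np.mgrid[0:size, 0:size]
    c = size // 2
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius_px**2


class TestCalibrateScale:
    def test_hand_arithmetic(self):
        assert pi.calibrate_scale(860) == pytest.approx(0.1)

    def test_unit_case(self):
        assert pi.calibrate_scale(86.0) == pytest.approx(1.0)

    def test_render_scale_recovered(self):
        # a plate rendered at 0.15 mm/px spans 86/0.15 px
        mm_per_px = 0.15
        image, _ = sd.generate_plate_image([2.0], mm_per_px=mm_per_px, seed=0)
        assert pi.calibrate_scale(image.shape[1]) == pytest.approx(mm_per_px, rel=0.01)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            pi.calibrate_scale(0)


class TestSubtractBackground:
    def test_flat_image_maps_to_zero(self):
        image = np.full((80, 80), 120, dtype=np.uint8)
        assert pi.subtract_background(image, 20).max() == 0

    def test_gradient_removed_disk_contrast_kept(self):
        size = 200
        yy, xx = np.mgrid[0:size, 0:size]
        image = 40 + 50 * xx / size  # slow illumination ramp
        mask = np.zeros((size, size), dtype=bool)
        for cx, cy in ((50, 50), (140, 120)):
            mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= 5**2
        image = image + 100 * mask
        out = pi.subtract_background(image.astype(np.uint8), 25)
        lawn = out[~mask]
        disks = out[(xx - 50) ** 2 + (yy - 50) ** 2 <= 3**2]
        assert lawn.mean() < 10
        assert abs(disks.mean() - 100) <= 10

    def test_huge_radius_subtracts_minimum(self):
        image = np.full((60, 60), 90, dtype=np.uint8)
        image[30:34, 30:34] = 200
        out = pi.subtract_background(image, 500)
        expected = image.astype(int) - 90
        assert np.abs(out.astype(int) - expected).max() <= 3

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            pi.subtract_background(np.zeros((10, 10), dtype=np.uint8), 0)


class TestApplyThreshold:
    def test_window_selection(self):
        image = np.full((40, 40), 200, dtype=np.uint8)
        assert pi.apply_threshold(image).all()
        assert not pi.apply_threshold(np.full((40, 40), 255, dtype=np.uint8)).any()

    def test_roi_masking(self):
        image = np.full((40, 40), 200, dtype=np.uint8)
        roi = np.zeros((40, 40), dtype=bool)
        roi[10:30, 10:30] = True
        mask = pi.apply_threshold(image, roi=roi)
        assert mask[20, 20] and not mask[0, 0]

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            pi.apply_threshold(np.zeros((4, 4), dtype=np.uint8), lower=200, upper=100)

    def test_raw_synthetic_plate_selects_only_plaques(self):
        image, truth = sd.generate_plate_image(
            [3.0, 2.0], mm_per_px=0.2, illumination_gradient=0.0, noise_sd=0.0, seed=1
        )
        roi = pi.elliptical_roi_mask(image.shape, 0.2)
        mask = pi.apply_threshold(image, 180, 238, roi)
        # every selected pixel lies inside a rendered disk (anti-aliased edge
        # pixels fall below the window, so interiors dominate the selection)
        yy, xx = np.nonzero(mask)
        x_mm, y_mm = (xx + 0.5) * 0.2, (yy + 0.5) * 0.2
        inside_any = np.zeros(len(xx), dtype=bool)
        for _, row in truth.iterrows():
            dist = np.hypot(x_mm - row.x_mm, y_mm - row.y_mm)
            inside_any |= dist <= row.diameter_mm / 2 + 0.2
        assert inside_any.all()
        true_px = sum(math.pi * (d / 2 / 0.2) ** 2 for d in truth.diameter_mm)
        assert 0.7 * true_px <= mask.sum() <= 1.05 * true_px


class TestAnalyzeParticles:
    def test_disk_geometry(self):
        mask = render_disk_mask(10)  # 1 mm radius at 0.1 mm/px
        [m] = pi.analyze_particles(mask, 0.1)
        assert m.area_mm2 == pytest.approx(math.pi, rel=0.05)
        assert m.equivalent_diameter_mm == pytest.approx(2.0, rel=0.05)
        assert m.circularity > 0.9

    def test_small_disk_filtered_by_area(self):
        # radius 0.2 mm -> area 0.126 mm^2, below the 0.2 mm^2 floor
        mask = render_disk_mask(2)
        assert pi.analyze_particles(mask, 0.1) == []

    def test_thin_bar_filtered_by_circularity(self):
        mask = np.zeros((40, 200), dtype=bool)
        mask[18:20, 5:195] = True
        assert pi.analyze_particles(mask, 0.1) == []

    def test_empty_mask(self):
        assert pi.analyze_particles(np.zeros((20, 20), dtype=bool), 0.1) == []

    def test_component_touching_roi_boundary_discarded(self):
        mask = np.zeros((100, 100), dtype=bool)
        roi = np.zeros((100, 100), dtype=bool)
        roi[10:90, 10:90] = True
        # one disk inside, one straddling the ROI edge
        yy, xx = np.mgrid[0:100, 0:100]
        inside = (xx - 50) ** 2 + (yy - 50) ** 2 <= 10**2
        straddle = (xx - 12) ** 2 + (yy - 50) ** 2 <= 10**2
        mask = (inside | straddle) & roi
        result = pi.analyze_particles(mask, 0.1, roi=roi)
        assert len(result) == 1

    def test_circularity_capped_at_one(self):
        mask = render_disk_mask(3)
        for m in pi.analyze_particles(mask, 0.3, area_range_mm2=(0.01, 64)):
            assert m.circularity <= 1.0


class TestPipelineRecovery:
    def test_scale_invariance_of_mm_measurements(self):
        rng = np.random.default_rng(3)
        diameters = rng.uniform(1.5, 5.0, 30)
        means = []
        for mm_per_px in (0.2, 0.1):
            image, truth = sd.generate_plate_image(
                diameters, mm_per_px=mm_per_px, seed=3
            )
            measured = pi.measure_plate(image, mm_per_px, SYNTH_CONFIG)
            assert len(measured) == len(truth)
            means.append(np.mean([m.equivalent_diameter_mm for m in measured]))
        assert abs(means[1] - means[0]) / means[0] < 0.02

    def test_known_disks_recovered(self):
        rng = np.random.default_rng(4)
        diameters = rng.uniform(0.6, 6.0, 60)
        image, truth = sd.generate_plate_image(diameters, mm_per_px=0.15, seed=4)
        measured = pi.measure_plate(image, 0.15, SYNTH_CONFIG)
        assert len(measured) >= 0.95 * len(truth)
        for m in measured:
            dist = np.hypot(
                truth.x_mm - m.centroid_mm[0], truth.y_mm - m.centroid_mm[1]
            )
            true_d = truth.diameter_mm[dist.idxmin()]
            assert abs(m.equivalent_diameter_mm - true_d) <= 0.05 * true_d + 2 * 0.15


class TestSizeReport:
    @staticmethod
    def _measurements(rng, mean_d, n):
        return [
            pi.PlaqueMeasurement(
                area_mm2=math.pi * (d / 2) ** 2,
                equivalent_diameter_mm=d,
                perimeter_mm=math.pi * d,
                circularity=1.0,
                centroid_mm=(0.0, 0.0),
            )
            for d in rng.normal(mean_d, 0.15 * mean_d, n)
        ]

    def test_separated_samples_significant_after_correction(self):
        rng = np.random.default_rng(5)
        groups = {
            "ancestor": self._measurements(rng, 2.0, 300),
            "evolved": self._measurements(rng, 1.0, 300),
        }
        report = {s.sample: s for s in pi.plaque_size_report(groups, reference="ancestor")}
        assert report["evolved"].significant

    def test_sample_vs_itself_not_significant(self):
        rng = np.random.default_rng(6)
        same = self._measurements(rng, 2.0, 100)
        report = {
            s.sample: s
            for s in pi.plaque_size_report(
                {"ancestor": same, "copy": list(same)}, reference="ancestor"
            )
        }
        assert not report["copy"].significant

    def test_identical_disks_zero_width_ci(self):
        group = self._measurements(np.random.default_rng(7), 2.0, 0)
        group = [
            pi.PlaqueMeasurement(math.pi, 2.0, 2 * math.pi, 1.0, (0.0, 0.0))
            for _ in range(20)
        ]
        [summary] = pi.plaque_size_report({"s": group})
        assert summary.ci_low == summary.ci_high == pytest.approx(2.0)

    def test_empty_group_skipped_with_warning(self):
        group = [pi.PlaqueMeasurement(math.pi, 2.0, 2 * math.pi, 1.0, (0.0, 0.0))] * 3
        with pytest.warns(UserWarning, match="skipped"):
            report = pi.plaque_size_report({"a": group, "b": []})
        assert [s.sample for s in report] == ["a"]


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("threshold_lower: 100\narea_range_mm2: [0.5, 32]\n")
        config = pi.PipelineConfig.from_yaml(path)
        assert config.threshold_lower == 100
        assert config.area_range_mm2 == (0.5, 32)
        assert config.rolling_ball_radius_px == 50.0

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("bogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            pi.PipelineConfig.from_yaml(path)
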