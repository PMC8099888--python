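import numpy as np
import pytest

from oiskit import contour
from oiskit.preprocess import OISMapSequence


def _disk_frame(shape=(80, 80), center=(40, 40), radius=9, amp=1.0, noise=0.0,
                rng=None):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    mask = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
    frame = amp * mask.astype(float)
    if noise:
        frame += noise * (rng or np.random.default_rng(0)).standard_normal(shape)
    return frame, mask


class TestThresholdPixels:
    def test_order_statistics_on_100_pixels(self):
        frame = np.arange(100, dtype=float).reshape(10, 10)
        pts = contour.threshold_pixels(frame, 95.0)
        assert len(pts) == 5  # strictly above the 95th percentile of 0..99

    def test_constant_frame_yields_empty_set(self):
        assert contour.threshold_pixels(np.ones((10, 10)), 95.0).size == 0

    @pytest.mark.parametrize("bad", [-1.0, 100.5])
    def test_percentile_range_validated(self, bad):
        with pytest.raises(ValueError):
            contour.threshold_pixels(np.ones((4, 4)), bad)


class TestKDEDensity:
    def test_tight_cluster_gives_unimodal_density_at_centroid(self, rng):
        pts = np.array([30, 50]) + rng.normal(0, 1.5, size=(300, 2))
        density = contour.kde_density(pts, grid_shape=(80, 80))
        mode = np.unravel_index(np.argmax(density), density.shape)
        assert abs(mode[0] - 30) <= 1 and abs(mode[1] - 50) <= 1

    def test_two_equal_clusters_give_equal_bimodal_peaks(self, rng):
        a = np.array([20, 20]) + rng.normal(0, 1.5, size=(400, 2))
        b = np.array([60, 60]) + rng.normal(0, 1.5, size=(400, 2))
        density = contour.kde_density(np.vstack([a, b]), bandwidth=0.15,
                                      grid_shape=(80, 80))
        peak_a = density[:40, :40].max()
        peak_b = density[40:, 40:].max()
        assert peak_a == pytest.approx(peak_b, rel=0.05)

    def test_density_integrates_to_one_over_grid(self, rng):
        pts = np.array([40, 40]) + rng.normal(0, 3, size=(500, 2))
        density = contour.kde_density(pts, grid_shape=(80, 80))
        assert density.sum() == pytest.approx(1.0, abs=0.01)

    def test_fewer_than_two_points_is_a_detection_failure(self):
        with pytest.raises(contour.DetectionFailure):
            contour.kde_density(np.array([[3, 3]]))


class TestDetectContour:
    def test_solid_disk_recovered_within_15_percent_of_pixel_count(self):
        frame, mask = _disk_frame()
        res = contour.detect_contour(frame, (40, 40), 95.0, 0.5)
        assert res.valid and res.contains_seed
        oracle = mask.sum() * 0.035 ** 2
        assert res.area_mm2 == pytest.approx(oracle, rel=0.15)

    def test_seed_outside_disk_invalidates_detection(self):
        frame, _ = _disk_frame()
        res = contour.detect_contour(frame, (5, 5), 95.0, 0.5)
        assert not res.contains_seed and not res.valid

    def test_salt_noise_without_spot_fails_fullness(self, rng):
        frame = (rng.random((80, 80)) < 0.05).astype(float)
        frame += 0.01 * rng.standard_normal((80, 80))
        res = contour.detect_contour(frame, (40, 40), 95.0, 0.5)
        assert not res.valid

    def test_detected_area_invariant_to_intensity_scaling(self):
        frame, _ = _disk_frame(noise=0.05)
        a1 = contour.detect_contour(frame, (40, 40), 95.0, 0.5).area_mm2
        a2 = contour.detect_contour(frame * 37.0, (40, 40), 95.0, 0.5).area_mm2
        assert a2 == pytest.approx(a1, rel=0.05)

    @pytest.mark.parametrize("percentile", [95.0, 97.0, 98.0])
    def test_area_stable_across_threshold_percentiles(self, percentile):
        frame, mask = _disk_frame(shape=(128, 128), center=(64, 64), radius=9)
        res = contour.detect_contour(frame, (64, 64), percentile, 0.5)
        assert res.valid
        assert res.area_mm2 == pytest.approx(mask.sum() * 0.035 ** 2, rel=0.15)

    def test_density_argmax_inside_footprint_at_snr_3(self, rng):
        frame, mask = _disk_frame(amp=3.0, noise=1.0, rng=rng)
        res = contour.detect_contour(frame, (40, 40), 95.0, 0.5)
        pts = contour.threshold_pixels(frame, 95.0)
        density = contour.kde_density(pts, grid_shape=(80, 80))
        argmax = np.unravel_index(np.argmax(density), density.shape)
        assert mask[argmax]


class TestPolygonArea:
    def test_square_shoelace_area(self):
        square = np.array([[0, 0], [0, 10], [10, 10], [10, 0], [0, 0]], float)
        assert contour.polygon_area_mm2(square, 35.0) == pytest.approx(0.1225)

    def test_disk_of_1118_px_is_about_1p37_mm2(self):
        theta = np.linspace(0, 2 * np.pi, 400)
        r = np.sqrt(1118 / np.pi)
        poly = np.column_stack([40 + r * np.cos(theta), 40 + r * np.sin(theta)])
        assert contour.polygon_area_mm2(poly, 35.0) == pytest.approx(1.37, rel=0.01)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            contour.polygon_area_mm2(np.array([[0, 0], [1, 1]], float), 35.0)

    def test_open_polygon_rejected(self):
        poly = np.array([[0, 0], [0, 5], [5, 5], [5, 0]], float)
        with pytest.raises(ValueError, match="closed"):
            contour.polygon_area_mm2(poly, 35.0)


def _map_sequence(frames):
    frames = np.asarray(frames, dtype=float)
    t = (np.arange(frames.shape[0]) + 0.5) / 6.0
    return OISMapSequence(maps=frames, time_axis_s=t, inverted=True,
                          wavelength_nm=625)


class TestDensityMapAndAreaCourse:
    def test_identical_frames_count_n_inside_zero_outside(self):
        frame, mask = _disk_frame(shape=(60, 60), center=(30, 30), radius=7)
        seq = _map_sequence([frame] * 4)
        dm = contour.contour_density(seq, (30, 30))
        assert dm.counts.max() == 4
        assert dm.counts[0, 0] == 0
        # the high-count region coincides with the footprint
        assert (dm.counts[mask] == 4).mean() > 0.8

    def test_zero_signal_stack_gives_all_zero_map(self, rng):
        seq = _map_sequence(0.001 * rng.standard_normal((3, 60, 60)))
        dm = contour.contour_density(seq, (30, 30))
        assert dm.counts.sum() == 0

    def test_constant_area_course_is_constant(self):
        frame, mask = _disk_frame(shape=(60, 60), center=(30, 30), radius=7)
        seq = _map_sequence([frame] * 14)
        course = contour.area_time_course(seq, (30, 30))
        np.testing.assert_allclose(course.values, course.values[0], rtol=1e-9)
        assert course.values[0] == pytest.approx(mask.sum() * 0.035 ** 2, rel=0.15)

    def test_step_response_smooths_monotonically(self, rng):
        frame, _ = _disk_frame(shape=(60, 60), center=(30, 30), radius=7)
        blank = 1e-4 * rng.standard_normal((60, 60))
        seq = _map_sequence([blank] * 8 + [frame] * 8)
        course = contour.area_time_course(seq, (30, 30))
        diffs = np.diff(course.values)
        assert (diffs >= -1e-12).all()

    def test_short_sequence_left_unsmoothed_with_warning(self):
        frame, _ = _disk_frame(shape=(60, 60), center=(30, 30), radius=7)
        seq = _map_sequence([frame] * 5)
        with pytest.warns(UserWarning, match="unsmoothed"):
            contour.area_time_course(seq, (30, 30))
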