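import numpy as np
import pytest

from oiskit import preprocess, synth, workflows
from oiskit.io import FrameStack, StimulusProtocol, TrialSet
from tests.conftest import QUIET


def _stack(frames, fs=6.0, wl=625):
    t = (np.arange(frames.shape[0]) + 0.5) / fs
    return FrameStack(frames=frames, time_axis_s=t, wavelength_nm=wl)


class TestGaussianSmooth:
    def test_constant_frame_unchanged(self):
        stack = _stack(np.full((3, 16, 16), 7.0))
        out = preprocess.gaussian_smooth(stack, 2.0)
        np.testing.assert_allclose(out.frames, 7.0)

    def test_impulse_center_weight_matches_discrete_kernel(self):
        frames = np.zeros((1, 41, 41))
        frames[0, 20, 20] = 1.0
        out = preprocess.gaussian_smooth(_stack(frames), 2.0)
        # brute-force normalized discrete gaussian (scipy truncates at 4 sigma)
        x = np.arange(-8, 9)
        k = np.exp(-0.5 * x ** 2 / 4.0)
        k /= k.sum()
        assert out.frames[0, 20, 20] == pytest.approx(k[8] ** 2, rel=1e-6)

    def test_frame_mean_preserved(self, rng):
        frames = rng.random((2, 30, 30))
        out = preprocess.gaussian_smooth(_stack(frames), 2.0)
        np.testing.assert_allclose(out.frames.mean(axis=(1, 2)),
                                   frames.mean(axis=(1, 2)), rtol=1e-3)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            preprocess.gaussian_smooth(_stack(np.ones((1, 4, 4))), -1.0)


class TestIlluminationCorrection:
    def test_global_ramp_drift_cancels_exactly(self):
        ramp = 1.0 + 0.01 * np.arange(20)
        frames = np.ones((20, 12, 12)) * ramp[:, None, None] * 100.0
        out = preprocess.correct_illumination(_stack(frames))
        assert out.frames.std(axis=0).max() < 1e-9 * 100.0

    def test_drift_free_stack_unchanged(self):
        frames = np.full((5, 12, 12), 50.0)
        out = preprocess.correct_illumination(_stack(frames))
        np.testing.assert_allclose(out.frames, 50.0)

    def test_empty_reference_region_rejected(self):
        stack = _stack(np.ones((3, 8, 8)))
        with pytest.raises(ValueError, match="empty"):
            preprocess.correct_illumination(stack, np.zeros((8, 8), dtype=bool))

    def test_overlap_with_footprint_warned(self):
        stack = _stack(np.ones((3, 30, 30)))
        footprint = np.zeros((30, 30), dtype=bool)
        footprint[:5, :5] = True
        with pytest.warns(UserWarning, match="overlap"):
            preprocess.correct_illumination(stack, response_footprint=footprint)


class TestTrialAveraging:
    def test_identical_trials_average_to_any_trial(self):
        tr = _stack(np.random.default_rng(0).random((10, 6, 6)))
        ts = TrialSet(trials=[tr, tr, tr], pre_window_s=1.0, post_window_s=1.0)
        np.testing.assert_allclose(preprocess.average_trials(ts).frames, tr.frames,
                                   rtol=1e-15)

    def test_white_noise_shrinks_like_sqrt_n(self, rng):
        n = 16
        trials = [_stack(rng.standard_normal((40, 10, 10)) + 100.0) for _ in range(n)]
        ts = TrialSet(trials=trials, pre_window_s=1.0, post_window_s=1.0)
        avg = preprocess.average_trials(ts)
        residual_sd = avg.frames.std()
        assert residual_sd == pytest.approx(1.0 / 4.0, rel=0.15)


class TestOISMap:
    @staticmethod
    def _avg_stack(darkening=0.0):
        t = np.arange(-12, 24) / 6.0 + 1 / 12.0
        frames = np.full((t.size, 10, 10), 1000.0)
        frames[t > 0] *= (1.0 - darkening)
        return FrameStack(frames=frames, time_axis_s=t, wavelength_nm=625)

    def test_static_stack_gives_zero_maps(self):
        maps = preprocess.ois_map(self._avg_stack())
        np.testing.assert_allclose(maps.maps, 0.0, atol=1e-12)

    def test_darkening_inverted_to_positive_deflection(self):
        maps = preprocess.ois_map(self._avg_stack(darkening=0.002))
        assert maps.inverted
        assert maps.maps[-1, 5, 5] == pytest.approx(0.002, rel=1e-9)

    def test_transmission_channel_not_inverted(self):
        maps = preprocess.ois_map(self._avg_stack(darkening=0.002),
                                  mode="transmission")
        assert not maps.inverted
        assert maps.maps[-1, 5, 5] == pytest.approx(-0.002, rel=1e-9)

    def test_first_frame_and_baseline_window_agree_on_drift_free_input(self):
        maps_a = preprocess.ois_map(self._avg_stack(0.002))
        maps_b = preprocess.ois_map(self._avg_stack(0.002), reference="first-frame")
        np.testing.assert_allclose(maps_a.maps, maps_b.maps, atol=1e-12)

    def test_zero_reference_pixel_flagged_nan(self):
        stack = self._avg_stack()
        stack.frames[:, 0, 0] = 0.0
        maps = preprocess.ois_map(stack)
        assert np.isnan(maps.maps[:, 0, 0]).all()


class TestTimeProfileAndPipeline:
    def test_radius_zero_is_single_pixel_trace(self):
        t = np.arange(-6, 6) / 6.0
        maps = preprocess.OISMapSequence(
            maps=np.arange(12 * 16).reshape(12, 4, 4).astype(float),
            time_axis_s=t, inverted=True, wavelength_nm=625)
        prof = preprocess.time_profile(maps, (2, 3), 0.0)
        np.testing.assert_array_equal(prof.values, maps.maps[:, 2, 3])

    def test_center_outside_grid_rejected(self):
        maps = preprocess.OISMapSequence(maps=np.zeros((3, 4, 4)),
                                         time_axis_s=np.arange(3.0),
                                         inverted=True, wavelength_nm=625)
        with pytest.raises(ValueError, match="outside"):
            preprocess.time_profile(maps, (9, 1), 0.0)

    def test_profile_peak_recovers_configured_amplitude(self, noiseless_session):
        recording, truth = noiseless_session
        maps = workflows.preprocess_channel(recording, 625, pre_s=5.0, post_s=20.0)
        prof = preprocess.time_profile(maps, (32, 32), radius_px=2)
        peak = prof.values.max()
        assert peak == pytest.approx(abs(truth.config.ls_peak_frac), rel=0.02)

    def test_profile_peak_delayed_by_onset_plus_rise(self, noiseless_session):
        recording, truth = noiseless_session
        maps = workflows.preprocess_channel(recording, 625, pre_s=5.0, post_s=20.0)
        prof = preprocess.time_profile(maps, (32, 32), radius_px=2)
        t_peak = prof.time_axis_s[np.argmax(prof.values)]
        assert t_peak == pytest.approx(truth.config.ls_kinetics.peak_time_s(),
                                       abs=0.25)

    def test_preprocessing_is_linear_in_evoked_amplitude(self, small_grid):
        peaks = {}
        for k in (1.0, 3.0):
            scene = synth.SceneConfig(area_mm2=0.08, noise=QUIET,
                                      ls_peak_frac=-0.002 * k,
                                      hbo_peak=4e-8 * k, hbr_peak=-1.6e-8 * k)
            recording, _ = synth.make_session(
                scene, protocol=StimulusProtocol(n_trials=2, inter_train_s=20.0),
                grid=small_grid, lead_in_s=6.0)
            maps = workflows.preprocess_channel(recording, 625, pre_s=5.0, post_s=20.0)
            prof = preprocess.time_profile(maps, (32, 32), radius_px=2)
            peaks[k] = prof.values.max()
        assert peaks[3.0] / peaks[1.0] == pytest.approx(3.0, rel=0.02)

    def test_map_of_zero_truth_render_is_zero_within_noise(self, small_grid):
        scene = synth.SceneConfig(area_mm2=0.08, ls_peak_frac=0.0, hbo_peak=0.0,
                                  hbr_peak=0.0,
                                  noise=synth.NoiseConfig(sd_frac=0.002))
        recording, _ = synth.make_session(
            scene, protocol=StimulusProtocol(n_trials=2, inter_train_s=20.0),
            grid=small_grid, lead_in_s=6.0, seed=3)
        maps = workflows.preprocess_channel(recording, 625, pre_s=5.0, post_s=20.0)
        # smoothed, trial-averaged noise: well below 0.002 / sqrt(2) per pixel
        assert np.abs(np.nanmean(maps.maps)) < 1e-4
        assert np.nanstd(maps.maps) < 0.002
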