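import numpy as np
import pytest

from oiskit import synth
from oiskit.decompose import DEFAULT_EXTINCTION
from oiskit.io import IlluminationSchedule, StimulusProtocol
from tests.conftest import QUIET


class TestWaveformAndScene:
    def test_zero_amplitude_config_gives_zero_truth(self, small_grid):
        cfg = synth.SceneConfig(area_mm2=0.08, ls_peak_frac=0.0, hbo_peak=0.0,
                                hbr_peak=0.0, noise=QUIET)
        truth = synth.make_scene(cfg, grid=small_grid)
        assert not truth.ls_t.any() and not truth.hbo_t.any() and not truth.hbr_t.any()

    def test_truth_zero_before_stimulus_onset(self, small_grid):
        truth = synth.make_scene(synth.SceneConfig(area_mm2=0.08, noise=QUIET),
                                 grid=small_grid,
                                 time_axis_s=np.arange(0, 30, 1 / 6),
                                 stim_onsets_s=(10.0,))
        pre = truth.time_axis_s < 10.0 + truth.config.ls_kinetics.onset_s
        assert not truth.ls_t[pre].any()
        assert truth.ls_t[~pre].any()

    def test_disk_footprint_pixel_count_matches_target_area(self):
        # 1.37 mm^2 at 35 um/px -> 1.37 / 0.035^2 = 1118.4 px
        truth = synth.make_scene(synth.SceneConfig(noise=QUIET))
        assert abs(int(truth.footprint_mask.sum()) - 1118) <= 1

    def test_ls_peaks_at_onset_plus_rise(self):
        t = np.arange(0, 30, 1 / 6)
        kin = synth.Kinetics()
        wave = synth.component_waveform(t, kin)
        t_peak = t[np.argmax(wave)]
        assert abs(t_peak - kin.peak_time_s()) <= 1 / 6

    def test_footprint_larger_than_field_rejected(self):
        with pytest.raises(ValueError, match="field of view"):
            synth.make_scene(synth.SceneConfig(noise=QUIET), grid=(24, 24))


class TestRenderFrames:
    def test_zero_truth_zero_noise_renders_baseline_times_drift(self, small_grid):
        cfg = synth.SceneConfig(area_mm2=0.08, ls_peak_frac=0.0, hbo_peak=0.0,
                                hbr_peak=0.0,
                                noise=synth.NoiseConfig(sd_frac=0.0))
        t = (np.arange(90) + 0.5) / 18.0
        truth = synth.make_scene(cfg, grid=small_grid, time_axis_s=t)
        rec = synth.render_frames(truth, protocol=StimulusProtocol(n_trials=12))
        drift = synth._drift(t, cfg.noise)
        for k, stack in enumerate(rec.stacks):
            i0 = cfg.baseline_intensity[stack.wavelength_nm]
            expected = i0 * drift[k::3]
            np.testing.assert_allclose(stack.frames.mean(axis=(1, 2)), expected,
                                       rtol=1e-6)

    def test_single_voxel_intensity_matches_hand_computed_attenuation(self, small_grid):
        cfg = synth.SceneConfig(area_mm2=0.08, noise=QUIET)
        t = (np.arange(18 * 20) + 0.5) / 18.0
        truth = synth.make_scene(cfg, grid=small_grid, time_axis_s=t,
                                 stim_onsets_s=(2.0,))
        rec = synth.render_frames(truth, protocol=StimulusProtocol(n_trials=12))
        red = rec.stack("Red")
        i = np.argmin(np.abs(red.time_axis_s - (2.0 + 3.2)))  # LS peak frame
        r, c = small_grid[0] // 2, small_grid[1] // 2
        ehbo, ehbr = DEFAULT_EXTINCTION.eps(625)
        ti = red.time_axis_s[i]
        idx = np.argmin(np.abs(truth.time_axis_s - ti))
        od = (ehbo * truth.hbo_t[idx] + ehbr * truth.hbr_t[idx]
              - np.log10(1 + truth.ls_t[idx]))
        expected = cfg.baseline_intensity[625.0] * 10.0 ** (-od)
        assert red.frames[i, r, c] == pytest.approx(expected, rel=1e-6)

    def test_noise_sd_matches_configuration(self, small_grid):
        cfg = synth.SceneConfig(area_mm2=0.08, ls_peak_frac=0.0, hbo_peak=0.0,
                                hbr_peak=0.0,
                                noise=synth.NoiseConfig(sd_frac=0.001,
                                                        drift_amp_frac=0.0))
        t = (np.arange(18 * 60) + 0.5) / 18.0
        truth = synth.make_scene(cfg, grid=small_grid, time_axis_s=t)
        rec = synth.render_frames(truth, seed=7, protocol=StimulusProtocol(n_trials=12))
        green = rec.stack("Green")
        sd = green.frames.std(axis=0).mean()
        assert sd == pytest.approx(0.001 * cfg.baseline_intensity[528.0], rel=0.1)


class TestDoseSeries:
    @staticmethod
    def _series(seed=0, concentrations=(0.0, 1.4)):
        scene = synth.SceneConfig(area_mm2=0.08, noise=QUIET)
        dose = synth.DoseConfig(concentrations=concentrations, tau_ls=1.4)
        protocol = StimulusProtocol(n_trials=1, inter_train_s=12.0)
        schedule = IlluminationSchedule(wavelengths_nm=(625,), modes=("reflection",))
        return synth.generate_dose_series(scene, dose, protocol=protocol,
                                          schedule=schedule, grid=(48, 48),
                                          seed=seed)

    def test_control_scale_is_one_and_tau_scale_is_one_over_e(self):
        series = self._series()
        (_, _, truth0), (_, _, truth1) = series
        # the waveform peak sampled at 6 Hz sits within 0.5% of the configured peak
        assert truth0.ls_t.min() == pytest.approx(-0.002, rel=0.005)
        assert truth1.ls_t.min() / truth0.ls_t.min() == pytest.approx(np.exp(-1.0),
                                                                      rel=1e-9)

    def test_hemodynamic_peaks_scale_with_the_same_factor(self):
        (_, _, truth0), (_, _, truth1) = self._series()
        assert truth1.hbo_t.max() / truth0.hbo_t.max() == pytest.approx(np.exp(-1),
                                                                        rel=1e-9)
        assert truth1.hbr_t.min() / truth0.hbr_t.min() == pytest.approx(np.exp(-1),
                                                                        rel=1e-9)

    def test_baseline_and_footprint_independent_of_concentration(self):
        (_, rec0, truth0), (_, rec1, truth1) = self._series()
        np.testing.assert_array_equal(truth0.footprint, truth1.footprint)
        pre0 = rec0.stacks[0].frames[:20].mean()
        pre1 = rec1.stacks[0].frames[:20].mean()
        assert pre0 == pytest.approx(pre1, rel=1e-5)

    def test_two_seeds_share_truth_but_not_noise(self):
        scene = synth.SceneConfig(area_mm2=0.08,
                                  noise=synth.NoiseConfig(sd_frac=0.005,
                                                          drift_amp_frac=0.0))
        dose = synth.DoseConfig(concentrations=(0.0,), tau_ls=1.4)
        protocol = StimulusProtocol(n_trials=1, inter_train_s=12.0)
        kw = dict(protocol=protocol, grid=(48, 48),
                  schedule=IlluminationSchedule(wavelengths_nm=(625,),
                                                modes=("reflection",)))
        (_, rec_a, truth_a), = synth.generate_dose_series(scene, dose, seed=1, **kw)
        (_, rec_b, truth_b), = synth.generate_dose_series(scene, dose, seed=2, **kw)
        np.testing.assert_array_equal(truth_a.ls_t, truth_b.ls_t)
        assert not np.array_equal(rec_a.stacks[0].frames, rec_b.stacks[0].frames)

    def test_same_seed_is_deterministic(self):
        a = self._series(seed=3)
        b = self._series(seed=3)
        np.testing.assert_array_equal(a[0][1].stacks[0].frames,
                                      b[0][1].stacks[0].frames)
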