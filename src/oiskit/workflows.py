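"""End-to-end analysis workflows over synthetic recordings.

Each function runs the library pipeline from generated raw data to a reported
quantity: per-wavelength dose-response fits, scattering/hemodynamic coupling,
contour-area recovery, and concentration-constant recovery on amplitude
cohorts. These are the entry points the drivers in ``analysis/``, the CLI and
the validation suite call.

Problem sizes default to desk scale: full 174 x 130 grids but reduced trial
counts and shortened inter-train intervals, which leave per-trial kinetics and
the dose model untouched because the pipeline is linear and every amplitude is
normalized to its own control.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Sequence

import numpy as np

from . import contour as contour_mod
from . import decompose, dose, metrics, preprocess, synth
from .io import IlluminationSchedule, StimulusProtocol, split_trials

__all__ = [
    "preprocess_channel",
    "channel_amplitude",
    "tau_recovery",
    "pipeline_dose_r2",
    "coupling_pearson",
    "contour_area_recovery",
    "retention_percent",
    "baseline_concentration_spearman",
]


def preprocess_channel(recording, wavelength_nm, pre_s: float = 5.0,
                       post_s: float = 30.0, sigma_px: float = 2.0,
                       invert_reflection: bool = True):
    """Standard chain for one channel: smooth, correct, split, average, map."""
    stack = recording.stack(wavelength_nm)
    stack = preprocess.gaussian_smooth(stack, sigma_px)
    stack = preprocess.correct_illumination(stack)
    trials = split_trials(stack, recording.protocol, recording.stim_onsets_s,
                          pre_window_s=pre_s, post_window_s=post_s)
    avg = preprocess.average_trials(trials)
    mode = recording.schedule.mode_of(wavelength_nm)
    return preprocess.ois_map(avg, invert_reflection=invert_reflection, mode=mode)


def channel_amplitude(map_sequence, center_px, radius_px: float = 10.0,
                      response_window_s=(0.0, 28.0),
                      smoothing_points: int = 50) -> float:
    """Signed OIS amplitude at the response center (Kaiser-smoothed peak)."""
    profile = preprocess.time_profile(map_sequence, center_px, radius_px)
    return metrics.amplitude(profile.values, profile.time_axis_s,
                             response_window_s=response_window_s,
                             smoothing_points=smoothing_points)


def tau_recovery(tau: float, concentrations: Sequence[float], n_series: int = 14,
                 noise_sigma: float = 0.05, seed=None, anesthetic: str = "urethane",
                 unit: str = "g/kg") -> dict:
    """Fit exponential dose curves to a synthetic amplitude cohort.

    Amplitudes follow A(c) = exp(-c/tau) with multiplicative lognormal noise;
    each series is normalized to its own control and fitted separately; the
    group constant is the mean of the per-series fits.
    """
    amps = synth.simulate_amplitude_series(tau, concentrations, n_series,
                                           noise_sigma=noise_sigma, seed=seed)
    fits = []
    for i in range(n_series):
        series = dose.normalize_to_control(concentrations, amps[i],
                                           anesthetic=anesthetic, unit=unit,
                                           animal_id=f"sim{i:02d}")
        fits.append(dose.fit_exponential(series))
    taus = np.array([f.tau for f in fits])
    mean_tau, ci = dose.jackknife_ci(taus)
    return {"mean_tau": float(mean_tau), "ci_tau": float(ci),
            "taus": taus, "mean_r2": float(np.mean([f.r2 for f in fits])),
            "n": n_series}


_T3_CONCENTRATIONS = (0.0, 0.3, 0.6, 0.9, 1.2, 1.5)


def pipeline_dose_r2(seed=None, concentrations: Sequence[float] = _T3_CONCENTRATIONS,
                     tau: float = 1.4, anesthetic: str = "urethane",
                     n_trials: int = 6, inter_train_s: float = 30.0,
                     pre_s: float = 5.0, post_s: float = 30.0,
                     grid: tuple = synth.DEFAULT_GRID) -> dict:
    """Full pipeline dose-response quality per wavelength channel.

    Renders one synthetic animal at each concentration, runs preprocessing,
    extracts the Kaiser-smoothed peak amplitude per channel, normalizes to
    control and fits the exponential model. Returns per-channel fitted tau and
    r^2 plus their mean.
    """
    scene = synth.SceneConfig()
    dose_cfg = synth.DoseConfig(anesthetic=anesthetic,
                                concentrations=tuple(concentrations), tau_ls=tau)
    protocol = StimulusProtocol(n_trials=n_trials, inter_train_s=inter_train_s)
    schedule = IlluminationSchedule()
    center = (grid[0] // 2, grid[1] // 2)
    amps = {label: [] for label in schedule.labels}
    for c, recording, truth in synth.iter_dose_series(
            scene, dose_cfg, protocol=protocol, schedule=schedule, grid=grid,
            lead_in_s=pre_s + 1.0, seed=seed):
        for wl, label in zip(schedule.wavelengths_nm, schedule.labels):
            maps = preprocess_channel(recording, wl, pre_s=pre_s, post_s=post_s)
            amps[label].append(channel_amplitude(
                maps, center, response_window_s=(0.0, post_s - 2.0)))
    out = {"channels": {}, "concentrations": list(concentrations)}
    r2s, taus = [], []
    for label in schedule.labels:
        series = dose.normalize_to_control(concentrations, amps[label],
                                           anesthetic=anesthetic,
                                           unit=dose_cfg.unit, component=label)
        fit = dose.fit_exponential(series)
        out["channels"][label] = {"tau": fit.tau, "r2": fit.r2,
                                  "amplitudes": list(map(float, amps[label]))}
        r2s.append(fit.r2)
        taus.append(fit.tau)
    out["mean_r2"] = float(np.mean(r2s))
    out["mean_tau"] = float(np.mean(taus))
    return out


def coupling_pearson(seed=None, n_animals: int = 14, n_concentrations: int = 10,
                     tau: float = 1.4, c_max: float = 2.0,
                     amplitude_cv: float = 0.01, rate_hz: float = 6.0,
                     pre_s: float = 5.0, post_s: float = 30.0) -> dict:
    """Signed HbO-vs-LS amplitude correlation across a coupled dose series.

    The positive HbO amplitude is a fixed linear gain times the magnitude of
    the negative LS amplitude. Per (animal, concentration) the component
    amplitudes carry multiplicative lognormal scatter (trial-to-trial
    variability); three-wavelength traces are rendered forward, unmixed by the
    modified Beer-Lambert solve, and the signed (LS, HbO) amplitude pairs are
    pooled into one Pearson correlation.
    """
    rng = np.random.default_rng(seed)
    scene = synth.SceneConfig()
    concentrations = np.linspace(0.0, c_max, n_concentrations)
    t = np.arange(-pre_s, post_s, 1.0 / rate_hz) + 0.5 / rate_hz
    ls_wave = synth.component_waveform(t, scene.ls_kinetics)
    hb_wave = synth.component_waveform(t - scene.hemo_delay_s, scene.hb_kinetics)
    ls_amps, hbo_amps = [], []
    for _ in range(n_animals):
        for c in concentrations:
            s = math.exp(-c / tau) * rng.lognormal(0.0, amplitude_cv)
            ls_frac = scene.ls_peak_frac * s * ls_wave
            hbo = scene.coupling_hbo_per_ls * (scene.ls_peak_frac * s) * hb_wave
            hbr = scene.hbr_peak * s * hb_wave
            traces_i = synth.render_intensity_traces(hbo, hbr, ls_frac,
                                                     noise_cv=0.0)
            od = {wl: decompose.delta_od(i, t) for wl, i in traces_i.items()}
            unmixed = decompose.unmix(od, time_axis_s=t)
            a_hbo, _, a_ls = decompose.component_amplitudes(
                unmixed, response_window_s=(0.0, post_s - 2.0),
                smoothing_points=50)
            ls_amps.append(a_ls)
            hbo_amps.append(a_hbo)
    stat = dose.pearson(ls_amps, hbo_amps)
    return {"pearson_r": stat.value, "p_value": stat.p_value, "n": stat.n,
            "ls_amplitudes": np.array(ls_amps), "hbo_amplitudes": np.array(hbo_amps)}


def contour_area_recovery(seed=None, area_mm2: float = 1.37, n_trials: int = 12,
                          snr: float = 5.0, grid: tuple = synth.DEFAULT_GRID,
                          percentile: float = 95.0, fullness_min: float = 0.5,
                          pre_s: float = 5.0, post_s: float = 25.0,
                          inter_train_s: float = 30.0) -> dict:
    """Detect a known circular footprint with the KDE contour detector.

    Renders a single-wavelength (red, 625 nm) control recording whose
    per-frame noise is set so the trial-averaged OIS map (before the spatial
    filter, which belongs to the detection method) has the requested
    amplitude/noise SNR, then detects the contour on the frame nearest the
    scattering peak.
    """
    amp = 0.002  # |fractional LS amplitude| of the default scene
    sd_frac = amp / snr * math.sqrt(n_trials)
    scene = replace(synth.SceneConfig(), area_mm2=area_mm2,
                    noise=synth.NoiseConfig(sd_frac=sd_frac))
    schedule = IlluminationSchedule(wavelengths_nm=(625,), modes=("reflection",))
    protocol = StimulusProtocol(n_trials=n_trials, inter_train_s=inter_train_s)
    recording, truth = synth.make_session(scene, schedule=schedule,
                                          protocol=protocol, grid=grid,
                                          lead_in_s=pre_s + 1.0, seed=seed)
    maps = preprocess_channel(recording, 625, pre_s=pre_s, post_s=post_s)
    i_peak = int(np.argmin(np.abs(maps.time_axis_s - scene.ls_kinetics.peak_time_s())))
    center = (grid[0] // 2, grid[1] // 2)
    result = contour_mod.detect_contour(maps.maps[i_peak], center,
                                        percentile=percentile,
                                        fullness_min=fullness_min,
                                        px_size_um=truth.px_size_um,
                                        frame_index=i_peak)
    return {"area_mm2": result.area_mm2, "true_area_mm2": truth.footprint_area_mm2,
            "valid": result.valid, "fullness": result.fullness,
            "contains_seed": result.contains_seed, "result": result}


def retention_percent(tau: float = 1.4, concentration: float = 1.5) -> float:
    """Percent of the control response retained at a concentration."""
    return 100.0 * dose.retention_at(tau, concentration)


def baseline_concentration_spearman(seed=None, n_concentrations: int = 500,
                                    c_max: float = 1.5, tau: float = 1.4,
                                    grid: tuple = (24, 24),
                                    area_mm2: float = 0.08) -> dict:
    """Spearman rank correlation of baseline light intensity vs concentration.

    Generates a dose series (small grid, one short trial per concentration)
    and correlates each recording's mean pre-stimulus intensity with the
    concentration. The generator keeps the illumination baseline
    concentration independent, so only sensor noise ranks the means and the
    correlation hovers near zero. Many concentrations keep the null rank
    correlation tight (SD ~ 1/sqrt(n - 1)).
    """
    scene = replace(synth.SceneConfig(), area_mm2=area_mm2)
    concentrations = tuple(np.linspace(0.0, c_max, n_concentrations))
    dose_cfg = synth.DoseConfig(concentrations=concentrations, tau_ls=tau)
    schedule = IlluminationSchedule(wavelengths_nm=(625,), modes=("reflection",))
    protocol = StimulusProtocol(n_trials=1, inter_train_s=12.0)
    baselines = []
    for c, recording, _ in synth.iter_dose_series(
            scene, dose_cfg, protocol=protocol, schedule=schedule, grid=grid,
            lead_in_s=5.0, seed=seed):
        stack = recording.stack(625)
        pre = stack.frames[stack.time_axis_s < recording.stim_onsets_s[0]]
        baselines.append(float(pre.mean()))
    stat = dose.spearman(concentrations, baselines)
    return {"spearman_rho": stat.value, "p_value": stat.p_value,
            "n": n_concentrations}
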