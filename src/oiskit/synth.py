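"""Forward model: synthetic multispectral recordings with known ground truth.

The scene is an evoked response in a small cortical footprint. Each component
(tissue light scattering LS; oxy-/deoxyhemoglobin HbO/HbR) follows a piecewise
waveform: zero until onset, a half-cosine ramp over the rise time, then a
single-exponential decay. The hemodynamic components lag the scattering
component by a fixed neurovascular delay. Amplitudes across an anesthetic dose
series scale as exp(-c/tau); the baseline illumination is concentration
independent.

Sign conventions: the evoked LS is a *darkening* (negative fractional
reflectance change), dHbO is positive and dHbR negative. Intensity is rendered
through the modified Beer-Lambert budget

    I(lambda,t,x,y) = I0(lambda) * 10**(-[eps_HbO dHbO + eps_HbR dHbR + dA])
                      * drift(t) * (1 + gaussian noise)

where dA = -log10(1 + dS) is the attenuation equivalent of the (negative)
fractional scattering change dS, so the rendered spot is dark, as observed.

Noise is white gaussian per pixel and frame (default SD 0.5% of baseline, a
shot-noise-limited wide-field camera) plus a slow multiplicative drift (linear
trend + 30-s sinusoid, default 0.2% amplitude) common to all pixels, which the
reference-region correction removes. All randomness flows through one seeded
generator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .decompose import DEFAULT_EXTINCTION, ExtinctionTable
from .io import (FrameStack, IlluminationSchedule, MultispectralRecording,
                 StimulusProtocol)

__all__ = [
    "Kinetics",
    "NoiseConfig",
    "SceneConfig",
    "DoseConfig",
    "SceneTruth",
    "component_waveform",
    "make_scene",
    "render_frames",
    "make_session",
    "iter_dose_series",
    "generate_dose_series",
    "simulate_amplitude_series",
    "render_intensity_traces",
]

DEFAULT_GRID = (174, 130)  # H x W, 35 um/px acquisition geometry
DEFAULT_BASELINE = {528.0: 10000.0, 625.0: 12000.0, 850.0: 8000.0}


@dataclass(frozen=True)
class Kinetics:
    """Waveform timing; defaults bracket reported neonatal OIS medians."""

    onset_s: float = 0.8
    rise_s: float = 2.4
    decay_s: float = 10.8

    def __post_init__(self) -> None:
        if self.rise_s <= 0 or self.decay_s <= 0:
            raise ValueError("rise_s and decay_s must be > 0")

    def rise_10_90_s(self) -> float:
        """Closed-form 10-90% rise time of the half-cosine ramp."""
        return (math.acos(-0.8) - math.acos(0.8)) / math.pi * self.rise_s

    def peak_time_s(self) -> float:
        return self.onset_s + self.rise_s


@dataclass(frozen=True)
class NoiseConfig:
    sd_frac: float = 0.005
    drift_amp_frac: float = 0.002
    drift_period_s: float = 30.0


@dataclass(frozen=True)
class SceneConfig:
    center_px: tuple = None          # None -> grid center
    footprint_shape: str = "disk"    # disk | gaussian
    area_mm2: float = 1.37
    ls_kinetics: Kinetics = Kinetics()
    ls_peak_frac: float = -0.002     # fractional reflectance change (dark spot)
    hb_kinetics: Kinetics = Kinetics()
    hbo_peak: float = 4.0e-8         # relative units (pathlength-uncalibrated)
    hbr_peak: float = -1.6e-8
    hemo_delay_s: float = 3.0
    coupling_hbo_per_ls: float = -2.0e-5  # dHbO per unit fractional LS (negative gain)
    baseline_intensity: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE))
    noise: NoiseConfig = NoiseConfig()
    px_size_um: float = 35.0

    def __post_init__(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError("area_mm2 must be > 0")
        if any(v <= 0 for v in self.baseline_intensity.values()):
            raise ValueError("baseline intensities must be > 0")

    def scaled(self, factor: float) -> "SceneConfig":
        """All evoked component amplitudes scaled by `factor` (dose scaling)."""
        return replace(self, ls_peak_frac=self.ls_peak_frac * factor,
                       hbo_peak=self.hbo_peak * factor,
                       hbr_peak=self.hbr_peak * factor)


@dataclass(frozen=True)
class DoseConfig:
    anesthetic: str = "urethane"     # urethane | isoflurane
    concentrations: tuple = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5)
    tau_ls: float = 1.4              # concentration constant (g/kg or %)
    tau_independent_area: bool = True

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if (c < 0).any() or 0.0 not in self.concentrations:
            raise ValueError("concentrations must be non-negative and include 0 (control)")
        if self.tau_ls <= 0:
            raise ValueError("tau_ls must be > 0")

    @property
    def unit(self) -> str:
        return "g/kg" if self.anesthetic == "urethane" else "%"

    def scale(self, concentration: float) -> float:
        return math.exp(-concentration / self.tau_ls)


@dataclass
class SceneTruth:
    """Ground truth: component time courses x spatial footprint (separable)."""

    time_axis_s: np.ndarray
    ls_t: np.ndarray                 # fractional reflectance change (<= 0)
    hbo_t: np.ndarray
    hbr_t: np.ndarray
    footprint: np.ndarray            # H x W weights in [0, 1]
    px_size_um: float
    config: SceneConfig
    stim_onsets_s: tuple

    @property
    def footprint_mask(self) -> np.ndarray:
        """Pixels at or above half of the footprint maximum."""
        return self.footprint >= 0.5 * self.footprint.max()

    @property
    def footprint_area_mm2(self) -> float:
        return float(self.footprint_mask.sum()) * (self.px_size_um / 1000.0) ** 2

    @property
    def delta_s_t(self) -> np.ndarray:
        """Scattering component in OD-budget units at the footprint peak."""
        return np.log10(1.0 + self.ls_t)

    def delta_s_field(self) -> np.ndarray:
        return np.log10(1.0 + self.ls_t[:, None, None] * self.footprint[None])

    def hbo_field(self) -> np.ndarray:
        return self.hbo_t[:, None, None] * self.footprint[None]

    def hbr_field(self) -> np.ndarray:
        return self.hbr_t[:, None, None] * self.footprint[None]

    def true_metrics(self) -> dict:
        cfg = self.config
        return {
            "ls_peak_frac": cfg.ls_peak_frac,
            "ls_onset_s": cfg.ls_kinetics.onset_s,
            "ls_rise_10_90_s": cfg.ls_kinetics.rise_10_90_s(),
            "ls_decay_s": cfg.ls_kinetics.decay_s,
            "ls_peak_time_s": cfg.ls_kinetics.peak_time_s(),
            "area_mm2": self.footprint_area_mm2,
        }


def component_waveform(t: np.ndarray, kinetics: Kinetics) -> np.ndarray:
    """Unit-peak waveform: 0 | half-cosine rise | exponential decay."""
    t = np.asarray(t, dtype=float)
    dt = t - kinetics.onset_s
    out = np.zeros_like(t)
    rising = (dt >= 0) & (dt < kinetics.rise_s)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * dt[rising] / kinetics.rise_s))
    falling = dt >= kinetics.rise_s
    out[falling] = np.exp(-(dt[falling] - kinetics.rise_s) / kinetics.decay_s)
    return out


def _footprint(config: SceneConfig, grid: tuple) -> np.ndarray:
    h, w = grid
    px_area_mm2 = (config.px_size_um / 1000.0) ** 2
    n_px = int(round(config.area_mm2 / px_area_mm2))
    center = config.center_px or (h // 2, w // 2)
    rr, cc = np.ogrid[:h, :w]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    radius = math.sqrt(n_px / math.pi)
    if radius > min(center[0], center[1], h - 1 - center[0], w - 1 - center[1]):
        raise ValueError(f"footprint of {config.area_mm2} mm^2 does not fit the "
                         f"{h}x{w} field of view at {config.px_size_um} um/px")
    if config.footprint_shape == "disk":
        # rank-based disk: exactly n_px nearest pixels
        flat = np.argsort(d2, axis=None, kind="stable")[:n_px]
        fp = np.zeros((h, w))
        fp.flat[flat] = 1.0
    elif config.footprint_shape == "gaussian":
        # truncated gaussian whose half-maximum region has the target area
        sigma = radius / math.sqrt(2.0 * math.log(2.0))
        fp = np.exp(-0.5 * d2 / sigma ** 2)
        fp[fp < 0.05] = 0.0
    else:
        raise ValueError(f"unknown footprint shape {config.footprint_shape!r}")
    return fp


def make_scene(config: SceneConfig, grid: tuple = DEFAULT_GRID,
               time_axis_s: np.ndarray = None,
               stim_onsets_s: Sequence[float] = (0.0,)) -> SceneTruth:
    """Evaluate the ground-truth component courses on a time axis.

    Responses from successive stimulus trains superpose linearly; with the
    default 90-s inter-train interval the overlap is negligible.
    """
    if time_axis_s is None:
        time_axis_s = np.arange(0.0, 60.0, 1.0 / 18.0)
    t = np.asarray(time_axis_s, dtype=float)
    ls = np.zeros_like(t)
    hb = np.zeros_like(t)
    for onset in stim_onsets_s:
        ls += component_waveform(t - onset, config.ls_kinetics)
        hb += component_waveform(t - onset - config.hemo_delay_s, config.hb_kinetics)
    return SceneTruth(
        time_axis_s=t,
        ls_t=config.ls_peak_frac * ls,
        hbo_t=config.hbo_peak * hb,
        hbr_t=config.hbr_peak * hb,
        footprint=_footprint(config, grid),
        px_size_um=config.px_size_um,
        config=config,
        stim_onsets_s=tuple(stim_onsets_s),
    )


def _drift(t: np.ndarray, noise: NoiseConfig) -> np.ndarray:
    if noise.drift_amp_frac == 0:
        return np.ones_like(t)
    span = max(t[-1] - t[0], 1e-9)
    lin = (t - t[0]) / span - 0.5
    sine = 0.5 * np.sin(2.0 * np.pi * t / noise.drift_period_s)
    return 1.0 + noise.drift_amp_frac * (lin + sine)


def render_frames(truth: SceneTruth, schedule: IlluminationSchedule = None,
                  extinction: ExtinctionTable = DEFAULT_EXTINCTION,
                  noise: NoiseConfig = None, seed=None,
                  protocol: StimulusProtocol = None,
                  pathlength_factors: dict = None) -> MultispectralRecording:
    """Render the truth into an interleaved multispectral recording.

    truth.time_axis_s is the global interleaved clock; channel k samples
    frames k, k+n, ... Negative rendered intensities are clipped at zero with
    a warning.
    """
    schedule = schedule or IlluminationSchedule()
    noise = noise if noise is not None else truth.config.noise
    protocol = protocol or StimulusProtocol()
    if not extinction.covers(schedule.wavelengths_nm):
        raise KeyError(f"extinction table does not cover {schedule.wavelengths_nm}")
    rng = np.random.default_rng(seed)
    n_ch = schedule.n_channels
    t_global = truth.time_axis_s
    if len(t_global) % n_ch:
        raise ValueError("global time axis length must be divisible by the channel count")
    L = {float(w): 1.0 for w in schedule.wavelengths_nm}
    if pathlength_factors:
        L.update({float(k): float(v) for k, v in pathlength_factors.items()})
    fp = truth.footprint
    drift_all = _drift(t_global, noise)
    clipped = 0
    stacks = []
    for k, wl in enumerate(schedule.wavelengths_nm):
        idx = np.arange(k, len(t_global), n_ch)
        ehbo, ehbr = extinction.eps(wl)
        hemo_od = (ehbo * truth.hbo_t[idx] + ehbr * truth.hbr_t[idx]) * L[float(wl)]
        od = hemo_od[:, None, None] * fp[None]
        od -= np.log10(1.0 + truth.ls_t[idx][:, None, None] * fp[None])
        i0 = truth.config.baseline_intensity[float(wl)]
        frames = i0 * 10.0 ** (-od) * drift_all[idx][:, None, None]
        if noise.sd_frac > 0:
            frames = frames * (1.0 + noise.sd_frac * rng.standard_normal(frames.shape))
        neg = frames < 0
        if neg.any():
            clipped += int(neg.sum())
            frames[neg] = 0.0
        stacks.append(FrameStack(frames=frames.astype(np.float32),
                                 time_axis_s=t_global[idx], wavelength_nm=float(wl),
                                 px_size_um=truth.px_size_um))
    if clipped:
        warnings.warn(f"{clipped} rendered intensities clipped at 0", stacklevel=2)
    return MultispectralRecording(
        stacks=stacks, schedule=schedule, protocol=protocol,
        stim_onsets_s=list(truth.stim_onsets_s), px_size_um=truth.px_size_um,
        metadata={"synthetic": True})


def make_session(scene_config: SceneConfig, schedule: IlluminationSchedule = None,
                 protocol: StimulusProtocol = None, grid: tuple = DEFAULT_GRID,
                 lead_in_s: float = 6.0, seed=None,
                 extinction: ExtinctionTable = DEFAULT_EXTINCTION) -> tuple:
    """Build a full stimulation session: (recording, truth).

    Trains start at lead_in_s and repeat every train + inter-train interval,
    protocol.n_trials times.
    """
    schedule = schedule or IlluminationSchedule()
    protocol = protocol or StimulusProtocol()
    period = protocol.train_duration_s + protocol.inter_train_s
    onsets = lead_in_s + period * np.arange(protocol.n_trials)
    duration = lead_in_s + period * protocol.n_trials
    n_per_channel = int(round(duration * schedule.per_channel_rate_hz))
    n_total = n_per_channel * schedule.n_channels
    dt = 1.0 / schedule.interleaved_rate_hz
    t_global = (np.arange(n_total) + 0.5) * dt
    truth = make_scene(scene_config, grid=grid, time_axis_s=t_global,
                       stim_onsets_s=onsets.tolist())
    recording = render_frames(truth, schedule=schedule, extinction=extinction,
                              noise=scene_config.noise, seed=seed, protocol=protocol)
    return recording, truth


def iter_dose_series(scene_config: SceneConfig, dose_config: DoseConfig,
                     protocol: StimulusProtocol = None,
                     schedule: IlluminationSchedule = None,
                     grid: tuple = DEFAULT_GRID, lead_in_s: float = 6.0,
                     seed=None,
                     extinction: ExtinctionTable = DEFAULT_EXTINCTION) -> Iterator[tuple]:
    """Yield (concentration, recording, truth) per dose, lazily.

    The LS peak at concentration c is the control peak times exp(-c/tau_ls);
    the hemodynamic peaks scale by the same factor (linear coupling). Baseline
    intensity and (when tau_independent_area) the footprint are concentration
    independent. The truth is deterministic; only the sensor noise consumes
    the seed, so two seeds share truths but differ in noise.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(dose_config.concentrations))
    for c, child in zip(dose_config.concentrations, children):
        cfg = scene_config.scaled(dose_config.scale(c))
        recording, truth = make_session(cfg, schedule=schedule, protocol=protocol,
                                        grid=grid, lead_in_s=lead_in_s,
                                        seed=child, extinction=extinction)
        recording.metadata.update({"anesthetic": dose_config.anesthetic,
                                   "concentration": c, "unit": dose_config.unit})
        yield c, recording, truth


def generate_dose_series(scene_config: SceneConfig, dose_config: DoseConfig,
                         protocol: StimulusProtocol = None, seed=None,
                         **kwargs) -> list:
    return list(iter_dose_series(scene_config, dose_config, protocol=protocol,
                                 seed=seed, **kwargs))


def simulate_amplitude_series(tau: float, concentrations: Sequence[float],
                              n_series: int, noise_sigma: float = 0.05,
                              seed=None) -> np.ndarray:
    """Amplitude cohorts A(c) = exp(-c/tau) with multiplicative lognormal noise.

    Returns an (n_series, n_concentrations) array of positive amplitudes
    (control included, un-normalized scale 1).
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(concentrations, dtype=float)
    clean = np.exp(-c / tau)
    noise = rng.lognormal(mean=0.0, sigma=noise_sigma, size=(n_series, c.size))
    return clean[None, :] * noise


def render_intensity_traces(hbo_t: np.ndarray, hbr_t: np.ndarray,
                            ls_frac_t: np.ndarray,
                            extinction: ExtinctionTable = DEFAULT_EXTINCTION,
                            wavelengths_nm: Sequence[float] = (528.0, 625.0, 850.0),
                            baseline_intensity: dict = None,
                            noise_cv: float = 0.0, seed=None) -> dict:
    """ROI-level forward render: {wavelength: intensity trace}.

    The trace-level analogue of :func:`render_frames` at the footprint peak,
    used for unmixing round trips and coupling analyses.
    """
    baseline_intensity = baseline_intensity or dict(DEFAULT_BASELINE)
    rng = np.random.default_rng(seed)
    out = {}
    for wl in wavelengths_nm:
        ehbo, ehbr = extinction.eps(wl)
        od = ehbo * np.asarray(hbo_t) + ehbr * np.asarray(hbr_t)
        od = od - np.log10(1.0 + np.asarray(ls_frac_t))
        i = baseline_intensity[float(wl)] * 10.0 ** (-od)
        if noise_cv > 0:
            i = i * (1.0 + noise_cv * rng.standard_normal(i.shape))
        out[float(wl)] = i
    return out
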