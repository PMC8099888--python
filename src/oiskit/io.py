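"""Containers and file I/O for multispectral wide-field recordings.

A recording is a set of per-wavelength frame stacks acquired under alternating
LED illumination, together with the illumination schedule and the whisker
stimulation protocol. On disk a recording is a multi-page TIFF (one
interleaved stack, or one file per wavelength) plus a JSON sidecar holding the
schedule, the protocol, pixel size and stimulus onsets.

Frame times are frame-center times in seconds, zero at the start of the
recording; stimulus onsets live in the same clock. Interleaving starts at
channel 0 of the schedule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "StimulusProtocol",
    "IlluminationSchedule",
    "FrameStack",
    "MultispectralRecording",
    "TrialSet",
    "ConfigurationError",
    "FormatError",
    "demultiplex",
    "interleave",
    "split_trials",
    "load_recording",
    "save_recording",
]

DEFAULT_WAVELENGTHS_NM = (528, 625, 850)
WAVELENGTH_LABELS = {528: "Green", 625: "Red", 850: "IR"}


class ConfigurationError(ValueError):
    """A sidecar/config is missing or holds an invalid key."""


class FormatError(ValueError):
    """An on-disk stack does not match its declared layout."""


def _label_for(wavelength_nm: float) -> str:
    return WAVELENGTH_LABELS.get(int(wavelength_nm), f"{wavelength_nm:g}nm")


@dataclass(frozen=True)
class StimulusProtocol:
    """Whisker deflection protocol: brief pulse trains repeated many times."""

    pulse_duration_s: float = 0.010
    train_duration_s: float = 10.0
    inter_train_s: float = 90.0
    pulse_rate_hz: float = 2.0
    n_trials: int = 14

    def __post_init__(self) -> None:
        for name in ("pulse_duration_s", "train_duration_s", "inter_train_s", "pulse_rate_hz"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.train_duration_s >= self.inter_train_s:
            raise ConfigurationError("train_duration_s must be shorter than inter_train_s")

    def to_dict(self) -> dict:
        return {
            "pulse_duration_s": self.pulse_duration_s,
            "train_duration_s": self.train_duration_s,
            "inter_train_s": self.inter_train_s,
            "pulse_rate_hz": self.pulse_rate_hz,
            "n_trials": self.n_trials,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(**d)


@dataclass(frozen=True)
class IlluminationSchedule:
    """Ordered LED wavelengths alternated frame-by-frame at a fixed per-channel rate."""

    wavelengths_nm: tuple = DEFAULT_WAVELENGTHS_NM
    per_channel_rate_hz: float = 6.0
    modes: tuple = ("reflection", "reflection", "transmission")

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths_nm", tuple(self.wavelengths_nm))
        object.__setattr__(self, "modes", tuple(self.modes))
        if len(set(self.wavelengths_nm)) != len(self.wavelengths_nm):
            raise ConfigurationError("wavelengths must be distinct")
        if self.per_channel_rate_hz <= 0:
            raise ConfigurationError("per_channel_rate_hz must be > 0")
        if len(self.modes) != len(self.wavelengths_nm):
            raise ConfigurationError("one mode per wavelength required")
        labels = self.labels
        if len(set(labels)) != len(labels):
            raise ConfigurationError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.wavelengths_nm)

    @property
    def labels(self) -> tuple:
        return tuple(_label_for(w) for w in self.wavelengths_nm)

    @property
    def interleaved_rate_hz(self) -> float:
        return self.per_channel_rate_hz * self.n_channels

    def mode_of(self, wavelength_nm: float) -> str:
        return self.modes[self.wavelengths_nm.index(wavelength_nm)]

    def to_dict(self) -> dict:
        return {
            "wavelengths_nm": list(self.wavelengths_nm),
            "per_channel_rate_hz": self.per_channel_rate_hz,
            "modes": list(self.modes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IlluminationSchedule":
        return cls(
            wavelengths_nm=tuple(d["wavelengths_nm"]),
            per_channel_rate_hz=d["per_channel_rate_hz"],
            modes=tuple(d.get("modes", ("reflection",) * len(d["wavelengths_nm"]))),
        )


@dataclass
class FrameStack:
    """A T x H x W stack of non-negative intensities for one wavelength."""

    frames: np.ndarray
    time_axis_s: np.ndarray
    wavelength_nm: float
    px_size_um: float = 35.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.time_axis_s = np.asarray(self.time_axis_s, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if self.frames.shape[0] != self.time_axis_s.shape[0]:
            raise ValueError("frame count must equal time axis length")
        if self.time_axis_s.size > 1 and not np.all(np.diff(self.time_axis_s) > 0):
            raise ValueError("time axis must be strictly increasing")
        if self.px_size_um <= 0:
            raise ValueError("px_size_um must be > 0")
        if np.issubdtype(self.frames.dtype, np.floating) and np.nanmin(self.frames) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_hw(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def label(self) -> str:
        return _label_for(self.wavelength_nm)


@dataclass
class MultispectralRecording:
    stacks: list  # list[FrameStack], schedule order
    schedule: IlluminationSchedule
    protocol: StimulusProtocol
    stim_onsets_s: list
    px_size_um: float = 35.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {s.shape_hw for s in self.stacks}
        if len(shapes) > 1:
            raise ValueError("all stacks must share the same grid")
        px = {s.px_size_um for s in self.stacks}
        if len(px) > 1 or (self.stacks and self.stacks[0].px_size_um != self.px_size_um):
            raise ValueError("all stacks must share px_size_um")
        t_end = max(s.time_axis_s[-1] for s in self.stacks) if self.stacks else 0.0
        for onset in self.stim_onsets_s:
            if not (0.0 <= onset <= t_end):
                raise ValueError(f"stimulus onset {onset} s outside the recording (0..{t_end:.2f} s)")

    def stack(self, key) -> FrameStack:
        """Fetch a stack by wavelength (number) or label (str)."""
        for s in self.stacks:
            if s.wavelength_nm == key or s.label == key:
                return s
        raise KeyError(f"no channel {key!r}")


@dataclass
class TrialSet:
    """Per-trial windows of one channel, aligned on the stimulus onset.

    Trial time axes are relative to the onset (negative = baseline).
    """

    trials: list  # list[FrameStack]
    pre_window_s: float
    post_window_s: float

    def __post_init__(self) -> None:
        if not self.trials:
            raise ValueError("at least one trial required")
        if self.pre_window_s <= 0:
            raise ValueError("pre_window_s must be > 0")
        shapes = {t.frames.shape for t in self.trials}
        if len(shapes) > 1:
            raise ValueError("all trials must have the same shape")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def demultiplex(frames: np.ndarray, schedule: IlluminationSchedule,
                px_size_um: float = 35.0) -> list:
    """Split an interleaved stack into per-wavelength stacks.

    Frames rotate through the schedule starting at channel 0; channel k
    receives frames k, k+n, k+2n, ... A trailing incomplete rotation is
    dropped with a warning. Each output carries the global frame-center
    times of its own frames.
    """
    frames = np.asarray(frames)
    n = schedule.n_channels
    t_total = frames.shape[0]
    usable = (t_total // n) * n
    if usable < t_total:
        warnings.warn(
            f"dropping {t_total - usable} trailing frame(s) of an incomplete "
            f"{n}-channel rotation", stacklevel=2)
    dt = 1.0 / schedule.interleaved_rate_hz
    global_times = (np.arange(t_total) + 0.5) * dt
    stacks = []
    for k, wl in enumerate(schedule.wavelengths_nm):
        idx = np.arange(k, usable, n)
        stacks.append(FrameStack(frames=frames[idx], time_axis_s=global_times[idx],
                                 wavelength_nm=wl, px_size_um=px_size_um))
    return stacks


def interleave(stacks: Sequence[FrameStack]) -> np.ndarray:
    """Inverse of :func:`demultiplex` for equal-length stacks."""
    n_frames = {s.n_frames for s in stacks}
    if len(n_frames) != 1:
        raise ValueError("stacks must have equal frame counts to interleave")
    t = n_frames.pop()
    out = np.empty((t * len(stacks),) + stacks[0].shape_hw, dtype=stacks[0].frames.dtype)
    for k, s in enumerate(stacks):
        out[k::len(stacks)] = s.frames
    return out


def split_trials(stack: FrameStack, protocol: StimulusProtocol,
                 stim_onsets_s: Sequence[float], pre_window_s: float,
                 post_window_s: float) -> TrialSet:
    """Cut [onset - pre, onset + post) windows, aligned on the nearest frame.

    The frame nearest each onset gets the same index in every trial, so
    trials can be averaged sample-by-sample.
    """
    t = stack.time_axis_s
    fs = 1.0 / float(np.median(np.diff(t)))
    n_pre = int(round(pre_window_s * fs))
    n_post = int(round(post_window_s * fs))
    bad = []
    trials = []
    for onset in stim_onsets_s:
        i0 = int(np.argmin(np.abs(t - onset)))
        lo, hi = i0 - n_pre, i0 + n_post
        if lo < 0 or hi > stack.n_frames:
            bad.append(onset)
            continue
        trials.append(FrameStack(frames=stack.frames[lo:hi],
                                 time_axis_s=t[lo:hi] - onset,
                                 wavelength_nm=stack.wavelength_nm,
                                 px_size_um=stack.px_size_um))
    if bad:
        raise ValueError(f"trial window out of range for onsets: {bad}")
    n = len(trials)
    if not 10 <= n <= 20:
        warnings.warn(f"trial count {n} outside the usual 10-20 range", stacklevel=2)
    return TrialSet(trials=trials, pre_window_s=pre_window_s, post_window_s=post_window_s)


_SIDECAR_REQUIRED = ("wavelengths_nm", "per_channel_rate_hz", "px_size_um",
                     "protocol", "stim_onsets_s", "layout")


def save_recording(recording: MultispectralRecording, stack_path, sidecar_path,
                   layout: str = "interleaved") -> list:
    """Write a recording as TIFF stack(s) + JSON sidecar; returns written paths.

    layout="interleaved" writes one multi-page TIFF in schedule rotation;
    layout="split" writes one TIFF per wavelength (suffix _<label>).
    """
    stack_path = Path(stack_path)
    sidecar_path = Path(sidecar_path)
    written = []
    if layout == "interleaved":
        tifffile.imwrite(stack_path, interleave(recording.stacks))
        written.append(stack_path)
    elif layout == "split":
        for s in recording.stacks:
            p = stack_path.with_name(f"{stack_path.stem}_{s.label}{stack_path.suffix}")
            tifffile.imwrite(p, s.frames)
            written.append(p)
    else:
        raise ConfigurationError(f"unknown layout {layout!r}")
    sidecar = {
        **recording.schedule.to_dict(),
        "px_size_um": recording.px_size_um,
        "protocol": recording.protocol.to_dict(),
        "stim_onsets_s": list(map(float, recording.stim_onsets_s)),
        "layout": layout,
        "metadata": recording.metadata,
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    written.append(sidecar_path)
    return written


def load_recording(stack_path, sidecar_path) -> MultispectralRecording:
    """Read a TIFF(+JSON) recording written by :func:`save_recording`."""
    sidecar_path = Path(sidecar_path)
    stack_path = Path(stack_path)
    if not sidecar_path.exists():
        raise ConfigurationError(f"sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in sidecar:
            raise ConfigurationError(f"sidecar missing required key {key!r}")
    schedule = IlluminationSchedule.from_dict(sidecar)
    protocol = StimulusProtocol.from_dict(sidecar["protocol"])
    px = float(sidecar["px_size_um"])
    layout = sidecar["layout"]
    if layout == "interleaved":
        frames = tifffile.imread(stack_path)
        if frames.shape[0] % schedule.n_channels:
            raise FormatError(
                f"interleaved frame count {frames.shape[0]} not divisible by "
                f"{schedule.n_channels} channels")
        stacks = demultiplex(frames, schedule, px_size_um=px)
    elif layout == "split":
        stacks = []
        dt = 1.0 / schedule.interleaved_rate_hz
        for k, wl in enumerate(schedule.wavelengths_nm):
            label = _label_for(wl)
            p = stack_path.with_name(f"{stack_path.stem}_{label}{stack_path.suffix}")
            frames = tifffile.imread(p)
            times = (np.arange(frames.shape[0]) * schedule.n_channels + k + 0.5) * dt
            stacks.append(FrameStack(frames=frames, time_axis_s=times,
                                     wavelength_nm=wl, px_size_um=px))
    else:
        raise FormatError(f"unknown layout {layout!r} in sidecar")
    return MultispectralRecording(
        stacks=stacks, schedule=schedule, protocol=protocol,
        stim_onsets_s=list(sidecar["stim_onsets_s"]), px_size_um=px,
        metadata=sidecar.get("metadata", {}))
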