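"""Surface-EMG conditioning.

This module implements the deterministic signal chain shared by the online
torque-estimation path and the offline analysis path:

* envelope extraction — 2nd-order Butterworth high-pass at 35 Hz, full-wave
  rectification, 2nd-order Butterworth low-pass at 4 Hz, then normalisation to
  the per-muscle maximum voluntary contraction (MVC);
* fatigue pre-filtering — 4th-order Butterworth band-pass 15–450 Hz;
* windowed RMS.

Two phase-handling modes are exposed everywhere: ``"causal"`` single-pass
filtering (what a streaming controller can do; zero initial conditions) and
``"zero_phase"`` forward–backward filtering for offline analysis (no group
delay; the effective order is doubled).  Stated filter orders are prototype
orders of the single-pass design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal


class SamplingRateError(ValueError):
    """Sampling rate too low for the requested filter corners."""


class ConfigurationError(ValueError):
    """Invalid configuration value (e.g. non-positive MVC)."""


def _as_2d(samples: np.ndarray) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("samples must be a 1-D or 2-D array")
    return x


@dataclass(frozen=True)
class EmgRecording:
    """Multichannel raw sEMG time series.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Raw amplitudes in any consistent unit (V in the hardware, arbitrary
        for synthetic data).
    fs : float
        Sampling rate in Hz.
    channels : tuple of str
        Ordered channel labels (e.g. ``("biceps", "triceps")``).
    t0 : float
        Start time in seconds.
    """

    samples: np.ndarray
    fs: float
    channels: tuple
    t0: float = 0.0

    def __post_init__(self):
        x = _as_2d(self.samples)
        object.__setattr__(self, "samples", x)
        object.__setattr__(self, "channels", tuple(self.channels))
        if not self.fs > 0:
            raise SamplingRateError("fs must be positive")
        if x.shape[1] != len(self.channels):
            raise ValueError(
                f"{x.shape[1]} data columns but {len(self.channels)} channel labels"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, self.channels.index(name)]


@dataclass(frozen=True)
class EmgEnvelope:
    """Per-channel non-negative EMG envelope, as a fraction of MVC."""

    values: np.ndarray
    fs: float
    channels: tuple
    t0: float = 0.0

    def __post_init__(self):
        v = _as_2d(self.values)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "channels", tuple(self.channels))
        if v.shape[1] != len(self.channels):
            raise ValueError("channel count mismatch")
        if np.any(v < 0):
            raise ValueError("envelope values must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channels.index(name)]


@dataclass(frozen=True)
class MvcRecord:
    """Per-channel maximum-voluntary-contraction envelope amplitude."""

    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        vals = dict(self.values)
        for ch, v in vals.items():
            if not (np.isfinite(v) and v > 0):
                raise ConfigurationError(f"MVC for {ch!r} must be strictly positive")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, ch: str) -> float:
        return self.values[ch]

    def channels(self):
        return tuple(self.values)


def _butter_sos(order: int, corners, btype: str, fs: float):
    return signal.butter(order, corners, btype=btype, fs=fs, output="sos")


def _apply(sos, x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "causal":
        return signal.sosfilt(sos, x, axis=0)
    if mode == "zero_phase":
        return signal.sosfiltfilt(sos, x, axis=0)
    raise ValueError(f"unknown mode {mode!r}; use 'causal' or 'zero_phase'")


def rectified_envelope(
    samples: np.ndarray,
    fs: float,
    mode: str = "zero_phase",
    hp_hz: float = 35.0,
    lp_hz: float = 4.0,
    order: int = 2,
) -> np.ndarray:
    """Unnormalised envelope: ``lowpass(|highpass(x)|)``.

    The building block behind :func:`envelope_pipeline`; also used to extract
    the MVC amplitude from an MVC trial.
    """
    x = _as_2d(samples)
    if fs < 100.0:
        raise SamplingRateError(
            f"fs={fs} Hz too low; the {lp_hz} Hz low-pass needs fs >= 100 Hz"
        )
    hp = _butter_sos(order, hp_hz, "highpass", fs)
    lp = _butter_sos(order, lp_hz, "lowpass", fs)
    env = _apply(lp, np.abs(_apply(hp, x, mode)), mode)
    return np.clip(env, 0.0, None)


def envelope_pipeline(
    rec: EmgRecording,
    mvc: MvcRecord,
    mode: str = "zero_phase",
    hp_hz: float = 35.0,
    lp_hz: float = 4.0,
    order: int = 2,
) -> EmgEnvelope:
    """High-pass, rectify, low-pass and MVC-normalise a raw EMG recording.

    Parameters
    ----------
    rec : EmgRecording
    mvc : MvcRecord
        Must cover every channel of ``rec``; envelopes are divided by the
        per-channel MVC so the output is a fraction of MVC.
    mode : {"zero_phase", "causal"}
        Offline analysis uses zero-phase filtering; the controller path uses
        causal single-pass filtering.
    """
    missing = [ch for ch in rec.channels if ch not in mvc.values]
    if missing:
        raise ConfigurationError(f"MVC record missing channels: {missing}")
    env = rectified_envelope(rec.samples, rec.fs, mode=mode, hp_hz=hp_hz,
                             lp_hz=lp_hz, order=order)
    scale = np.array([mvc[ch] for ch in rec.channels])
    return EmgEnvelope(env / scale, fs=rec.fs, channels=rec.channels, t0=rec.t0)


def mvc_from_trial(
    rec: EmgRecording, mode: str = "zero_phase", **kwargs
) -> MvcRecord:
    """MVC amplitudes as the peak of the MVC-trial *envelope* (noise-robust)."""
    env = rectified_envelope(rec.samples, rec.fs, mode=mode, **kwargs)
    return MvcRecord({ch: float(env[:, i].max()) for i, ch in enumerate(rec.channels)})


def bandpass_fatigue(
    rec: EmgRecording,
    lo_hz: float = 15.0,
    hi_hz: float = 450.0,
    order: int = 4,
    mode: str = "zero_phase",
) -> EmgRecording:
    """Band-pass a raw recording 15–450 Hz (4th-order Butterworth) for fatigue
    analysis."""
    if rec.fs <= 2 * hi_hz:
        raise SamplingRateError(
            f"fs={rec.fs} Hz too low for a {hi_hz} Hz band edge (need fs > {2 * hi_hz})"
        )
    sos = _butter_sos(order, (lo_hz, hi_hz), "bandpass", rec.fs)
    return EmgRecording(_apply(sos, rec.samples, mode), fs=rec.fs,
                        channels=rec.channels, t0=rec.t0)


def rms(window: np.ndarray) -> float:
    """Root mean square of an amplitude window (same units as the input)."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("RMS of an empty window is undefined")
    return float(np.sqrt(np.mean(np.square(x))))
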