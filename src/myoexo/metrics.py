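"""Offline outcome metrics.

Movement segmentation (Savitzky–Golay derivative thresholding), spectral
arc-length smoothness (SPARC), per-phase muscular-activity RMS, EMG fatigue
indices (average rectified value and median frequency over eight 3 s epochs
with first-order rate fits) and the biological-torque decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .myoprocessor import TorqueSeries
from .signal_processing import EmgEnvelope, EmgRecording, rms


@dataclass(frozen=True)
class MovementSegment:
    """Half-open sample range [start, end) of one movement phase."""

    start: int
    end: int
    phase: str  # "flexion" | "extension"
    peak_velocity: float  # rad/s (signed peak of the smoothed derivative)

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("segment start must precede its end")
        if self.phase not in ("flexion", "extension"):
            raise ValueError("phase must be 'flexion' or 'extension'")


def segment_movements(
    angle: np.ndarray,
    fs: float,
    sg_window: int = 51,
    sg_order: int = 3,
    threshold: float = 0.10,
    min_duration: float = 0.05,
) -> list:
    """Segment flexion/extension movements from the elbow angle.

    The angle is smoothed with a Savitzky–Golay filter whose derivative kernel
    yields d theta/dt directly; contiguous runs where |d theta/dt| exceeds
    ``threshold`` times its peak magnitude become segments, labelled flexion
    (positive mean derivative) or extension (negative). Runs shorter than
    ``min_duration`` seconds are discarded as noise stubs.
    """
    angle = np.asarray(angle, dtype=float)
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and greater than sg_order")
    if angle.size <= sg_window:
        raise ValueError("angle series shorter than the smoothing window")
    dtheta = signal.savgol_filter(angle, sg_window, sg_order, deriv=1,
                                  delta=1.0 / fs)
    peak = np.max(np.abs(dtheta))
    if peak <= 1e-10:  # numerically flat signal
        return []
    mask = np.abs(dtheta) > threshold * peak
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    min_len = int(round(min_duration * fs))
    segments = []
    for s, e in zip(run_starts, run_ends):
        if e - s < max(min_len, 2):
            continue
        d = dtheta[s:e]
        phase = "flexion" if float(np.mean(d)) >= 0 else "extension"
        pk = d[np.argmax(np.abs(d))]
        segments.append(MovementSegment(int(s), int(e), phase, float(pk)))
    return segments


@dataclass(frozen=True)
class SparcParams:
    """SPARC settings: spectral cutoff (Hz), adaptive amplitude threshold on
    the normalised magnitude spectrum, and zero-padding level (the FFT length
    is 2**(ceil(log2 n) + pad_level))."""

    cutoff: float = 10.0
    amp_threshold: float = 0.05
    pad_level: int = 4

    def __post_init__(self):
        if not self.cutoff > 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.amp_threshold < 1:
            raise ValueError("amp_threshold must be in (0, 1)")


def sparc(speed: np.ndarray, fs: float, params: SparcParams | None = None) -> float:
    """Spectral arc-length smoothness of a speed profile (dimensionless, <= 0;
    closer to zero = smoother).

    The magnitude spectrum of the speed profile is normalised by its maximum,
    restricted to the adaptive band (up to the last frequency below ``cutoff``
    where it still exceeds ``amp_threshold``), and its arc length — with the
    frequency axis scaled by the band width — is returned negated. Invariant
    to amplitude scaling by construction.
    """
    p = params or SparcParams()
    v = np.asarray(speed, dtype=float)
    if v.size == 0:
        raise ValueError("speed profile is empty")
    if np.all(v == 0):
        warnings.warn("all-zero speed profile: SPARC undefined, returning NaN",
                      stacklevel=2)
        return float("nan")
    v = v / np.max(np.abs(v))  # amplitude invariance, numerically exact
    nfft = int(2 ** (np.ceil(np.log2(v.size)) + p.pad_level))
    f = np.arange(nfft // 2 + 1) * fs / nfft
    Mf = np.abs(np.fft.rfft(v, nfft))
    Mf = Mf / Mf.max()
    below = f <= p.cutoff
    f_sel, M_sel = f[below], Mf[below]
    above = np.flatnonzero(M_sel >= p.amp_threshold)
    f_sel = f_sel[: above[-1] + 1]
    M_sel = M_sel[: above[-1] + 1]
    f_range = f_sel[-1] if f_sel[-1] > 0 else 1.0
    darc = np.sqrt((np.diff(f_sel) / f_range) ** 2 + np.diff(M_sel) ** 2)
    return float(-np.sum(darc))


def phase_rms(env: EmgEnvelope | EmgRecording, segments: list) -> dict:
    """RMS activity per channel over the union of same-phase segments.

    For an :class:`EmgEnvelope` the result is in %MVC; for a raw
    :class:`EmgRecording` it stays in signal units. A phase with no segments
    maps to ``None`` (missing value, not zero).
    """
    if isinstance(env, EmgEnvelope):
        data, scale = env.values, 100.0
    else:
        data, scale = env.samples, 1.0
    n = data.shape[0]
    out = {}
    for phase in ("flexion", "extension"):
        segs = [s for s in segments if s.phase == phase]
        if any(s.end > n for s in segs):
            raise ValueError("segment extends past the end of the series")
        if not segs:
            out[phase] = None
            continue
        sl = np.concatenate([np.arange(s.start, s.end) for s in segs])
        out[phase] = {
            ch: scale * rms(data[sl, i]) for i, ch in enumerate(env.channels)
        }
    return out


@dataclass(frozen=True)
class FatigueMetrics:
    """Per-epoch fatigue indices and their first-order rates for one channel.

    ``arv`` (signal units) and ``mnf`` (Hz) over the epochs; the rates are the
    least-squares slopes over epoch mid-times expressed as % of the fitted
    first-epoch value per second.
    """

    epoch_times: np.ndarray
    arv: np.ndarray
    mnf: np.ndarray
    arv_rate: float
    mnf_rate: float


def _median_frequency(x: np.ndarray, fs: float, estimator: str = "median") -> float:
    f, P = signal.periodogram(x - np.mean(x), fs=fs, window="hann")
    f, P = f[1:], P[1:]
    total = float(np.sum(P))
    if total == 0:
        return float("nan")
    if estimator == "mean":
        return float(np.sum(f * P) / total)
    cum = np.cumsum(P)
    half = total / 2.0
    i = int(np.searchsorted(cum, half))
    if i == 0:
        return float(f[0])
    # linear interpolation inside the crossing bin
    frac = (half - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(f[i - 1] + frac * (f[i] - f[i - 1]))


def _rate_fit(times: np.ndarray, values: np.ndarray) -> float:
    # times are relative to the contraction onset; the rate is normalised by
    # the fitted value at the start of the first epoch (the onset), so a
    # signal ramping at r %/s of its initial value is recovered as r
    slope, intercept = np.polyfit(times, values, 1)
    if intercept == 0:
        return float("nan")
    return float(100.0 * slope / intercept)


def fatigue_indices(
    rec: EmgRecording,
    window: tuple,
    n_epochs: int = 8,
    epoch_len: float = 3.0,
    estimator: str = "median",
) -> dict:
    """ARV and median-frequency fatigue indices over consecutive epochs.

    Parameters
    ----------
    rec : EmgRecording
        Band-passed (15–450 Hz) raw EMG.
    window : (t_start, t_end)
        Contraction window in seconds relative to the recording start; must be
        at least ``n_epochs * epoch_len`` long. Epochs are laid out from
        ``t_start``.
    estimator : {"median", "mean"}
        Spectral centre statistic. The study's "MNF" is the *median* frequency
        of the power spectrum; a mean-frequency variant is kept behind this
        flag.

    Returns
    -------
    dict channel -> FatigueMetrics
    """
    t_start, t_end = window
    if t_end - t_start < n_epochs * epoch_len - 1e-9:
        raise ValueError(
            f"window of {t_end - t_start:.1f} s too short for "
            f"{n_epochs} epochs of {epoch_len} s"
        )
    i0 = int(round(t_start * rec.fs))
    ne = int(round(epoch_len * rec.fs))
    if i0 + n_epochs * ne > rec.n_samples:
        raise ValueError("window extends past the end of the recording")
    mid_times = t_start + (np.arange(n_epochs) + 0.5) * epoch_len
    out = {}
    for ci, ch in enumerate(rec.channels):
        x = rec.samples[:, ci]
        arv = np.empty(n_epochs)
        mnf = np.empty(n_epochs)
        for k in range(n_epochs):
            seg = x[i0 + k * ne: i0 + (k + 1) * ne]
            arv[k] = np.mean(np.abs(seg))
            mnf[k] = _median_frequency(seg, rec.fs, estimator)
        rel = mid_times - t_start  # rates relative to the contraction onset
        out[ch] = FatigueMetrics(
            epoch_times=mid_times, arv=arv, mnf=mnf,
            arv_rate=_rate_fit(rel, arv), mnf_rate=_rate_fit(rel, mnf),
        )
    return out


def biological_torque(tau_id: TorqueSeries, tau_assist: TorqueSeries):
    """Biological torque tau_bio = tau_ID - tau_assist and relative changes.

    Returns ``(series, report)`` where the report carries the mean torques and
    the relative change of the biological torque with respect to the
    inverse-dynamics torque, both as the ratio of the means and as the mean of
    the per-sample ratios (the study's per-subject averaging convention).
    """
    if tau_id.tau.shape != tau_assist.tau.shape or \
            not np.allclose(tau_id.t, tau_assist.t):
        raise ValueError("torque series are misaligned")
    bio = tau_id.tau - tau_assist.tau
    series = TorqueSeries(tau_id.t, bio, role="biological")
    mean_id = float(np.mean(tau_id.tau))
    mean_bio = float(np.mean(bio))
    rel_ratio_of_means = 100.0 * (mean_bio - mean_id) / mean_id if mean_id else float("nan")
    valid = np.abs(tau_id.tau) > 1e-9
    if np.any(valid):
        ratios = (bio[valid] - tau_id.tau[valid]) / tau_id.tau[valid]
        rel_mean_of_ratios = float(100.0 * np.mean(ratios))
    else:
        rel_mean_of_ratios = float("nan")
    report = {
        "mean_inverse_dynamics_Nm": mean_id,
        "mean_assist_Nm": float(np.mean(tau_assist.tau)),
        "mean_biological_Nm": mean_bio,
        "relative_change_ratio_of_means_pct": rel_ratio_of_means,
        "relative_change_mean_of_ratios_pct": rel_mean_of_ratios,
    }
    return series, report
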