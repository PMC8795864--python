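"""Continuous-recording preprocessing: band-pass, decimation, epoching, rejection.

The standard TMS-EEG chain is 3-30 Hz zero-phase band-pass at the
acquisition rate (1,024 Hz), 8-fold sample-rate reduction to 128 Hz,
epoching from 1,000 ms before to 2,000 ms after each stimulus, and
artifact-based segment rejection that keeps roughly 80-100 of the 120
stimulus segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)


@dataclass
class RawRecording:
    """Continuous multichannel recording with stimulus events.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Amplitude in microvolt-scaled units.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
    events : ndarray of int
        Stimulus onsets as sample indices, strictly increasing.
    band_hz : tuple of float, optional
        Pass-band of the last band-pass applied, used to decide whether
        decimation needs its own anti-alias filter.
    """

    signal: np.ndarray
    fs: float
    channel_labels: tuple
    events: np.ndarray
    band_hz: tuple | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.events = np.asarray(self.events, dtype=np.int64)
        self.channel_labels = tuple(self.channel_labels)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("channel_labels length does not match signal")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.events.size:
            if np.any(np.diff(self.events) <= 0):
                raise ValueError("events must be strictly increasing")
            if self.events[0] < 0 or self.events[-1] >= self.signal.shape[1]:
                raise ValueError("events outside signal bounds")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class EpochSet:
    """Stimulus-locked segments, each a multichannel time series X(t).

    ``data`` has shape (n_segments, n_channels, n_samples); ``t0_index``
    is the within-segment sample of the stimulus; ``dt`` the sampling
    interval in seconds (1/128 s after standard preprocessing).
    """

    data: np.ndarray
    dt: float
    t0_index: int
    channel_labels: tuple

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (segments x channels x samples)")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.t0_index < self.data.shape[2]:
            raise ValueError("t0_index outside segment")

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def times_ms(self) -> np.ndarray:
        """Sample times relative to the stimulus, in milliseconds."""
        return (np.arange(self.n_samples) - self.t0_index) * self.dt * 1e3


def bandpass(raw: RawRecording, f_lo: float, f_hi: float, order: int = 4) -> RawRecording:
    """Zero-phase Butterworth band-pass (forward-backward, 4th order).

    Zero-phase filtering preserves the latency of evoked components,
    which matters because network snapshots are read at fixed
    post-stimulus times.
    """
    if not (0 < f_lo < f_hi < raw.fs / 2):
        raise ValueError(
            f"band ({f_lo}, {f_hi}) Hz infeasible for fs={raw.fs} Hz"
        )
    sos = signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=raw.fs, output="sos")
    out = signal.sosfiltfilt(sos, raw.signal, axis=1)
    return replace(raw, signal=out, band_hz=(f_lo, f_hi))


def decimate(raw: RawRecording, factor: int) -> RawRecording:
    """Reduce the sampling rate by an integer factor.

    If the recording is already band-limited below the new Nyquist
    frequency (tracked via ``band_hz``), plain subsampling is used so
    that no additional phase distortion is introduced; otherwise a
    zero-phase anti-alias low-pass is applied first. Event indices are
    rescaled by integer division.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    if factor == 1:
        return replace(raw)
    fs_new = raw.fs / factor
    if abs(fs_new - round(fs_new)) > 1e-9:
        raise ValueError(
            f"factor {factor} gives non-integer rate {fs_new} Hz from fs={raw.fs}"
        )
    new_nyq = fs_new / 2
    sig = raw.signal
    if raw.band_hz is None or raw.band_hz[1] >= new_nyq:
        logger.info("decimate: applying anti-alias low-pass at %.6g Hz", 0.8 * new_nyq)
        sos = signal.butter(8, 0.8 * new_nyq, btype="lowpass", fs=raw.fs, output="sos")
        sig = signal.sosfiltfilt(sos, sig, axis=1)
        band = (0.0, 0.8 * new_nyq)
    else:
        band = raw.band_hz
    return RawRecording(
        signal=sig[:, ::factor],
        fs=fs_new,
        channel_labels=raw.channel_labels,
        events=raw.events // factor,
        band_hz=band,
    )


def epoch(raw: RawRecording, t_pre_ms: float = -1000.0, t_post_ms: float = 2000.0) -> EpochSet:
    """Cut stimulus-locked segments over ``[t_pre, t_post)`` milliseconds.

    The window is closed on the left, open on the right, so the default
    (-1000, 2000) ms window at 128 Hz gives exactly 384 samples with the
    stimulus at sample 128. Events too close to the recording edge for a
    full window are dropped (logged), not fatal.
    """
    if t_pre_ms >= t_post_ms:
        raise ValueError("t_pre_ms must be below t_post_ms")
    n_pre = int(round(-t_pre_ms / 1e3 * raw.fs))
    n_post = int(round(t_post_ms / 1e3 * raw.fs))
    if n_pre < 0 or n_post <= 0:
        raise ValueError("epoch window must straddle or follow the stimulus")
    segments = []
    n_dropped = 0
    for e in raw.events:
        lo, hi = e - n_pre, e + n_post
        if lo < 0 or hi > raw.n_samples:
            n_dropped += 1
            logger.info("epoch: dropping event at sample %d (incomplete window)", e)
            continue
        segments.append(raw.signal[:, lo:hi])
    if n_dropped:
        logger.warning("epoch: dropped %d/%d boundary events", n_dropped, len(raw.events))
    if not segments:
        raise ValueError("no event has full window coverage")
    return EpochSet(
        data=np.stack(segments),
        dt=1.0 / raw.fs,
        t0_index=n_pre,
        channel_labels=raw.channel_labels,
    )


def reject_segments(
    epochs: EpochSet,
    amp_threshold: float = 120.0,
    z_threshold: float = 5.0,
    max_segments: int | None = None,
) -> EpochSet:
    """Drop artifact segments by peak amplitude and variance outlier score.

    A segment is rejected when its peak absolute amplitude exceeds
    ``amp_threshold`` (microvolt-scaled units; 120 is a conventional
    EEG artifact bound) or when its variance is a robust outlier: the
    per-segment variance's deviation from the median, scaled by the
    MAD-based robust standard deviation, exceeds ``z_threshold``.
    ``max_segments`` optionally caps the retained count (first-come),
    mirroring studies that analyse at most ~100 of 120 stimuli.
    """
    if amp_threshold <= 0 or z_threshold <= 0:
        raise ValueError("thresholds must be positive")
    peak = np.max(np.abs(epochs.data), axis=(1, 2))
    var = np.var(epochs.data, axis=(1, 2))
    med = np.median(var)
    mad = np.median(np.abs(var - med))
    robust_sd = 1.4826 * mad if mad > 0 else np.std(var)
    if robust_sd == 0:
        z = np.zeros_like(var)
    else:
        z = (var - med) / robust_sd
    keep = (peak <= amp_threshold) & (z <= z_threshold)
    n_amp = int(np.sum(peak > amp_threshold))
    n_var = int(np.sum((z > z_threshold) & (peak <= amp_threshold)))
    if not np.any(keep):
        raise ValueError(
            f"all {epochs.n_segments} segments rejected "
            f"(amp_threshold={amp_threshold}, z_threshold={z_threshold})"
        )
    idx = np.flatnonzero(keep)
    if max_segments is not None:
        idx = idx[:max_segments]
    logger.info(
        "reject_segments: kept %d/%d (amplitude: %d, variance: %d, cap: %s)",
        len(idx), epochs.n_segments, n_amp, n_var, max_segments,
    )
    return EpochSet(
        data=epochs.data[idx],
        dt=epochs.dt,
        t0_index=epochs.t0_index,
        channel_labels=epochs.channel_labels,
    )
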