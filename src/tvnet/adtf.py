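"""Adaptive directed transfer function: spectral transfer, normalization,
band integration, segment averaging and baseline correction.

From the time-varying coefficient matrices A(k, t), the frequency-domain
system matrix at each retained time point is

    Lam(f, t) = I - sum_{k=1..P} A(k, t) exp(-j 2 pi f dt k),

its inverse H(f, t) = Lam(f, t)^-1 is the transfer matrix, and the
normalized directed influence of source j on sink i is

    gamma2_ij(f, t) = |H_ij(f, t)|^2 / sum_m |H_im(f, t)|^2,

so each sink row sums to one over sources. Band integration averages
gamma2 over the frequency bins of [f1, f2] (default 3-30 Hz in 1 Hz
steps, 28 bins), giving Theta2_ij(t) in [0, 1]. Subtracting the
time-averaged pre-stimulus baseline makes negative values mark
connections weaker than baseline.

Index convention throughout: first matrix index = sink, second = source;
the information outflow of channel j is read down column j.

Time grids are defined by (start, count) — 40 baseline points from
-360 ms and 246 post-stimulus points from +60 ms, both stepping one
sample of the 128 Hz analysis rate — anchored to the nearest coefficient
sample. The counts are part of the analysis contract and are validated,
not derived from naive window arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tvmvar import TVMVARModel

logger = logging.getLogger(__name__)

#: Default analysis band (Hz) and grid step.
DEFAULT_BAND = (3.0, 30.0)
DEFAULT_FREQ_STEP = 1.0
#: (start_ms, n_points) of the default baseline and post-stimulus grids.
BASELINE_GRID = (-360.0, 40)
POST_GRID = (60.0, 246)
#: A run whose fraction of numerically singular (f, t) points exceeds
#: this bound fails loudly instead of silently averaging around them.
MAX_FLAGGED_FRACTION = 0.01
_SINGULAR_NORM = 1e12


@dataclass
class TimeGrid:
    """Evenly spaced analysis time points anchored to coefficient samples."""

    indices: np.ndarray   # sample indices within the segment
    times_ms: np.ndarray  # relative to the stimulus

    @property
    def n_points(self) -> int:
        return self.indices.size


def make_time_grid(t0_index: int, fs: float, start_ms: float, n_points: int,
                   n_samples: int | None = None) -> TimeGrid:
    """Grid of ``n_points`` consecutive samples starting nearest ``start_ms``."""
    first = t0_index + int(round(start_ms / 1e3 * fs))
    idx = first + np.arange(n_points)
    if idx[0] < 0 or (n_samples is not None and idx[-1] >= n_samples):
        raise ValueError(
            f"grid ({start_ms} ms, {n_points} points) exceeds segment bounds"
        )
    return TimeGrid(indices=idx, times_ms=(idx - t0_index) / fs * 1e3)


def band_frequencies(f1: float = DEFAULT_BAND[0], f2: float = DEFAULT_BAND[1],
                     step: float = DEFAULT_FREQ_STEP) -> np.ndarray:
    """Inclusive frequency grid over [f1, f2]; 3-30 Hz at 1 Hz -> 28 bins."""
    if not 0 < f1 < f2:
        raise ValueError("need 0 < f1 < f2")
    return np.arange(f1, f2 + step / 2, step)


@dataclass
class SpectralTransfer:
    """Transfer matrices H(f, t) with singular (f, t) points flagged."""

    H: np.ndarray          # (T, F, n, n) complex
    freqs: np.ndarray      # Hz
    times_ms: np.ndarray
    flagged: np.ndarray    # (T, F) bool: numerically singular, not usable
    channel_labels: tuple


@dataclass
class ADTFMatrix:
    """Normalized directed influence gamma2 in [0, 1], sink x source."""

    gamma2: np.ndarray     # (T, F, n, n)
    freqs: np.ndarray
    times_ms: np.ndarray
    flagged: np.ndarray    # (T, F)
    channel_labels: tuple


@dataclass
class BandADTF:
    """Band-integrated influence Theta2_ij(t) on [f1, f2]."""

    theta2: np.ndarray     # (T, n, n)
    f1: float
    f2: float
    times_ms: np.ndarray
    channel_labels: tuple
    flagged_fraction: float = 0.0


@dataclass
class BaselineMatrix:
    """Time-averaged pre-stimulus influence, one n x n matrix."""

    mean_theta2: np.ndarray
    window_ms: tuple
    n_timepoints: int
    channel_labels: tuple


@dataclass
class CorrectedTensor:
    """Baseline-corrected influence; negative entries = weakened edges."""

    values: np.ndarray     # (T, n, n)
    times_ms: np.ndarray
    channel_labels: tuple
    band: tuple


def _transfer_from_coeffs(coeffs: np.ndarray, dt: float, freqs: np.ndarray):
    """H(f, t) from coefficient stacks (T, P, n, n); returns (H, flagged)."""
    n_t, order, n, _ = coeffs.shape
    phase = np.exp(-2j * np.pi * freqs[:, None] * dt * np.arange(1, order + 1)[None, :])
    # (T, n*n, P) @ (P, F) -> (T, n*n, F), then to (T, F, n, n)
    stack = np.ascontiguousarray(coeffs.transpose(0, 2, 3, 1).reshape(n_t, n * n, order))
    summed = stack @ phase.T  # (T, n*n, F) complex
    lam = np.eye(n) - summed.reshape(n_t, n, n, freqs.size).transpose(0, 3, 1, 2)
    try:
        with np.errstate(all="ignore"):
            h = np.linalg.inv(lam)
    except np.linalg.LinAlgError:
        h = np.full(lam.shape, np.nan, dtype=complex)
        for t in range(n_t):
            for f in range(freqs.size):
                try:
                    h[t, f] = np.linalg.inv(lam[t, f])
                except np.linalg.LinAlgError:
                    pass
    finite = np.isfinite(h).all(axis=(2, 3))
    with np.errstate(all="ignore"):
        big = np.nanmax(np.abs(h), axis=(2, 3)) > _SINGULAR_NORM
    flagged = ~finite | big
    return h, flagged


def spectral_transfer(model: TVMVARModel, freqs: np.ndarray,
                      times: np.ndarray) -> SpectralTransfer:
    """Transfer matrices of a fitted model at given sample indices.

    ``times`` are sample indices into the model's trajectory; they must
    all be estimated samples. Frequencies must lie strictly inside
    (0, Nyquist).
    """
    freqs = np.asarray(freqs, dtype=float)
    times = np.asarray(times, dtype=int)
    nyq = 0.5 / model.dt
    if np.any(freqs <= 0) or np.any(freqs >= nyq):
        raise ValueError(f"frequencies must lie in (0, {nyq}) Hz")
    if np.any(~model.estimated[times]):
        raise ValueError("requested times include unestimated samples")
    h, flagged = _transfer_from_coeffs(model.coeffs[times], model.dt, freqs)
    if flagged.any():
        logger.warning("spectral_transfer: %d singular (f,t) points flagged",
                       int(flagged.sum()))
    times_ms = (times - model.t0_index) * model.dt * 1e3
    return SpectralTransfer(H=h, freqs=freqs, times_ms=times_ms,
                            flagged=flagged, channel_labels=model.channel_labels)


def adtf_normalized(transfer: SpectralTransfer) -> ADTFMatrix:
    """Sink-row-normalized squared transfer magnitudes.

    Every unflagged (sink, f, t) row sums to one by construction; rows
    with zero norm are flagged rather than filled.
    """
    h = transfer.H
    power = h.real ** 2 + h.imag ** 2
    row = power.sum(axis=-1, keepdims=True)
    flagged = transfer.flagged | (row[..., 0] == 0).any(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma2 = power / row
    gamma2[flagged] = np.nan
    return ADTFMatrix(gamma2=gamma2, freqs=transfer.freqs,
                      times_ms=transfer.times_ms, flagged=flagged,
                      channel_labels=transfer.channel_labels)


def band_integrate(gamma: ADTFMatrix, f1: float = DEFAULT_BAND[0],
                   f2: float = DEFAULT_BAND[1]) -> BandADTF:
    """Average gamma2 over the frequency bins inside [f1, f2].

    Flagged (f, t) points are excluded from the average and their overall
    fraction recorded; a fraction above ``MAX_FLAGGED_FRACTION`` raises.
    A time point with every bin flagged cannot be averaged and raises.
    """
    sel = (gamma.freqs >= f1 - 1e-9) & (gamma.freqs <= f2 + 1e-9)
    if not np.any(sel):
        raise ValueError(f"no frequency bins inside [{f1}, {f2}] Hz")
    g = gamma.gamma2[:, sel]
    bad = gamma.flagged[:, sel]
    frac = float(bad.mean())
    if frac > MAX_FLAGGED_FRACTION:
        raise RuntimeError(
            f"{frac:.1%} of (f,t) points are numerically singular "
            f"(limit {MAX_FLAGGED_FRACTION:.0%})"
        )
    if np.any(bad.all(axis=1)):
        raise RuntimeError("a time point has every frequency bin flagged")
    if frac == 0.0:
        theta2 = g.mean(axis=1)
    else:
        w = (~bad).astype(float)[:, :, None, None]
        theta2 = np.nansum(np.where(np.isnan(g), 0.0, g) * w, axis=1) / w.sum(axis=1)
    return BandADTF(theta2=theta2, f1=float(f1), f2=float(f2),
                    times_ms=gamma.times_ms, channel_labels=gamma.channel_labels,
                    flagged_fraction=frac)


def segment_average(band_list) -> BandADTF:
    """Element-wise mean of per-segment band-integrated influence."""
    band_list = list(band_list)
    if not band_list:
        raise ValueError("empty segment list")
    ref = band_list[0]
    for b in band_list[1:]:
        if (b.f1, b.f2) != (ref.f1, ref.f2) or b.channel_labels != ref.channel_labels \
                or b.times_ms.shape != ref.times_ms.shape \
                or not np.allclose(b.times_ms, ref.times_ms):
            raise ValueError("segment grids do not match")
    theta2 = np.mean([b.theta2 for b in band_list], axis=0)
    frac = float(np.mean([b.flagged_fraction for b in band_list]))
    return BandADTF(theta2=theta2, f1=ref.f1, f2=ref.f2, times_ms=ref.times_ms,
                    channel_labels=ref.channel_labels, flagged_fraction=frac)


def baseline_stats(band: BandADTF, window_ms: tuple = (-360.0, -40.0),
                   expected_points: int = BASELINE_GRID[1]) -> BaselineMatrix:
    """Time-average the influence over the pre-stimulus baseline window.

    The default contract is exactly 40 baseline time points; any other
    count signals a grid-construction bug and raises.
    """
    sel = (band.times_ms >= window_ms[0] - 1e-9) & (band.times_ms <= window_ms[1] + 1e-9)
    n_pts = int(sel.sum())
    if expected_points is not None and n_pts != expected_points:
        raise ValueError(
            f"baseline window {window_ms} ms holds {n_pts} grid points, "
            f"expected {expected_points}"
        )
    return BaselineMatrix(mean_theta2=band.theta2[sel].mean(axis=0),
                          window_ms=tuple(window_ms), n_timepoints=n_pts,
                          channel_labels=band.channel_labels)


def baseline_correct(band: BandADTF, base: BaselineMatrix) -> CorrectedTensor:
    """Subtract the baseline matrix from every time point.

    Values lie in [-1, 1]; negative entries mark influence weaker than
    the pre-stimulus baseline.
    """
    if band.channel_labels != base.channel_labels:
        raise ValueError("channel sets of band and baseline do not match")
    return CorrectedTensor(values=band.theta2 - base.mean_theta2,
                           times_ms=band.times_ms,
                           channel_labels=band.channel_labels,
                           band=(band.f1, band.f2))


def band_adtf_from_coeffs(coeffs: np.ndarray, dt: float, times_ms: np.ndarray,
                          freqs: np.ndarray, f1: float, f2: float,
                          channel_labels: tuple) -> BandADTF:
    """Coefficients -> band-integrated influence in one pass (per segment).

    Composes the transfer, normalization and band-integration steps
    without retaining the full (T, F, n, n) spectral tensors beyond one
    segment at a time.
    """
    h, flagged = _transfer_from_coeffs(coeffs, dt, freqs)
    transfer = SpectralTransfer(H=h, freqs=freqs, times_ms=times_ms,
                                flagged=flagged, channel_labels=channel_labels)
    return band_integrate(adtf_normalized(transfer), f1, f2)
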