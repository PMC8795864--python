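"""Time-varying MVAR estimation: SBC order selection and Kalman tracking.

The signal model is a vector autoregression with time-varying
coefficients,

    X(t) = sum_{i=1..P} A(i, t) X(t - i) + E(t),

estimated per segment by a Kalman filter in which the stacked
coefficients form a random-walk state. The model order P is selected
once per subject with the Schwarz Bayesian criterion on a pooled
stationary least-squares fit, so every segment shares one coefficient
dimensionality.

Kalman conventions (the adaptive-filter classics): random-walk state
transition; process noise q(t) = uc * trace(S(t)) / dim, isotropic, with
``uc`` the dimensionless update constant; initial coefficients zero;
initial state covariance identity; forward filtering only, preserving
the causality of the evoked response. With a shared regressor across
output channels, a scalar observation-noise proxy (the mean innovation
variance) and an isotropic initial covariance, the coefficient rows of
all channels share one regressor covariance matrix; the implementation
exploits this to propagate a single (P*n x P*n) covariance per segment
instead of the full (P*n^2)^2 state covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class OrderSelection:
    """SBC scores over candidate model orders and the selected argmin."""

    candidate_orders: list
    sbc_scores: np.ndarray
    selected: int

    def __post_init__(self):
        if self.selected not in self.candidate_orders:
            raise ValueError("selected order not among candidates")
        if not np.all(np.isfinite(self.sbc_scores)):
            raise ValueError("SBC scores must be finite")


@dataclass
class TVMVARModel:
    """Kalman-tracked coefficient trajectory for one segment.

    ``coeffs[t, k]`` is the estimate of A(k+1, t); samples before the
    first ``order`` lags are unestimated (``estimated`` False, NaN
    coefficients). ``innovation_cov[t]`` is the running EWMA estimate of
    cov(E(t)).
    """

    coeffs: np.ndarray          # (T, P, n, n)
    innovation_cov: np.ndarray  # (T, n, n)
    estimated: np.ndarray       # (T,) bool
    order: int
    uc: float
    dt: float
    channel_labels: tuple
    t0_index: int = 0

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[2]

    @property
    def n_samples(self) -> int:
        return self.coeffs.shape[0]


def _lag_design(data: np.ndarray, order: int):
    """Pooled lagged design (rows: all segments, t >= order)."""
    n_seg, n, n_t = data.shape
    if n_t <= order:
        raise ValueError("segment shorter than model order")
    y = data[:, :, order:].transpose(0, 2, 1).reshape(-1, n)
    cols = [data[:, :, order - k : n_t - k].transpose(0, 2, 1).reshape(-1, n)
            for k in range(1, order + 1)]
    z = np.concatenate(cols, axis=1)
    return z, y


def select_order_sbc(epochs: EpochSet, p_max: int) -> OrderSelection:
    """Select the MVAR order by the Schwarz Bayesian criterion.

    For each candidate P a stationary MVAR is fitted by least squares on
    the pooled segments and scored as

        SBC(P) = ln det(Sigma_res) + (ln N / N) * P * n^2,

    with N = (segment length - P) * n_segments effective samples.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    n = epochs.n_channels
    if epochs.n_samples <= p_max * n:
        raise ValueError("segments too short for requested p_max")
    candidates = list(range(1, p_max + 1))
    scores = np.empty(len(candidates))
    # one pooled design at p_max; order p uses its first p*n regressor
    # columns, so every candidate is scored on the same sample base
    z, y = _lag_design(epochs.data, p_max)
    n_obs = y.shape[0]
    gram = z.T @ z
    cross = z.T @ y
    yy = y.T @ y
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"singular regression (Gram condition {cond:.3g}); "
            "constant or duplicated channels?"
        )
    for i, p in enumerate(candidates):
        m = p * n
        b = np.linalg.solve(gram[:m, :m], cross[:m])
        sigma = (yy - cross[:m].T @ b) / n_obs
        sigma = 0.5 * (sigma + sigma.T)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0 or not np.isfinite(logdet):
            raise ValueError(f"singular residual covariance at order {p}")
        scores[i] = logdet + np.log(n_obs) / n_obs * p * n * n
    selected = candidates[int(np.argmin(scores))]
    logger.info("select_order_sbc: selected P=%d from %s", selected, candidates)
    return OrderSelection(candidate_orders=candidates, sbc_scores=scores, selected=selected)


def ols_mvar(epochs: EpochSet, order: int) -> np.ndarray:
    """Stationary least-squares MVAR fit; returns (order, n, n) coefficients.

    The stationary reference the Kalman estimates converge to on
    stationary data as ``uc`` shrinks, and the warm start the pipeline
    hands to the per-segment filters.
    """
    n = epochs.n_channels
    z, y = _lag_design(epochs.data, order)
    b, *_ = np.linalg.lstsq(z, y, rcond=None)
    return b.T.reshape(n, order, n).transpose(1, 0, 2)


def _kalman_batch(
    data: np.ndarray,
    order: int,
    uc: float,
    keep: np.ndarray,
    store_innovation: bool = True,
    coeffs_init: np.ndarray | None = None,
):
    """Forward Kalman pass over a batch of segments.

    ``data``: (S, n, T); ``keep``: sorted sample indices (all >= order)
    at which coefficient estimates are stored; ``coeffs_init``: optional
    (order, n, n) warm start shared by all segments. Returns
    (coeffs (S, K, order, n, n), innov (S, K, n, n) or None).
    """
    n_seg, n, n_t = data.shape
    pn = order * n
    eye_pn = np.eye(pn)
    if coeffs_init is None:
        coef = np.zeros((n_seg, n, pn))
    else:
        c0 = np.asarray(coeffs_init)
        if c0.shape != (order, n, n):
            raise ValueError("coeffs_init must have shape (order, n, n)")
        coef = np.tile(c0.transpose(1, 0, 2).reshape(n, pn), (n_seg, 1, 1))
    cov = np.tile(eye_pn, (n_seg, 1, 1))
    r_est = np.tile(np.eye(n), (n_seg, 1, 1))
    keep = np.asarray(keep)
    keep_pos = np.full(n_t, -1, dtype=int)
    keep_pos[keep] = np.arange(keep.size)
    out = np.zeros((n_seg, keep.size, order, n, n))
    innov = np.zeros((n_seg, keep.size, n, n)) if store_innovation else None
    for t in range(order, n_t):
        z = np.concatenate([data[:, :, t - k] for k in range(1, order + 1)], axis=1)
        q = uc * np.trace(cov, axis1=1, axis2=2) / pn
        cov = cov + q[:, None, None] * eye_pn
        sz = (cov @ z[:, :, None])[:, :, 0]
        denom = np.einsum("sp,sp->s", z, sz) + np.trace(r_est, axis1=1, axis2=2) / n
        err = data[:, :, t] - np.einsum("sip,sp->si", coef, z)
        if not np.all(np.isfinite(err)):
            bad = int(np.flatnonzero(~np.isfinite(err).all(axis=1))[0])
            raise FloatingPointError(
                f"Kalman state non-finite at sample {t} (segment {bad})"
            )
        gain = sz / denom[:, None]
        coef = coef + err[:, :, None] * gain[:, None, :]
        cov = cov - sz[:, :, None] * sz[:, None, :] / denom[:, None, None]
        cov = 0.5 * (cov + cov.transpose(0, 2, 1))
        r_est = (1 - uc) * r_est + uc * err[:, :, None] * err[:, None, :]
        pos = keep_pos[t]
        if pos >= 0:
            out[:, pos] = coef.reshape(n_seg, n, order, n).transpose(0, 2, 1, 3)
            if store_innovation:
                innov[:, pos] = r_est
    return out, innov


def kalman_fit(segment: EpochSet, order: int, uc: float = 1e-3,
               coeffs_init: np.ndarray | None = None) -> TVMVARModel:
    """Kalman-filter coefficient tracking for a single segment.

    ``segment`` must hold exactly one segment; ``uc`` in (0, 1) sets the
    random-walk process-noise scale (default 1e-3). ``coeffs_init``
    optionally warm-starts the state (e.g. at a pooled stationary fit);
    the default start is zero coefficients.
    """
    if segment.n_segments != 1:
        raise ValueError("kalman_fit expects a single-segment EpochSet")
    if not 0 < uc < 1:
        raise ValueError("uc must lie in (0, 1)")
    n_t = segment.n_samples
    if n_t <= order:
        raise ValueError("segment shorter than model order")
    keep = np.arange(order, n_t)
    coeffs_k, innov_k = _kalman_batch(segment.data, order, uc, keep,
                                      coeffs_init=coeffs_init)
    n = segment.n_channels
    coeffs = np.full((n_t, order, n, n), np.nan)
    innov = np.full((n_t, n, n), np.nan)
    coeffs[order:] = coeffs_k[0]
    innov[order:] = innov_k[0]
    estimated = np.zeros(n_t, dtype=bool)
    estimated[order:] = True
    return TVMVARModel(
        coeffs=coeffs,
        innovation_cov=innov,
        estimated=estimated,
        order=order,
        uc=uc,
        dt=segment.dt,
        channel_labels=segment.channel_labels,
        t0_index=segment.t0_index,
    )


def kalman_fit_epochs(
    epochs: EpochSet,
    order: int,
    uc: float = 1e-3,
    keep: np.ndarray | None = None,
    chunk_size: int = 16,
    coeffs_init: np.ndarray | None = None,
):
    """Kalman-track every segment, yielding (segment_index, coeffs).

    ``coeffs`` has shape (K, order, n, n) with K = len(keep) (default:
    every estimable sample). Segments are filtered in batches for speed
    but each segment's filter is independent, matching the per-segment
    estimation convention. ``coeffs_init`` warm-starts every segment at
    the same coefficients (the pipeline passes the subject's pooled OLS
    fit so that short pre-stimulus windows are not dominated by the
    filter's convergence transient).
    """
    if not 0 < uc < 1:
        raise ValueError("uc must lie in (0, 1)")
    if keep is None:
        keep = np.arange(order, epochs.n_samples)
    keep = np.asarray(keep, dtype=int)
    if keep.size and (keep.min() < order or keep.max() >= epochs.n_samples):
        raise ValueError("keep indices must lie in [order, n_samples)")
    for lo in range(0, epochs.n_segments, chunk_size):
        batch = epochs.data[lo : lo + chunk_size]
        coeffs_k, _ = _kalman_batch(batch, order, uc, keep,
                                    store_innovation=False,
                                    coeffs_init=coeffs_init)
        for s in range(batch.shape[0]):
            yield lo + s, coeffs_k[s]


def kalman_fit_ensemble(
    epochs: EpochSet,
    order: int,
    uc: float = 1e-3,
    keep: np.ndarray | None = None,
    coeffs_init: np.ndarray | None = None,
) -> np.ndarray:
    """Multi-trial (ensemble) Kalman coefficient tracking.

    One shared coefficient state is updated at every time step with the
    measurements of *all* segments simultaneously (an exact
    multi-measurement Kalman update via the matrix inversion lemma).
    With ~100 stimulus-locked trials per step the state is converged
    within a few samples yet still tracks post-stimulus coefficient
    changes, which per-segment filtering cannot achieve for
    high-dimensional states on short pre-stimulus windows — the standard
    approach for event-locked multi-trial recordings.

    Returns the shared coefficient trajectory, shape (K, order, n, n).
    """
    if not 0 < uc < 1:
        raise ValueError("uc must lie in (0, 1)")
    data = epochs.data
    n_seg, n, n_t = data.shape
    if keep is None:
        keep = np.arange(order, n_t)
    keep = np.asarray(keep, dtype=int)
    if keep.size and (keep.min() < order or keep.max() >= n_t):
        raise ValueError("keep indices must lie in [order, n_samples)")
    pn = order * n
    eye_pn = np.eye(pn)
    eye_s = np.eye(n_seg)
    if coeffs_init is None:
        coef = np.zeros((n, pn))
    else:
        coef = np.asarray(coeffs_init).transpose(1, 0, 2).reshape(n, pn).copy()
    cov = eye_pn.copy()
    r_est = np.eye(n)
    keep_pos = np.full(n_t, -1, dtype=int)
    keep_pos[keep] = np.arange(keep.size)
    out = np.zeros((keep.size, order, n, n))
    for t in range(order, n_t):
        z = np.concatenate([data[:, :, t - k] for k in range(1, order + 1)], axis=1)
        cov = cov + (uc * np.trace(cov) / pn) * eye_pn
        g = cov @ z.T                                  # (pn, S)
        r = np.trace(r_est) / n
        m = z @ g + r * eye_s
        gain = np.linalg.solve(m.T, g.T).T             # cov Z' (Z cov Z' + rI)^-1
        err = data[:, :, t] - z @ coef.T               # (S, n)
        if not np.all(np.isfinite(err)):
            raise FloatingPointError(f"ensemble Kalman state non-finite at sample {t}")
        coef = coef + (gain @ err).T
        cov = cov - gain @ g.T
        cov = 0.5 * (cov + cov.T)
        mean_ee = err.T @ err / n_seg
        r_est = (1 - uc) * r_est + uc * mean_ee
        pos = keep_pos[t]
        if pos >= 0:
            out[pos] = coef.reshape(n, order, n).transpose(1, 0, 2)
    return out
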