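"""Per-subject and group orchestration of the full analysis chain.

One subject run is: band-pass -> decimate -> epoch -> reject ->
SBC order selection -> per-segment Kalman coefficient tracking ->
spectral transfer -> normalized directed influence -> band integration ->
segment averaging -> baseline statistics -> baseline correction ->
weakened-network thresholding. Every parameter, count and default is
recorded in a manifest so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from . import adtf as _adtf
from . import network as _network
from . import preprocess as _pre
from . import tvmvar as _tvmvar
from .preprocess import EpochSet, RawRecording
from .synthetic import SyntheticSession

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All analysis parameters with their standard defaults.

    Time grids are (start_ms, n_points) pairs stepping one analysis
    sample: 40 baseline points from -360 ms, 246 post-stimulus points
    from +60 ms.
    """

    band: tuple = (3.0, 30.0)
    freq_step: float = 1.0
    decim_factor: int = 8
    epoch_window_ms: tuple = (-1000.0, 2000.0)
    baseline_start_ms: float = _adtf.BASELINE_GRID[0]
    baseline_points: int = _adtf.BASELINE_GRID[1]
    baseline_window_ms: tuple = (-360.0, -40.0)
    post_start_ms: float = _adtf.POST_GRID[0]
    post_points: int = _adtf.POST_GRID[1]
    order: int | str = "auto"
    p_max: int = 5
    uc: float = 1e-3
    estimation: str = "ensemble"   # "ensemble" | "per_segment"
    fraction: float = 0.10
    snapshot_times_ms: tuple = (119.0, 212.0, 415.0)
    amp_threshold: float = 120.0
    z_threshold: float = 5.0
    max_segments: int | None = 100
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self):
        f1, f2 = self.band
        if not 0 < f1 < f2:
            raise ValueError("band must satisfy 0 < f1 < f2")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        if not 0 < self.uc < 1:
            raise ValueError("uc must lie in (0, 1)")
        if self.order != "auto" and int(self.order) < 1:
            raise ValueError("order must be 'auto' or a positive integer")
        if self.estimation not in ("ensemble", "per_segment"):
            raise ValueError("estimation must be 'ensemble' or 'per_segment'")
        if self.baseline_window_ms[0] >= self.baseline_window_ms[1]:
            raise ValueError("baseline window must be increasing")
        if self.baseline_window_ms[1] > self.post_start_ms:
            raise ValueError("baseline window must end before the post window begins")
        if self.baseline_start_ms < self.baseline_window_ms[0] - 1e-9:
            raise ValueError("baseline grid starts before the baseline window")
        if not (self.epoch_window_ms[0] < 0 < self.epoch_window_ms[1]):
            raise ValueError("epoch window must straddle the stimulus")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("band", "epoch_window_ms", "baseline_window_ms", "snapshot_times_ms"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class SubjectResult:
    """Everything the per-subject analysis produces."""

    baseline_band: _adtf.BandADTF
    post_band: _adtf.BandADTF
    baseline_matrix: _adtf.BaselineMatrix
    corrected: _adtf.CorrectedTensor
    snapshots: list                      # every post-grid time point
    report_snapshots: dict               # requested time -> snapshot
    order_selection: _tvmvar.OrderSelection | None
    manifest: dict


@dataclass
class GroupResult:
    per_subject: dict     # group label -> list of SubjectResult
    group_corrected: dict  # group label -> CorrectedTensor
    group_networks: dict   # group label -> GroupNetwork


def _as_recording(session) -> RawRecording:
    if isinstance(session, SyntheticSession):
        return session.recording
    if isinstance(session, RawRecording):
        return session
    raise TypeError(f"cannot analyse object of type {type(session).__name__}")


def preprocess_session(config: PipelineConfig, session) -> EpochSet:
    """Standard preprocessing chain for one session."""
    rec = _as_recording(session)
    rec = _pre.bandpass(rec, *config.band)
    rec = _pre.decimate(rec, config.decim_factor)
    epochs = _pre.epoch(rec, *config.epoch_window_ms)
    return _pre.reject_segments(
        epochs,
        amp_threshold=config.amp_threshold,
        z_threshold=config.z_threshold,
        max_segments=config.max_segments,
    )


def run_subject(config: PipelineConfig, session) -> SubjectResult:
    """Full per-subject analysis; see module docstring for the stages."""
    stage = "preprocess"
    try:
        rec = _as_recording(session)
        n_events = len(rec.events)
        epochs = preprocess_session(config, session)

        stage = "order selection"
        if config.order == "auto":
            selection = _tvmvar.select_order_sbc(epochs, config.p_max)
            order = selection.selected
        else:
            selection = None
            order = int(config.order)

        stage = "grid construction"
        fs = epochs.fs
        base_grid = _adtf.make_time_grid(epochs.t0_index, fs, config.baseline_start_ms,
                                         config.baseline_points, epochs.n_samples)
        post_grid = _adtf.make_time_grid(epochs.t0_index, fs, config.post_start_ms,
                                         config.post_points, epochs.n_samples)
        if base_grid.indices[0] < order:
            raise ValueError("baseline grid begins before the first estimable sample")
        keep = np.concatenate([base_grid.indices, post_grid.indices])
        times_ms = np.concatenate([base_grid.times_ms, post_grid.times_ms])
        freqs = _adtf.band_frequencies(*config.band, step=config.freq_step)

        stage = "Kalman tracking / ADTF"
        n_base = base_grid.n_points
        if config.estimation == "ensemble":
            # one shared coefficient trajectory assimilating all
            # segments at each time step (multi-trial Kalman); the
            # band-integrated influence needs no segment averaging
            coeffs = _tvmvar.kalman_fit_ensemble(epochs, order, config.uc, keep=keep)
            band_all = _adtf.band_adtf_from_coeffs(
                coeffs, epochs.dt, times_ms, freqs, *config.band,
                channel_labels=epochs.channel_labels,
            )
            mean_theta2 = band_all.theta2
            flagged = [band_all.flagged_fraction]
        else:
            # per-segment filtering, warm-started at the subject's pooled
            # stationary fit so short pre-stimulus windows are not
            # dominated by the convergence transient; the per-segment
            # band influences are then averaged
            warm = _tvmvar.ols_mvar(epochs, order)
            sum_theta2 = None
            flagged = []
            for _, coeffs in _tvmvar.kalman_fit_epochs(epochs, order, config.uc,
                                                       keep=keep, coeffs_init=warm):
                band_seg = _adtf.band_adtf_from_coeffs(
                    coeffs, epochs.dt, times_ms, freqs, *config.band,
                    channel_labels=epochs.channel_labels,
                )
                flagged.append(band_seg.flagged_fraction)
                sum_theta2 = band_seg.theta2 if sum_theta2 is None else sum_theta2 + band_seg.theta2
            mean_theta2 = sum_theta2 / epochs.n_segments
        baseline_band = _adtf.BandADTF(
            theta2=mean_theta2[:n_base], f1=config.band[0], f2=config.band[1],
            times_ms=base_grid.times_ms, channel_labels=epochs.channel_labels,
            flagged_fraction=float(np.mean(flagged)),
        )
        post_band = _adtf.BandADTF(
            theta2=mean_theta2[n_base:], f1=config.band[0], f2=config.band[1],
            times_ms=post_grid.times_ms, channel_labels=epochs.channel_labels,
            flagged_fraction=float(np.mean(flagged)),
        )

        stage = "baseline correction"
        baseline_matrix = _adtf.baseline_stats(
            baseline_band, window_ms=config.baseline_window_ms,
            expected_points=config.baseline_points,
        )
        corrected = _adtf.baseline_correct(post_band, baseline_matrix)

        stage = "network thresholding"
        snapshots = _network.threshold_weakened(corrected, config.fraction)
        report = {float(t): _network.snapshot_at(snapshots, t)
                  for t in config.snapshot_times_ms}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "tvnet_version": __version__,
        "config": config.to_dict(),
        "n_events": int(n_events),
        "n_segments_retained": int(epochs.n_segments),
        "selected_order": int(order),
        "estimation": config.estimation,
        "sbc_scores": None if selection is None else [float(s) for s in selection.sbc_scores],
        "uc": config.uc,
        "fs_analysis_hz": float(fs),
        "n_baseline_points": int(base_grid.n_points),
        "n_post_points": int(post_grid.n_points),
        "baseline_times_ms": [float(t) for t in base_grid.times_ms],
        "post_first_ms": float(post_grid.times_ms[0]),
        "post_last_ms": float(post_grid.times_ms[-1]),
        "flagged_fraction": float(np.mean(flagged)),
        "snapshot_times_ms": [float(t) for t in config.snapshot_times_ms],
        "channel_labels": list(epochs.channel_labels),
    }
    return SubjectResult(
        baseline_band=baseline_band,
        post_band=post_band,
        baseline_matrix=baseline_matrix,
        corrected=corrected,
        snapshots=snapshots,
        report_snapshots=report,
        order_selection=selection,
        manifest=manifest,
    )


def run_group(config: PipelineConfig, sessions: dict) -> GroupResult:
    """Per-subject runs plus group-averaged weakened networks.

    ``sessions`` maps a group label to a non-empty list of sessions.
    Group networks are thresholded from the grand-average of subject
    corrected tensors (averaging before thresholding).
    """
    per_subject = {}
    group_corrected = {}
    group_networks = {}
    for label, group_sessions in sessions.items():
        if not group_sessions:
            raise ValueError(f"group {label!r} is empty")
        results = [run_subject(config, s) for s in group_sessions]
        per_subject[label] = results
        avg = _network.group_average([r.corrected for r in results])
        group_corrected[label] = avg
        snaps = _network.threshold_weakened(avg, config.fraction)
        group_networks[label] = _network.GroupNetwork(
            label=label,
            snapshots={float(t): _network.snapshot_at(snaps, t)
                       for t in config.snapshot_times_ms},
            n_subjects=len(results),
        )
    return GroupResult(per_subject=per_subject,
                       group_corrected=group_corrected,
                       group_networks=group_networks)
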