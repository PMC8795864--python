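"""Session and result containers: HDF5, TSV events, EDF reading.

The HDF5 session container layout:

    /signal          float64 (n_channels, n_samples), microvolt-scaled
    /events          int64 stimulus sample indices
    attrs: fs, channel_labels (list of str), seed, profile,
           truth_json (ground-truth schedule, JSON) when synthetic

Result containers hold the band-integrated and corrected tensors with
their time/frequency axes as attributes, so any stage can be re-run or
inspected independently.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .preprocess import RawRecording
from .synthetic import (GroundTruthSchedule, SchedulePhase, SyntheticSession)


def _truth_to_json(truth: GroundTruthSchedule) -> str:
    return json.dumps({
        "n_channels": truth.n_channels,
        "order": truth.order,
        "noise_scale": truth.noise_scale,
        "channel_labels": list(truth.channel_labels),
        "window_ms": list(truth.window_ms),
        "phases": [
            {"t_start_ms": ph.t_start_ms, "t_end_ms": ph.t_end_ms,
             "coeffs": ph.coeffs.tolist()}
            for ph in truth.phases
        ],
    })


def _truth_from_json(text: str) -> GroundTruthSchedule:
    d = json.loads(text)
    return GroundTruthSchedule(
        n_channels=d["n_channels"],
        order=d["order"],
        phases=[SchedulePhase(p["t_start_ms"], p["t_end_ms"], np.array(p["coeffs"]))
                for p in d["phases"]],
        noise_scale=d["noise_scale"],
        channel_labels=tuple(d["channel_labels"]),
        window_ms=tuple(d["window_ms"]),
    )


def save_session(session: SyntheticSession | RawRecording, path) -> None:
    """Write a session (or bare recording) to the HDF5 container."""
    rec = session.recording if isinstance(session, SyntheticSession) else session
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("events", data=rec.events)
        f.attrs["fs"] = rec.fs
        f.attrs["channel_labels"] = list(rec.channel_labels)
        if isinstance(session, SyntheticSession):
            f.attrs["seed"] = session.seed
            f.attrs["profile"] = session.profile or ""
            f.attrs["truth_json"] = _truth_to_json(session.truth)


def load_session(path) -> SyntheticSession | RawRecording:
    """Read a session container; returns a SyntheticSession when ground
    truth is embedded, otherwise a plain RawRecording."""
    with h5py.File(path, "r") as f:
        rec = RawRecording(
            signal=f["signal"][()],
            fs=float(f.attrs["fs"]),
            channel_labels=[str(c) for c in f.attrs["channel_labels"]],
            events=f["events"][()],
        )
        if "truth_json" in f.attrs:
            return SyntheticSession(
                recording=rec,
                truth=_truth_from_json(f.attrs["truth_json"]),
                seed=int(f.attrs.get("seed", 0)),
                profile=str(f.attrs.get("profile", "")) or None,
            )
    return rec


def save_events_tsv(events: np.ndarray, path, label: str = "tms_pulse") -> None:
    pd.DataFrame({"sample_index": np.asarray(events, dtype=int),
                  "label": label}).to_csv(path, sep="\t", index=False)


def load_events_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["sample_index"].to_numpy(dtype=np.int64)


def load_raw_edf(path, stim_annotation: str | None = None) -> RawRecording:
    """Read a continuous EDF recording (via mne) into a RawRecording.

    Events are taken from the embedded annotations (optionally filtered
    by description); pass events separately via ``load_events_tsv`` when
    the EDF carries none.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    onsets = raw.annotations.onset
    if stim_annotation is not None:
        onsets = onsets[np.asarray(raw.annotations.description) == stim_annotation]
    events = np.round(np.sort(onsets) * raw.info["sfreq"]).astype(np.int64)
    return RawRecording(
        signal=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        events=events,
    )


def save_subject_result(result, path) -> None:
    """Persist a subject bundle (tensors + manifest) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("theta2_post", data=result.post_band.theta2)
        f.create_dataset("theta2_baseline", data=result.baseline_band.theta2)
        f.create_dataset("baseline_matrix", data=result.baseline_matrix.mean_theta2)
        f.create_dataset("corrected", data=result.corrected.values)
        f.create_dataset("times_post_ms", data=result.post_band.times_ms)
        f.create_dataset("times_baseline_ms", data=result.baseline_band.times_ms)
        f.attrs["band"] = [result.post_band.f1, result.post_band.f2]
        f.attrs["channel_labels"] = list(result.post_band.channel_labels)
        f.attrs["manifest_json"] = json.dumps(result.manifest)
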