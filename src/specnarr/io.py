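"""On-disk containers: HDF5 signal/epoch stores plus CSV tables.

The signal container has one float dataset per subject (sites x samples)
under ``/signals`` with a ``sampling_rate`` attribute; site and event tables
travel as CSV so every artifact except the raw samples is plain text.
"""
from __future__ import annotations

from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .preprocess import EpochSet
from .schedule import StimulusEvent, events_to_frame, frame_to_events
from .simulate import GroundTruth, Recording
from .spectral import FREQ_GRID, PSDMatrix

__all__ = [
    "save_recording",
    "load_recording",
    "save_events",
    "load_events",
    "save_epochs",
    "load_epochs",
    "save_psd_matrix",
    "load_psd_matrix",
]


def save_recording(
    recording: Recording,
    out_dir: str | Path,
    ground_truth: GroundTruth | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "recording.h5", "w") as f:
        f.attrs["sampling_rate"] = recording.sampling_rate
        grp = f.create_group("signals")
        for subject, sig in recording.signals.items():
            grp.create_dataset(subject, data=sig)
    recording.sites.to_csv(out / "sites.csv", index=False)
    if ground_truth is not None:
        ground_truth.gains.to_csv(out / "ground_truth_gains.csv", index=False)
        ground_truth.edges.to_csv(out / "ground_truth_edges.csv", index=False)


def load_recording(out_dir: str | Path) -> Recording:
    out = Path(out_dir)
    sites = pd.read_csv(out / "sites.csv")
    sites["excluded"] = sites["excluded"].astype(bool)
    with h5py.File(out / "recording.h5", "r") as f:
        fs = float(f.attrs["sampling_rate"])
        signals = {name: ds[()] for name, ds in f["signals"].items()}
    return Recording(signals, sites, fs)


def save_events(events: Sequence[StimulusEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def load_events(path: str | Path) -> list[StimulusEvent]:
    return frame_to_events(pd.read_csv(path))


def save_epochs(epochs: EpochSet, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with h5py.File(out / "epochs.h5", "w") as f:
        f.attrs["sampling_rate"] = epochs.sampling_rate
        f.attrs["window_lo_ms"] = epochs.window_ms[0]
        f.attrs["window_hi_ms"] = epochs.window_ms[1]
        f.create_dataset("samples", data=np.asarray(epochs.samples, dtype=np.float32))
    epochs.meta.to_csv(out / "epoch_meta.csv", index=False)


def load_epochs(out_dir: str | Path) -> EpochSet:
    out = Path(out_dir)
    meta = pd.read_csv(out / "epoch_meta.csv")
    with h5py.File(out / "epochs.h5", "r") as f:
        samples = f["samples"][()]
        fs = float(f.attrs["sampling_rate"])
        window = (float(f.attrs["window_lo_ms"]), float(f.attrs["window_hi_ms"]))
    return EpochSet(samples, meta, window, fs)


def save_psd_matrix(psds: PSDMatrix, path: str | Path) -> None:
    value_cols = pd.DataFrame(psds.values, columns=[f"f{int(f)}" for f in psds.grid])
    pd.concat([psds.meta.reset_index(drop=True), value_cols], axis=1).to_csv(
        path, index=False
    )


def load_psd_matrix(path: str | Path) -> PSDMatrix:
    df = pd.read_csv(path)
    value_cols = [f"f{int(f)}" for f in FREQ_GRID]
    values = df[value_cols].to_numpy()
    meta = df.drop(columns=value_cols)
    return PSDMatrix(values, meta)
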