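"""Re-referencing, site exclusion and peri-transition epoching.

Signals are re-referenced per subject to the common average over included
sites.  Epochs cover [-100, +500) ms around image onsets (600 samples at
1 kHz) with onset at sample 100; the default trial universe is the
within-series image-to-image transitions (28 per condition), with the
series-initial transitions available as separate classes for the
first-versus-rest habituation analysis, and gray-screen onsets available as
ISI controls.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .schedule import StimulusEvent
from .simulate import Recording

__all__ = [
    "DEFAULT_WINDOW_MS",
    "EpochSet",
    "common_average_reference",
    "exclude_sites",
    "epoch_transitions",
    "baseline_correct",
    "baseline_correct_epochs",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOW_MS = (-100.0, 500.0)
DEFAULT_CLASSES = frozenset({"image_to_image"})


@dataclass
class EpochSet:
    """Peri-transition epochs: one row per (site, event), metadata aligned."""

    samples: np.ndarray  # (n_rows, n_samples)
    meta: pd.DataFrame
    window_ms: tuple[float, float]
    sampling_rate: float

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.meta):
            raise ValueError("samples and metadata are misaligned")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def select(self, mask: np.ndarray | pd.Series) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            self.samples[mask],
            self.meta.loc[mask].reset_index(drop=True),
            self.window_ms,
            self.sampling_rate,
        )


def common_average_reference(recording: Recording) -> Recording:
    """Subtract, per subject and per sample, the mean over included sites.

    Excluded sites neither contribute to the reference nor are modified.
    """
    out = recording.copy()
    for subject in out.subjects:
        sub = out.subject_sites(subject)
        included = (~sub["excluded"]).to_numpy()
        if included.sum() < 2:
            raise ValueError(
                f"subject {subject!r} has {int(included.sum())} included site(s); "
                "a common average reference needs at least 2"
            )
        sig = out.signals[subject]
        ref = sig[included].mean(axis=0)
        sig[included] -= ref
    return out


def exclude_sites(
    recording: Recording, site_ids: Iterable[tuple[str, str]]
) -> Recording:
    """Flag (subject_id, site_id) pairs as excluded from all downstream stages."""
    ids = list(site_ids)
    out = recording.copy()
    known = set(zip(out.sites["subject_id"], out.sites["site_id"]))
    for pair in ids:
        if tuple(pair) not in known:
            raise KeyError(f"unknown site {pair!r}")
    flag = set(map(tuple, ids))
    newly = [
        (s, c) in flag for s, c in zip(out.sites["subject_id"], out.sites["site_id"])
    ]
    out.sites.loc[newly, "excluded"] = True
    n_kept = int((~out.sites["excluded"]).sum())
    if n_kept == 0:
        raise ValueError("exclusion would leave zero analyzable sites")
    log.info(
        "excluded %d sites; %d of %d remain in analysis",
        int(out.sites["excluded"].sum()), n_kept, len(out.sites),
    )
    return out


def epoch_transitions(
    recording: Recording,
    events: Sequence[StimulusEvent],
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    classes: Iterable[str] = DEFAULT_CLASSES,
) -> EpochSet:
    """Cut one epoch per selected event per included site.

    ``classes`` selects transition classes; gray-screen onsets are epoched
    when ``image_to_isi`` is requested.
    """
    classes = frozenset(classes)
    fs = recording.sampling_rate
    lo, hi = window_ms
    n_win = int(round((hi - lo) * fs / 1000.0))
    selected = [e for e in events if e.transition_class in classes]
    rows: list[pd.DataFrame] = []
    chunks: list[np.ndarray] = []
    for subject in recording.subjects:
        sub = recording.subject_sites(subject)
        keep = (~sub["excluded"]).to_numpy()
        sub = sub.loc[keep].reset_index(drop=True)
        if len(sub) == 0:
            continue
        sig = recording.signals[subject][keep]
        n_total = sig.shape[1]
        starts = []
        for e in selected:
            a = int(round((e.onset_ms + lo) * fs / 1000.0))
            if a < 0 or a + n_win > n_total:
                raise ValueError(
                    f"event at {e.onset_ms} ms ({e.transition_class}) falls within "
                    f"{window_ms} ms of the recording edge for subject {subject!r}"
                )
            starts.append(a)
        if not starts:
            continue
        idx = np.asarray(starts)[:, None] + np.arange(n_win)[None, :]
        cut = sig[:, idx]  # (n_sites, n_events, n_win)
        chunks.append(cut.reshape(-1, n_win))
        meta = pd.DataFrame(
            {
                "subject_id": np.repeat(sub["subject_id"].to_numpy(), len(selected)),
                "site_id": np.repeat(sub["site_id"].to_numpy(), len(selected)),
                "region": np.repeat(sub["region"].to_numpy(), len(selected)),
                "hemisphere": np.repeat(sub["hemisphere"].to_numpy(), len(selected)),
                "condition": np.tile([e.condition for e in selected], len(sub)),
                "transition_class": np.tile(
                    [e.transition_class for e in selected], len(sub)
                ),
                "series_index": np.tile(
                    [e.series_index for e in selected], len(sub)
                ),
                "position_in_series": np.tile(
                    [-1 if e.position_in_series is None else e.position_in_series
                     for e in selected],
                    len(sub),
                ),
                "onset_ms": np.tile([e.onset_ms for e in selected], len(sub)),
            }
        )
        rows.append(meta)
    if not chunks:
        return EpochSet(
            np.empty((0, n_win), dtype=np.float32),
            pd.DataFrame(
                columns=[
                    "subject_id", "site_id", "region", "hemisphere", "condition",
                    "transition_class", "series_index", "position_in_series",
                    "onset_ms",
                ]
            ),
            window_ms,
            fs,
        )
    return EpochSet(
        np.concatenate(chunks, axis=0),
        pd.concat(rows, ignore_index=True),
        window_ms,
        fs,
    )


def baseline_correct(
    samples: np.ndarray,
    baseline_ms: tuple[float, float],
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    sampling_rate: float = 1000.0,
) -> np.ndarray:
    """Subtract the mean over ``baseline_ms`` (relative to onset) per epoch.

    Two baselines are in routine use: (-100, 50) ms for time-domain display
    and (-100, 100) ms as the DC-offset correction of the connectivity path.
    """
    samples = np.asarray(samples, dtype=float)
    lo, hi = window_ms
    b0, b1 = baseline_ms
    if b0 < lo or b1 > hi or b1 <= b0:
        raise ValueError(
            f"baseline window {baseline_ms} must be a non-empty sub-interval of "
            f"the epoch window {window_ms}"
        )
    a = int(round((b0 - lo) * sampling_rate / 1000.0))
    b = int(round((b1 - lo) * sampling_rate / 1000.0))
    mean = samples[..., a:b].mean(axis=-1, keepdims=True)
    return samples - mean


def baseline_correct_epochs(
    epochs: EpochSet, baseline_ms: tuple[float, float]
) -> EpochSet:
    corrected = baseline_correct(
        epochs.samples, baseline_ms, epochs.window_ms, epochs.sampling_rate
    )
    return EpochSet(corrected, epochs.meta.copy(), epochs.window_ms, epochs.sampling_rate)
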