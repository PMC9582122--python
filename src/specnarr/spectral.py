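"""Single-trial Welch spectra on the analysis grid and per-site normalization.

Each 600-sample epoch is z-scored and passed to a Welch estimator with a
Hamming taper, segment length floor(600/4.5) = 133 and 50% overlap (the
"eight segments" reading of a 600-sample window), zero-padded to 1000 points
so the spectrum is evaluated at 1 Hz increments.  Analysis is confined to
2-100 Hz with the 56-63 Hz band dropped to avoid line-noise bins, leaving
91 bins.  Per site, every trial spectrum is divided by the mean spectrum over
all of that site's trials (both conditions pooled), so each bin averages to 1
and only relative, trial-specific power modulation survives.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .preprocess import EpochSet
from .schedule import CONDITIONS

__all__ = [
    "FREQ_GRID",
    "N_BINS",
    "PSDMatrix",
    "welch_psd",
    "compute_psds",
    "normalize_psd_set",
    "condition_average",
]

_FULL_GRID = np.arange(2, 101)
_EXCLUDED = np.arange(56, 64)  # closed interval 56..63, 8 line-noise bins
FREQ_GRID = np.setdiff1d(_FULL_GRID, _EXCLUDED)
N_BINS = FREQ_GRID.size  # 91

_EPOCH_SAMPLES = 600
_NPERSEG = _EPOCH_SAMPLES * 2 // 9  # floor(600 / 4.5) = 133
_NOVERLAP = _NPERSEG // 2
_NFFT = 1000

_META_COLS = [
    "subject_id", "site_id", "region", "hemisphere", "condition",
    "transition_class", "series_index", "position_in_series", "onset_ms",
]


@dataclass
class PSDMatrix:
    """Rows of 91-bin spectra with aligned row metadata."""

    values: np.ndarray  # (n_rows, 91)
    meta: pd.DataFrame
    grid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.grid is None:
            self.grid = FREQ_GRID
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.size:
            raise ValueError(
                f"PSD matrix must have {self.grid.size} columns, "
                f"got shape {self.values.shape}"
            )
        if len(self.values) != len(self.meta):
            raise ValueError("values and metadata are misaligned")

    def __len__(self) -> int:
        return len(self.values)

    def select(self, mask) -> "PSDMatrix":
        mask = np.asarray(mask)
        return PSDMatrix(
            self.values[mask], self.meta.loc[mask].reset_index(drop=True), self.grid
        )


def welch_psd(samples: np.ndarray, sampling_rate: float = 1000.0) -> np.ndarray:
    """Welch PSD of one epoch (or a stack of epochs) on the 91-bin grid.

    The epoch is z-scored first, so absolute amplitude is deliberately
    discarded and all downstream contrasts reflect spectral shape and
    within-window dynamics only.
    """
    x = np.asarray(samples, dtype=float)
    if x.shape[-1] != _EPOCH_SAMPLES:
        raise ValueError(
            f"expected epochs of {_EPOCH_SAMPLES} samples, got {x.shape[-1]}"
        )
    sd = x.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("constant epoch: z-scoring is undefined")
    z = (x - x.mean(axis=-1, keepdims=True)) / sd
    freqs, pxx = sp_signal.welch(
        z,
        fs=sampling_rate,
        window="hamming",
        nperseg=_NPERSEG,
        noverlap=_NOVERLAP,
        nfft=_NFFT,
        detrend=False,
        scaling="density",
        axis=-1,
    )
    idx = np.searchsorted(freqs, FREQ_GRID.astype(float))
    if not np.allclose(freqs[idx], FREQ_GRID):
        raise RuntimeError("Welch frequency grid does not align at 1 Hz")
    return pxx[..., idx]


def compute_psds(epochs: EpochSet, chunk: int = 4096) -> PSDMatrix:
    """Single-trial PSDs for every epoch row (chunked to bound memory)."""
    n = len(epochs)
    values = np.empty((n, N_BINS))
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        values[a:b] = welch_psd(epochs.samples[a:b], epochs.sampling_rate)
    return PSDMatrix(values, epochs.meta[_META_COLS].reset_index(drop=True))


def normalize_psd_set(psds: PSDMatrix) -> PSDMatrix:
    """Divide each trial spectrum by its site's across-trial mean spectrum.

    The denominator pools all trials of the site across both experimental
    conditions, so per site and per bin the normalized values average to 1.
    """
    if len(psds) == 0:
        raise ValueError("empty PSD set")
    values = psds.values.copy()
    for _, idx in psds.meta.groupby(["subject_id", "site_id"]).groups.items():
        idx = np.asarray(idx)
        denom = values[idx].mean(axis=0)
        if np.any(denom == 0):
            raise ValueError(
                f"zero mean power in a frequency bin for site {_}; "
                "normalization undefined"
            )
        values[idx] = values[idx] / denom
    return PSDMatrix(values, psds.meta.copy(), psds.grid)


def condition_average(psds: PSDMatrix) -> PSDMatrix:
    """Arithmetic per-bin mean per (site, condition): one row per site per
    condition; 970 analyzed sites yield 1940 rows."""
    if len(psds) == 0:
        raise ValueError("empty PSD set")
    conditions = sorted(
        set(psds.meta["condition"].unique()) | set(CONDITIONS)
    )
    frames = []
    values = []
    for (subject, site), idx in psds.meta.groupby(
        ["subject_id", "site_id"]
    ).groups.items():
        idx = np.asarray(idx)
        sub = psds.meta.loc[idx]
        for condition in conditions:
            sel = idx[(sub["condition"] == condition).to_numpy()]
            if sel.size == 0:
                raise ValueError(
                    f"site ({subject}, {site}) has no trials in condition "
                    f"{condition!r}"
                )
            values.append(psds.values[sel].mean(axis=0))
            first = psds.meta.loc[sel[0]]
            frames.append(
                {
                    "subject_id": subject,
                    "site_id": site,
                    "region": first["region"],
                    "hemisphere": first["hemisphere"],
                    "condition": condition,
                    "n_trials": int(sel.size),
                }
            )
    return PSDMatrix(np.asarray(values), pd.DataFrame(frames), psds.grid)
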