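"""Pooled PCA over condition-averaged spectra and leave-one-subject-out
projection of single-trial spectra onto the first principal component.

On real and synthetic data alike the dominant axis of variation across the
normalized spectra is a broadband (>10 Hz) power shift, so PC1 is oriented to
load positively on the >10 Hz bins and the scalar feature y = q . p (trial
spectrum q projected on PC1 p, after centering) indexes broadband power.
To keep the feature out-of-sample per subject, the PCA used to project a
subject's trials is fitted on the other subjects' condition-averaged rows.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .spectral import FREQ_GRID, PSDMatrix

__all__ = ["PCModel", "fit_pca", "orient_pc1", "project_pc1", "loso_project",
           "project_all_loso"]

log = logging.getLogger(__name__)

ORIENT_ABOVE_HZ = 10.0


@dataclass
class PCModel:
    components: np.ndarray  # (k, n_bins), orthonormal rows
    variance_fractions: np.ndarray  # (k,), non-increasing, sums to 1
    mean: np.ndarray  # (n_bins,) centering vector
    grid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.grid is None:
            self.grid = FREQ_GRID


def fit_pca(psds: PSDMatrix | np.ndarray) -> PCModel:
    """Centered PCA (full deterministic SVD) keeping every component."""
    values = psds.values if isinstance(psds, PSDMatrix) else np.asarray(psds, float)
    if values.ndim != 2 or len(values) < 2:
        raise ValueError("PCA needs at least 2 rows")
    if np.allclose(values, values[0]):
        raise ValueError("rank-0 input: all rows identical, PCA undefined")
    pca = PCA(svd_solver="full")
    pca.fit(values)
    return PCModel(
        components=pca.components_.copy(),
        variance_fractions=pca.explained_variance_ratio_.copy(),
        mean=pca.mean_.copy(),
    )


def orient_pc1(model: PCModel) -> PCModel:
    """Fix the sign of PC1 so its mean loading above 10 Hz is positive.

    SVD sign is arbitrary; anchoring it to the broadband band makes larger
    projections mean more broadband power everywhere downstream.
    """
    high = model.grid > ORIENT_ABOVE_HZ
    m = float(model.components[0, high].mean())
    components = model.components.copy()
    if m < 0:
        components[0] = -components[0]
    elif m == 0:
        warnings.warn("PC1 mean loading above 10 Hz is exactly 0; sign kept as-is")
    return PCModel(components, model.variance_fractions.copy(), model.mean.copy(),
                   model.grid)


def project_pc1(model: PCModel, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    return (values - model.mean) @ model.components[0]


def loso_project(
    cond_avg: PSDMatrix,
    trial_psds: PSDMatrix,
    held_out_subject: str,
) -> pd.DataFrame:
    """Project one subject's single-trial spectra on a PC1 fitted without them.

    The PCA is fitted on the condition-averaged rows of every other subject;
    the held-out subject's trial spectra are centered with the fitted mean and
    projected onto the oriented PC1.
    """
    subjects = set(cond_avg.meta["subject_id"])
    if held_out_subject not in subjects:
        raise KeyError(f"held-out subject {held_out_subject!r} not in PSD set")
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    train_mask = (cond_avg.meta["subject_id"] != held_out_subject).to_numpy()
    model = orient_pc1(fit_pca(cond_avg.values[train_mask]))
    trial_mask = (trial_psds.meta["subject_id"] == held_out_subject).to_numpy()
    if not trial_mask.any():
        raise KeyError(f"no trials for held-out subject {held_out_subject!r}")
    out = trial_psds.meta.loc[trial_mask].reset_index(drop=True).copy()
    out["y"] = project_pc1(model, trial_psds.values[trial_mask])
    return out


def project_all_loso(cond_avg: PSDMatrix, trial_psds: PSDMatrix) -> pd.DataFrame:
    """PC1 projections for every subject, each from its own held-out fit."""
    frames = [
        loso_project(cond_avg, trial_psds, subject)
        for subject in sorted(set(cond_avg.meta["subject_id"]))
    ]
    df = pd.concat(frames, ignore_index=True)
    df["trial_id"] = (
        df["condition"].astype(str)
        + ":" + df["series_index"].astype(int).astype(str)
        + ":" + df["position_in_series"].astype(int).astype(str)
    )
    return df
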