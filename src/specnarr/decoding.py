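"""Correlation-matching decoding of the condition label from PC1 patterns.

Trials are stimulus-indexed (every subject saw the same sequences), so a
pattern vector — one measured PC1 projection per site — is well defined for
each trial even when the sites come from different subjects.  For a test
trial, each site's predicted per-condition weights are refit on every trial
except the tested one; the trial is assigned the condition whose predicted
pattern correlates best with the measured pattern.  Chance is 50%.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import child_rng, pearson
from .schedule import CONDITIONS

__all__ = [
    "split_trials",
    "rank_sites",
    "projection_matrix",
    "decode_trial",
    "accuracy_curve",
]

log = logging.getLogger(__name__)


def split_trials(
    trial_ids: np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """One seeded, condition-stratified 80/20 split of the trial universe.

    With 56 image-to-image trials this floors to a 44-trial train/validate
    pool and a 12-trial test set.
    """
    ids = pd.unique(np.asarray(trial_ids))
    rng = child_rng(seed, "trial_split")
    train: list[str] = []
    test: list[str] = []
    for condition in CONDITIONS:
        cond_ids = np.sort(ids[[i.startswith(condition + ":") for i in ids]])
        if cond_ids.size == 0:
            raise ValueError(f"no trials for condition {condition!r}")
        perm = rng.permutation(cond_ids)
        n_train = int(np.floor((1 - test_fraction) * cond_ids.size))
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return sorted(train), sorted(test)


def rank_sites(results: pd.DataFrame) -> list[tuple[str, str]]:
    """Sites in descending prediction accuracy; ties break lexicographically
    by (subject_id, site_id) so the ranking is order-independent."""
    if len(results) == 0:
        raise ValueError("no encoding results to rank")
    ordered = results.sort_values(
        ["mean_r", "subject_id", "site_id"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return list(zip(ordered["subject_id"], ordered["site_id"]))


def projection_matrix(projections: pd.DataFrame) -> tuple[np.ndarray, list, list]:
    """Pivot projections to (site x trial): rows keyed (subject, site)."""
    df = projections[projections["transition_class"] == "image_to_image"]
    pivot = df.pivot_table(
        index=["subject_id", "site_id"], columns="trial_id", values="y"
    )
    if pivot.isna().any().any():
        raise ValueError("missing projections for some (site, trial) pairs")
    return pivot.to_numpy(), list(pivot.index), list(pivot.columns)


@dataclass
class _WeightCache:
    """Leave-one-trial-out condition means for every site at once."""

    y: np.ndarray  # (n_sites, n_trials)
    is_scr: np.ndarray  # (n_trials,)

    def __post_init__(self) -> None:
        self.sum_scr = self.y[:, self.is_scr].sum(axis=1)
        self.sum_seq = self.y[:, ~self.is_scr].sum(axis=1)
        self.n_scr = int(self.is_scr.sum())
        self.n_seq = int((~self.is_scr).sum())

    def predicted(self, left_out: int) -> tuple[np.ndarray, np.ndarray]:
        """(pred_scr, pred_seq) per site, fit on all trials but ``left_out``."""
        yt = self.y[:, left_out]
        if self.is_scr[left_out]:
            pred_scr = (self.sum_scr - yt) / (self.n_scr - 1)
            pred_seq = self.sum_seq / self.n_seq
        else:
            pred_scr = self.sum_scr / self.n_scr
            pred_seq = (self.sum_seq - yt) / (self.n_seq - 1)
        return pred_scr, pred_seq


def decode_trial(
    measured: np.ndarray,
    pred_scr: np.ndarray,
    pred_seq: np.ndarray,
    true_condition: str,
) -> tuple[str | None, bool]:
    """Assign the condition whose predicted pattern correlates best.

    An exact correlation tie or a zero-variance measured pattern is scored as
    unsuccessful (conservative).
    """
    measured = np.asarray(measured, dtype=float)
    if measured.size < 2:
        raise ValueError("pattern vectors need at least 2 sites")
    if np.ptp(measured) == 0:
        warnings.warn("zero-variance measured pattern; trial scored unsuccessful")
        return None, False
    r_scr = pearson(measured, pred_scr, warn=False)
    r_seq = pearson(measured, pred_seq, warn=False)
    if r_scr == r_seq:
        warnings.warn("correlation tie; trial scored unsuccessful")
        return None, False
    predicted = CONDITIONS[0] if r_scr > r_seq else CONDITIONS[1]
    return predicted, predicted == true_condition


def accuracy_curve(
    projections: pd.DataFrame,
    ranked_sites: list[tuple[str, str]],
    test_trial_ids: list[str],
    sizes: list[int] | None = None,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Decoding accuracy versus ensemble size.

    For each group size n: take the top-n ranked sites, draw a uniform random
    half (floor(n/2) sites), decode every test trial from that subgroup's
    pattern, and record the percent decoded correctly; repeat ``repeats``
    times and report mean and SEM.
    """
    y, site_index, trial_ids = projection_matrix(projections)
    if not test_trial_ids:
        raise ValueError("test trial set is empty")
    order = {key: i for i, key in enumerate(site_index)}
    ranked_rows = np.array([order[s] for s in ranked_sites])
    n_sites = len(ranked_rows)
    if sizes is None:
        sizes = list(range(4, n_sites + 1, 2))
    if min(sizes) < 4:
        raise ValueError("minimum group size is 4")
    is_scr = np.array([t.startswith(CONDITIONS[0] + ":") for t in trial_ids])
    cache = _WeightCache(y, is_scr)
    trial_pos = {t: i for i, t in enumerate(trial_ids)}
    test_pos = [trial_pos[t] for t in test_trial_ids]

    rng = child_rng(seed, "decode_curve")
    records = []
    for size in sizes:
        if size > n_sites:
            raise ValueError(f"group size {size} exceeds {n_sites} ranked sites")
        top = ranked_rows[:size]
        accs = []
        for _rep in range(repeats):
            half = rng.choice(top, size=size // 2, replace=False)
            n_ok = 0
            for t in test_pos:
                pred_scr, pred_seq = cache.predicted(t)
                true = CONDITIONS[0] if is_scr[t] else CONDITIONS[1]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, ok = decode_trial(
                        y[half, t], pred_scr[half], pred_seq[half], true
                    )
                n_ok += int(ok)
            accs.append(100.0 * n_ok / len(test_pos))
        accs = np.asarray(accs)
        sem = float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0
        records.append(
            {"size": size, "mean_accuracy": float(accs.mean()), "sem": sem}
        )
    return pd.DataFrame(records)
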