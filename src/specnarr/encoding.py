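"""Per-site condition encoding of the PC1-projection feature.

The encoding model regresses single-trial PC1 projections on a binary design
matrix with one indicator column per condition plus an intercept (y = Xb + e).
The design is deliberately rank deficient (the two indicators sum to the
intercept column); the minimum-norm least-squares solution is used, and the
exported "predicted weight" of a condition is the model's predicted
projection for that condition (indicator weight + intercept), which equals
the condition's training mean and is invariant to the parameterization.

Prediction accuracy is the mean Pearson correlation between predicted and
observed projections over Monte-Carlo cross-validation folds (default: 10
folds of 17 training trials drawn from the 44-trial train/validate pool, the
27 remaining trials scored per fold).  Site selection uses a condition-swap
permutation null of that accuracy with an add-one p-value estimate.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import child_rng, pearson
from .schedule import CONDITIONS, FIRST_CLASSES

__all__ = [
    "EncodingModel",
    "EncodingResult",
    "fit_condition_regression",
    "predict_projections",
    "condition_weights",
    "mc_cross_validate",
    "permutation_select",
    "encode_sites",
    "first_vs_rest_contrast",
]

log = logging.getLogger(__name__)


@dataclass
class EncodingModel:
    beta: np.ndarray  # (3,): Scr weight, Seq weight, intercept
    conditions: tuple[str, str] = CONDITIONS


@dataclass
class EncodingResult:
    subject_id: str | None
    site_id: str | None
    fold_r: np.ndarray
    mean_r: float
    weight_scr: float
    weight_seq: float
    p_value: float | None = None
    significant: bool | None = None
    null_mean: float | None = None
    null_q95: float | None = None
    n_perm: int | None = None


def _design(labels: np.ndarray) -> np.ndarray:
    scr = (labels == CONDITIONS[0]).astype(float)
    seq = (labels == CONDITIONS[1]).astype(float)
    if not scr.any() or not seq.any():
        raise ValueError("both conditions must be present in the training set")
    unknown = ~((labels == CONDITIONS[0]) | (labels == CONDITIONS[1]))
    if unknown.any():
        raise ValueError(f"unknown condition labels: {set(labels[unknown])}")
    return np.column_stack([scr, seq, np.ones_like(scr)])


def fit_condition_regression(y: np.ndarray, labels: np.ndarray) -> EncodingModel:
    """Minimum-norm least squares of projections on the condition design."""
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    X = _design(labels)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return EncodingModel(beta)


def predict_projections(model: EncodingModel, labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    w = condition_weights(model)
    return np.where(labels == CONDITIONS[0], w[CONDITIONS[0]], w[CONDITIONS[1]])


def condition_weights(model: EncodingModel) -> dict[str, float]:
    """Predicted projection per condition: indicator weight + intercept."""
    return {
        CONDITIONS[0]: float(model.beta[0] + model.beta[2]),
        CONDITIONS[1]: float(model.beta[1] + model.beta[2]),
    }


def _draw_folds(
    n_pool: int,
    labels: np.ndarray,
    folds: int,
    n_train: int,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per fold, sample ``n_train`` trials without replacement, resampling
    until both conditions are present in the training draw."""
    if n_train >= n_pool:
        raise ValueError("n_train must be smaller than the trial pool")
    out = []
    all_idx = np.arange(n_pool)
    for _ in range(folds):
        for _try in range(max_tries):
            train = rng.choice(n_pool, size=n_train, replace=False)
            if len(set(labels[train])) == 2:
                break
        else:  # pragma: no cover - pathological label imbalance
            raise ValueError("could not draw a training fold with both conditions")
        val = np.setdiff1d(all_idx, train)
        out.append((np.sort(train), val))
    return out


def _fold_scores(
    y: np.ndarray,
    scr: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    warn: bool = True,
) -> np.ndarray:
    rs = np.empty(len(folds))
    for k, (train, val) in enumerate(folds):
        s_tr = scr[train]
        n_scr = s_tr.sum()
        n_seq = len(train) - n_scr
        if n_scr == 0 or n_seq == 0:
            rs[k] = 0.0
            continue
        m_scr = y[train][s_tr.astype(bool)].mean()
        m_seq = y[train][~s_tr.astype(bool)].mean()
        pred = np.where(scr[val].astype(bool), m_scr, m_seq)
        if np.ptp(pred) == 0 or np.ptp(y[val]) == 0:
            if warn:
                warnings.warn("degenerate validation fold; fold r set to 0")
            rs[k] = 0.0
            continue
        rs[k] = pearson(pred, y[val], warn=False)
    return rs


def mc_cross_validate(
    y: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    n_train: int = 17,
    seed: int = 0,
    subject_id: str | None = None,
    site_id: str | None = None,
) -> EncodingResult:
    """Monte-Carlo cross-validated prediction accuracy of one site."""
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    _design(labels)  # validates labels
    rng = child_rng(seed, "mc_cv", str(subject_id), str(site_id))
    fold_idx = _draw_folds(len(y), labels, folds, n_train, rng)
    scr = (labels == CONDITIONS[0]).astype(float)
    fold_r = _fold_scores(y, scr, fold_idx)
    w = condition_weights(fit_condition_regression(y, labels))
    return EncodingResult(
        subject_id=subject_id,
        site_id=site_id,
        fold_r=fold_r,
        mean_r=float(fold_r.mean()),
        weight_scr=w[CONDITIONS[0]],
        weight_seq=w[CONDITIONS[1]],
    )


def _null_mean_r(
    y: np.ndarray,
    scr_perms: np.ndarray,  # (n_perm, n) 0/1
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Vectorized fold scoring of permuted label assignments."""
    n_perm = scr_perms.shape[0]
    total = np.zeros(n_perm)
    for train, val in folds:
        s_tr = scr_perms[:, train]  # (P, n_train)
        n_scr = s_tr.sum(axis=1)
        n_seq = len(train) - n_scr
        ok = (n_scr > 0) & (n_seq > 0)
        m_scr = np.zeros(n_perm)
        m_seq = np.zeros(n_perm)
        np.divide(s_tr @ y[train], n_scr, out=m_scr, where=ok)
        np.divide((1 - s_tr) @ y[train], n_seq, out=m_seq, where=ok)
        s_va = scr_perms[:, val]  # (P, n_val)
        pred = s_va * m_scr[:, None] + (1 - s_va) * m_seq[:, None]
        yv = y[val]
        pred_c = pred - pred.mean(axis=1, keepdims=True)
        yv_c = yv - yv.mean()
        denom = np.sqrt((pred_c ** 2).sum(axis=1) * (yv_c ** 2).sum())
        num = pred_c @ yv_c
        r = np.zeros(n_perm)
        good = ok & (denom > 0)
        np.divide(num, denom, out=r, where=good)
        total += r
    return total / len(folds)


def permutation_select(
    y: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    n_train: int = 17,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    subject_id: str | None = None,
    site_id: str | None = None,
) -> EncodingResult:
    """Condition-swap permutation test of the cross-validated accuracy.

    The null redraws the condition assignment uniformly (label shuffle) and
    recomputes the mean fold correlation on the same fold draws; the add-one
    estimator p = (1 + #{null >= observed}) / (n_perm + 1) avoids p = 0.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value resolution")
    y = np.asarray(y, dtype=float)
    labels = np.asarray(labels)
    _design(labels)
    rng = child_rng(seed, "perm", str(subject_id), str(site_id))
    fold_idx = _draw_folds(len(y), labels, folds, n_train, rng)
    scr = (labels == CONDITIONS[0]).astype(float)
    fold_r = _fold_scores(y, scr, fold_idx)
    observed = float(fold_r.mean())

    perms = np.empty((n_perm, len(y)))
    for i in range(n_perm):
        perms[i] = rng.permutation(scr)
    null = _null_mean_r(y, perms, fold_idx)
    p = float((1 + np.sum(null >= observed)) / (n_perm + 1))
    w = condition_weights(fit_condition_regression(y, labels))
    return EncodingResult(
        subject_id=subject_id,
        site_id=site_id,
        fold_r=fold_r,
        mean_r=observed,
        weight_scr=w[CONDITIONS[0]],
        weight_seq=w[CONDITIONS[1]],
        p_value=p,
        significant=bool(p < alpha),
        null_mean=float(null.mean()),
        null_q95=float(np.quantile(null, 0.95)),
        n_perm=n_perm,
    )


def encode_sites(
    projections: pd.DataFrame,
    pool_trial_ids: set[str] | None = None,
    folds: int = 10,
    n_train: int = 17,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the permutation-selected encoding model for every site.

    ``projections`` must carry columns subject_id, site_id, region,
    hemisphere, condition, transition_class, trial_id, y.  ``pool_trial_ids``
    restricts the analysis to the train/validate pool (the 80% split);
    ``None`` uses every image-to-image trial present.
    """
    df = projections[projections["transition_class"] == "image_to_image"]
    if pool_trial_ids is not None:
        df = df[df["trial_id"].isin(pool_trial_ids)]
    rows = []
    for (subject, site), grp in df.groupby(["subject_id", "site_id"], sort=True):
        res = permutation_select(
            grp["y"].to_numpy(),
            grp["condition"].to_numpy(),
            folds=folds,
            n_train=n_train,
            n_perm=n_perm,
            alpha=alpha,
            seed=seed,
            subject_id=str(subject),
            site_id=str(site),
        )
        rows.append(
            {
                "subject_id": subject,
                "site_id": site,
                "region": grp["region"].iloc[0],
                "hemisphere": grp["hemisphere"].iloc[0],
                "mean_r": res.mean_r,
                "p_value": res.p_value,
                "significant": res.significant,
                "weight_scr": res.weight_scr,
                "weight_seq": res.weight_seq,
                "null_mean": res.null_mean,
                "null_q95": res.null_q95,
            }
        )
    return pd.DataFrame(rows)


def first_vs_rest_contrast(
    projections: pd.DataFrame,
    regions: tuple[str, ...] = ("frontal", "temporal"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group projections into region x condition x {First, Rest} cells.

    "First" is the series-initial (gray-to-image) transition, "Rest" the
    within-series transitions; the habituation question is whether the two
    conditions differ in each subset.  Returns a cell summary (mean, SEM, n)
    and rank-based (Kruskal-Wallis) comparisons per region: First Seq-vs-Scr,
    Rest Seq-vs-Scr, and within-condition First-vs-Rest.
    """
    df = projections.copy()
    df["transition_group"] = np.where(
        df["transition_class"].isin(FIRST_CLASSES), "First", "Rest"
    )
    summaries = []
    tests = []
    for region in regions:
        sub = df[df["region"] == region]
        cells: dict[tuple[str, str], np.ndarray] = {}
        for condition in CONDITIONS:
            for group in ("First", "Rest"):
                y = sub.loc[
                    (sub["condition"] == condition)
                    & (sub["transition_group"] == group),
                    "y",
                ].to_numpy()
                if y.size == 0:
                    raise ValueError(
                        f"empty cell: region={region}, condition={condition}, "
                        f"group={group}"
                    )
                cells[(condition, group)] = y
                summaries.append(
                    {
                        "region": region,
                        "condition": condition,
                        "transition_group": group,
                        "mean": float(y.mean()),
                        "sem": float(stats.sem(y)) if y.size > 1 else 0.0,
                        "n": int(y.size),
                    }
                )
        comparisons = {
            "first_seq_vs_scr": (cells[("Seq", "First")], cells[("Scr", "First")]),
            "rest_seq_vs_scr": (cells[("Seq", "Rest")], cells[("Scr", "Rest")]),
            "seq_first_vs_rest": (cells[("Seq", "First")], cells[("Seq", "Rest")]),
            "scr_first_vs_rest": (cells[("Scr", "First")], cells[("Scr", "Rest")]),
        }
        for name, (a, b) in comparisons.items():
            if np.ptp(np.concatenate([a, b])) == 0:
                # all values identical across groups: rank statistic at its
                # tie-minimum, nothing to reject
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.kruskal(a, b)
            tests.append(
                {
                    "region": region,
                    "comparison": name,
                    "statistic": float(stat),
                    "p_value": float(p),
                    "mean_difference": float(a.mean() - b.mean()),
                }
            )
    return pd.DataFrame(summaries), pd.DataFrame(tests)
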