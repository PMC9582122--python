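"""Pairwise autoregressive Granger causality and the source-sink network
contrast between conditions.

For an ordered site pair (x, y) the full model regresses y on its own past
and x's past; the restricted model uses y's own past only.  Lagged samples
are pooled across trials without crossing trial boundaries.  The statistic is
the log residual-variance ratio gc = ln(s2_restricted / s2_full) >= 0, tested
with an F (Wald-type) model comparison, one directional test per direction.
x "Granger-causes" y — a source-sink couplet — when gc(x->y) > gc(y->x) and
its p < alpha.  Couplet counts per (source region, sink region) cell form a
6x6 contingency table per condition; the Seq/Scr tables are contrasted with
an omnibus Pearson chi-square over the stacked condition x cell layout, with
per-cell standardized adjusted residuals (Bonferroni-corrected) as post-hocs,
and lateralized region pairs with Fisher's exact test.
"""
from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import EpochSet, baseline_correct_epochs
from .simulate import REGIONS

__all__ = [
    "GCResult",
    "pairwise_gc",
    "select_order_aic",
    "condition_gc",
    "identify_couplets",
    "region_contingency",
    "ContrastResult",
    "chi_square_contrast",
    "fisher_lateralization",
]

log = logging.getLogger(__name__)


@dataclass
class GCResult:
    x_site: tuple[str, str]
    y_site: tuple[str, str]
    condition: str
    gc_xy: float
    gc_yx: float
    p_xy: float
    p_yx: float
    order: int


def _lagged_design(trials: np.ndarray, order: int) -> np.ndarray:
    """Stack lag-1..order columns per trial, never crossing trial boundaries.

    trials: (n_trials, n_samples) -> (n_trials*(n_samples-order), order)
    """
    n_trials, n_samp = trials.shape
    cols = [trials[:, order - k:n_samp - k].reshape(-1) for k in range(1, order + 1)]
    return np.column_stack(cols)


def _targets(trials: np.ndarray, order: int) -> np.ndarray:
    return trials[:, order:].reshape(-1)


def _gc_one_direction(
    x: np.ndarray, y: np.ndarray, order: int
) -> tuple[float, float]:
    """gc and p for x -> y from pooled trialwise regressions."""
    n_obs = y.shape[0] * (y.shape[1] - order)
    target = _targets(y, order)
    own = _lagged_design(y, order)
    other = _lagged_design(x, order)
    ones = np.ones((n_obs, 1))
    X_restricted = np.column_stack([ones, own])
    X_full = np.column_stack([ones, own, other])
    k_full = X_full.shape[1]
    beta_f, rss_f, rank_f, _ = np.linalg.lstsq(X_full, target, rcond=None)
    if rank_f < k_full:
        raise np.linalg.LinAlgError(
            "singular regression: full-model design is rank deficient "
            "(identical or collinear series?)"
        )
    beta_r, rss_r, _, _ = np.linalg.lstsq(X_restricted, target, rcond=None)
    rss_f = float(np.sum((target - X_full @ beta_f) ** 2))
    rss_r = float(np.sum((target - X_restricted @ beta_r) ** 2))
    if rss_f <= 0:
        raise np.linalg.LinAlgError("zero full-model residual; gc undefined")
    gc = float(np.log(rss_r / rss_f))
    if gc < 0:  # numerically impossible for nested OLS, guard rounding
        gc = 0.0
    df_num = order
    df_den = n_obs - k_full
    f_stat = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    p = float(stats.f.sf(max(f_stat, 0.0), df_num, df_den))
    return gc, p


def pairwise_gc(
    x_trials: np.ndarray,
    y_trials: np.ndarray,
    order: int,
    condition: str = "",
    x_site: tuple[str, str] = ("", ""),
    y_site: tuple[str, str] = ("", ""),
) -> GCResult:
    """Granger causality in both directions for one site pair.

    Inputs are DC-corrected response-window segments, shape
    (n_trials, n_samples), with equal trial counts for x and y.
    """
    x = np.asarray(x_trials, dtype=float)
    y = np.asarray(y_trials, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have identical (n_trials, n_samples) shape")
    if order < 1:
        raise ValueError("model order must be >= 1")
    if order >= x.shape[1]:
        raise ValueError(
            f"model order {order} must be smaller than the window length "
            f"{x.shape[1]}"
        )
    gc_xy, p_xy = _gc_one_direction(x, y, order)
    gc_yx, p_yx = _gc_one_direction(y, x, order)
    return GCResult(x_site, y_site, condition, gc_xy, gc_yx, p_xy, p_yx, order)


def select_order_aic(
    x_trials: np.ndarray, y_trials: np.ndarray, max_order: int = 20
) -> int:
    """AIC model-order selection for the bivariate VAR on pooled trials."""
    x = np.asarray(x_trials, dtype=float)
    y = np.asarray(y_trials, dtype=float)
    best_order, best_aic = 1, np.inf
    for order in range(1, max_order + 1):
        if order >= x.shape[1]:
            break
        n_obs = x.shape[0] * (x.shape[1] - order)
        lx = _lagged_design(x, order)
        ly = _lagged_design(y, order)
        X = np.column_stack([np.ones(n_obs), ly, lx])
        resid = []
        for target_series in (y, x):
            t = _targets(target_series, order)
            beta, *_ = np.linalg.lstsq(X, t, rcond=None)
            resid.append(t - X @ beta)
        E = np.column_stack(resid)
        sigma = (E.T @ E) / n_obs
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        k_params = 2 * (2 * order + 1)
        aic = logdet + 2.0 * k_params / n_obs
        if aic < best_aic:
            best_aic, best_order = aic, order
    return best_order


def condition_gc(
    epochs: EpochSet,
    order: int | None = None,
    max_order: int = 20,
    response_window_ms: tuple[float, float] = (100.0, 500.0),
    dc_window_ms: tuple[float, float] = (-100.0, 100.0),
) -> pd.DataFrame:
    """GC for every within-subject site pair, per condition.

    Epochs are DC-corrected with the mean over ``dc_window_ms`` and restricted
    to the post-onset ``response_window_ms`` segment before fitting.  When
    ``order`` is None it is selected once per subject by AIC on the first
    eligible pair and reused (configurable standard practice; Granger
    causality across subjects is physically meaningless and is not computed).
    """
    corrected = baseline_correct_epochs(epochs, dc_window_ms)
    fs = epochs.sampling_rate
    lo, hi = epochs.window_ms
    a = int(round((response_window_ms[0] - lo) * fs / 1000.0))
    b = int(round((response_window_ms[1] - lo) * fs / 1000.0))
    meta = corrected.meta
    rows = []
    for subject in sorted(meta["subject_id"].unique()):
        sub_mask = (meta["subject_id"] == subject).to_numpy()
        sub_meta = meta.loc[sub_mask].reset_index(drop=True)
        sub_samp = corrected.samples[sub_mask][:, a:b]
        sites = sorted(sub_meta["site_id"].unique())
        regions = {
            s: sub_meta.loc[sub_meta["site_id"] == s, "region"].iloc[0] for s in sites
        }
        for condition in sorted(sub_meta["condition"].unique()):
            per_site = {}
            for s in sites:
                sel = (
                    (sub_meta["site_id"] == s) & (sub_meta["condition"] == condition)
                ).to_numpy()
                per_site[s] = sub_samp[sel]
            counts = {s: t.shape[0] for s, t in per_site.items()}
            if len(set(counts.values())) != 1:
                raise ValueError(
                    f"unequal trial counts across sites for subject {subject!r}"
                )
            sub_order = order
            for s1, s2 in itertools.combinations(sites, 2):
                if sub_order is None:
                    sub_order = select_order_aic(
                        per_site[s1], per_site[s2], max_order=max_order
                    )
                try:
                    res = pairwise_gc(
                        per_site[s1],
                        per_site[s2],
                        sub_order,
                        condition=condition,
                        x_site=(subject, s1),
                        y_site=(subject, s2),
                    )
                except np.linalg.LinAlgError as err:
                    log.warning(
                        "skipping pair (%s, %s) condition %s: %s",
                        s1, s2, condition, err,
                    )
                    continue
                rows.append(
                    {
                        "subject_id": subject,
                        "x_site": s1,
                        "y_site": s2,
                        "x_region": regions[s1],
                        "y_region": regions[s2],
                        "condition": condition,
                        "gc_xy": res.gc_xy,
                        "gc_yx": res.gc_yx,
                        "p_xy": res.p_xy,
                        "p_yx": res.p_yx,
                        "order": res.order,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "x_site", "y_site", "x_region", "y_region",
            "condition", "gc_xy", "gc_yx", "p_xy", "p_yx", "order",
        ],
    )


def identify_couplets(gc_results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Source-sink couplets: direction of the larger gc, requiring its p < alpha.

    At most one couplet per unordered pair per condition; an exact gc tie is
    conservative (no couplet).
    """
    rows = []
    for rec in gc_results.itertuples(index=False):
        if rec.gc_xy == rec.gc_yx:
            if rec.gc_xy > 0:
                warnings.warn(
                    f"exact gc tie for pair ({rec.x_site}, {rec.y_site}); "
                    "no couplet assigned"
                )
            continue
        if rec.gc_xy > rec.gc_yx:
            src, snk, src_rg, snk_rg, p = (
                rec.x_site, rec.y_site, rec.x_region, rec.y_region, rec.p_xy
            )
        else:
            src, snk, src_rg, snk_rg, p = (
                rec.y_site, rec.x_site, rec.y_region, rec.x_region, rec.p_yx
            )
        if p < alpha:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "source_site": src,
                    "sink_site": snk,
                    "source_region": src_rg,
                    "sink_region": snk_rg,
                    "condition": rec.condition,
                    "gc": max(rec.gc_xy, rec.gc_yx),
                    "p_value": p,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "source_site", "sink_site", "source_region",
            "sink_region", "condition", "gc", "p_value",
        ],
    )


def region_contingency(
    couplets: pd.DataFrame, regions: tuple[str, ...] = REGIONS
) -> pd.DataFrame:
    """6x6 couplet counts: source region rows, sink region columns."""
    table = pd.DataFrame(0, index=list(regions), columns=list(regions))
    for rec in couplets.itertuples(index=False):
        if rec.source_region not in table.index or rec.sink_region not in table.columns:
            raise ValueError(
                f"couplet references unlabeled region "
                f"({rec.source_region}, {rec.sink_region})"
            )
        table.loc[rec.source_region, rec.sink_region] += 1
    return table


@dataclass
class ContrastResult:
    statistic: float
    dof: int
    p_value: float
    cells: pd.DataFrame  # per tested cell: counts, adjusted residual, p, direction
    n_dropped_cells: int


def chi_square_contrast(
    table_seq: pd.DataFrame | np.ndarray,
    table_scr: pd.DataFrame | np.ndarray,
    alpha: float = 0.05,
) -> ContrastResult:
    """Omnibus Pearson chi-square of condition x source-sink-cell counts,
    with per-cell adjusted-residual post-hocs (Bonferroni over tested cells).

    Cells empty in both conditions have zero expectation and are dropped
    (reported in ``n_dropped_cells``).
    """
    seq = np.asarray(table_seq, dtype=float)
    scr = np.asarray(table_scr, dtype=float)
    if seq.shape != scr.shape:
        raise ValueError("condition tables must have identical shape")
    if isinstance(table_seq, pd.DataFrame):
        labels = [
            (str(r), str(c)) for r in table_seq.index for c in table_seq.columns
        ]
    else:
        labels = [
            (str(i), str(j))
            for i in range(seq.shape[0])
            for j in range(seq.shape[1] if seq.ndim == 2 else 1)
        ]
    flat_seq = seq.reshape(-1)
    flat_scr = scr.reshape(-1)
    keep = (flat_seq + flat_scr) > 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("both contingency tables are all-zero")
    obs = np.vstack([flat_seq[keep], flat_scr[keep]])  # rows: Seq, Scr
    if obs.shape[1] < 2:
        raise ValueError("need at least 2 nonempty cells for a contrast")
    stat, p, dof, expected = stats.chi2_contingency(obs, correction=False)

    n = obs.sum()
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    kept_labels = [lab for lab, k in zip(labels, keep) if k]
    n_tested = obs.shape[1]
    cells = []
    for j, (src, snk) in enumerate(kept_labels):
        denom = expected[0, j] * (1 - row_tot[0] / n) * (1 - col_tot[j] / n)
        z = (obs[0, j] - expected[0, j]) / np.sqrt(denom) if denom > 0 else 0.0
        p_cell = min(1.0, 2.0 * stats.norm.sf(abs(z)) * n_tested)
        cells.append(
            {
                "source": src,
                "sink": snk,
                "observed_seq": int(obs[0, j]),
                "observed_scr": int(obs[1, j]),
                "adjusted_residual": float(z),
                "p_adjusted": float(p_cell),
                "direction": "Seq>Scr" if z > 0 else ("Seq<Scr" if z < 0 else "tie"),
                "significant": bool(p_cell < alpha),
            }
        )
    return ContrastResult(float(stat), int(dof), float(p), pd.DataFrame(cells),
                          n_dropped)


def fisher_lateralization(
    couplets_seq: pd.DataFrame,
    couplets_scr: pd.DataFrame,
    site_table: pd.DataFrame,
    pair: tuple[tuple[str, str], tuple[str, str]],
) -> tuple[float, np.ndarray]:
    """Two-sided Fisher exact test of a lateralized source-sink pair.

    ``pair`` is ((source region, source hemisphere), (sink region, sink
    hemisphere)).  The 2x2 table is condition x {couplet matches the
    lateralized pair, any other couplet}.
    """
    hemi = {
        (r.subject_id, r.site_id): r.hemisphere for r in site_table.itertuples()
    }
    (src_region, src_hemi), (snk_region, snk_hemi) = pair

    def count(couplets: pd.DataFrame) -> tuple[int, int]:
        match = 0
        for rec in couplets.itertuples(index=False):
            sh = hemi.get((rec.subject_id, rec.source_site))
            kh = hemi.get((rec.subject_id, rec.sink_site))
            if sh is None or kh is None:
                raise ValueError("couplet references a site missing from the table")
            if (
                rec.source_region == src_region
                and rec.sink_region == snk_region
                and sh == src_hemi
                and kh == snk_hemi
            ):
                match += 1
        return match, len(couplets) - match

    table = np.array([count(couplets_seq), count(couplets_scr)])
    if table.sum(axis=1).min() == 0 or table.sum() == 0:
        raise ValueError("empty margin: Fisher test undefined")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), table
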