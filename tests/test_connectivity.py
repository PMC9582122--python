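"""Granger causality against VAR oracles; contingency and exact-test oracles."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from specnarr import (
    chi_square_contrast,
    fisher_lateralization,
    identify_couplets,
    pairwise_gc,
    region_contingency,
)
from specnarr.connectivity import select_order_aic


def _var1(rng, n_trials=56, n_samples=400, a=0.3, c=0.5):
    """y_t = a*y_{t-1} + c*x_{t-1} + e_t with x, e unit white noise."""
    x = rng.standard_normal((n_trials, n_samples))
    e = rng.standard_normal((n_trials, n_samples))
    y = np.zeros_like(x)
    for t in range(1, n_samples):
        y[:, t] = a * y[:, t - 1] + c * x[:, t - 1] + e[:, t]
    return x, y


def _closed_form_gc(a=0.3, c=0.5, sx=1.0, se=1.0):
    """Restricted AR(1) innovation variance of y is c^2 sx^2 + se^2 (y alone
    is an exact AR(1)); the full model recovers se^2."""
    return math.log((c**2 * sx**2 + se**2) / se**2)


class TestPairwiseGC:
    def test_var1_matches_closed_form_within_10pct(self):
        truth = _closed_form_gc()
        estimates = []
        for seed in range(8):
            x, y = _var1(np.random.default_rng(seed))
            estimates.append(pairwise_gc(x, y, order=1).gc_xy)
        assert np.mean(estimates) == pytest.approx(truth, rel=0.10)

    def test_var1_direction_recovered(self):
        hits, sig = 0, 0
        n = 20
        for seed in range(n):
            x, y = _var1(np.random.default_rng(100 + seed))
            res = pairwise_gc(x, y, order=1)
            hits += res.gc_xy > res.gc_yx
            sig += res.p_xy < 0.05
        assert hits >= 0.9 * n
        assert sig >= 0.9 * n

    def test_independent_series_calibrated(self):
        """gc near 0 and direction-wise false-positive rate compatible with
        alpha = 0.05 on independent series."""
        gcs, rejections = [], 0
        n = 200
        rng = np.random.default_rng(0)
        for _ in range(n):
            x = rng.standard_normal((8, 120))
            y = rng.standard_normal((8, 120))
            res = pairwise_gc(x, y, order=2)
            gcs.append(res.gc_xy)
            rejections += res.p_xy < 0.05
        assert np.mean(gcs) < 0.02
        # one-sided binomial check against a 5% false-positive rate (1% level)
        assert stats.binomtest(rejections, n, 0.05, "greater").pvalue > 0.01

    def test_identical_series_rejected(self):
        x = np.random.default_rng(1).standard_normal((4, 100))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            pairwise_gc(x, x, order=2)

    def test_order_must_fit_window(self):
        x = np.random.default_rng(2).standard_normal((4, 50))
        with pytest.raises(ValueError, match="order"):
            pairwise_gc(x, x, order=50)

    def test_gc_nonnegative_and_p_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.standard_normal((6, 80))
            y = rng.standard_normal((6, 80))
            res = pairwise_gc(x, y, order=3)
            assert res.gc_xy >= 0 and res.gc_yx >= 0
            assert 0 <= res.p_xy <= 1 and 0 <= res.p_yx <= 1

    def test_aic_selects_small_order_for_var1(self):
        x, y = _var1(np.random.default_rng(4))
        assert select_order_aic(x, y, max_order=8) <= 3


def test_injected_coupling_absent_during_isi():
    """Directed coupling is driven by the stimulus response: GC on gray-screen
    (ISI) epochs is weaker than on stimulus epochs for injected pairs."""
    from specnarr import (
        CouplingEdge,
        CouplingSpec,
        EffectSpec,
        condition_gc,
        epoch_transitions,
    )
    from conftest import make_study

    coupling = CouplingSpec([CouplingEdge("temporal", "frontal", "Seq", 5, 0.6)])
    schedule, recording, truth = make_study(
        seed=31, gains=EffectSpec.null(), coupling=coupling,
        n_subjects=1, sites_per_subject=8,
    )
    stim = epoch_transitions(recording, schedule, classes={"image_to_image"})
    isi = epoch_transitions(recording, schedule, classes={"image_to_isi"})

    def injected_gc(epochs):
        gc = condition_gc(epochs, order=10)
        gc = gc[gc["condition"] == "Seq"]
        vals = []
        for e in truth.edges.itertuples():
            fwd = gc[(gc["x_site"] == e.source_site) & (gc["y_site"] == e.sink_site)]
            rev = gc[(gc["y_site"] == e.source_site) & (gc["x_site"] == e.sink_site)]
            if len(fwd):
                vals.append(fwd["gc_xy"].iloc[0])
            elif len(rev):
                vals.append(rev["gc_yx"].iloc[0])
        return float(np.mean(vals))

    assert injected_gc(stim) > 2 * injected_gc(isi)


class TestCouplets:
    def _frame(self, gc_xy, gc_yx, p_xy, p_yx):
        return pd.DataFrame(
            [
                {
                    "subject_id": "S01",
                    "x_site": "a", "y_site": "b",
                    "x_region": "temporal", "y_region": "frontal",
                    "condition": "Seq",
                    "gc_xy": gc_xy, "gc_yx": gc_yx,
                    "p_xy": p_xy, "p_yx": p_yx,
                    "order": 3,
                }
            ]
        )

    def test_significant_larger_direction_wins(self):
        out = identify_couplets(self._frame(0.4, 0.1, 0.01, 0.5))
        assert len(out) == 1
        assert out.iloc[0]["source_site"] == "a"
        assert out.iloc[0]["sink_site"] == "b"

    def test_insignificant_direction_dropped(self):
        assert len(identify_couplets(self._frame(0.4, 0.1, 0.20, 0.01))) == 0

    def test_exact_tie_is_conservative(self):
        with pytest.warns(UserWarning, match="tie"):
            out = identify_couplets(self._frame(0.3, 0.3, 0.01, 0.01))
        assert len(out) == 0

    def test_reverse_direction(self):
        out = identify_couplets(self._frame(0.1, 0.4, 0.5, 0.01))
        assert out.iloc[0]["source_site"] == "b"
        assert out.iloc[0]["source_region"] == "frontal"


class TestRegionContingency:
    def _couplets(self, triples):
        return pd.DataFrame(
            [
                {
                    "subject_id": "S01",
                    "source_site": "a", "sink_site": "b",
                    "source_region": src, "sink_region": snk,
                    "condition": cond, "gc": 0.5, "p_value": 0.01,
                }
                for src, snk, cond in triples
            ]
        )

    def test_counts_land_in_cells(self):
        table = region_contingency(
            self._couplets([("temporal", "frontal", "Seq")] * 3)
        )
        assert table.loc["temporal", "frontal"] == 3
        assert table.to_numpy().sum() == 3

    def test_empty_gives_zero_table(self):
        table = region_contingency(self._couplets([]))
        assert table.shape == (6, 6)
        assert table.to_numpy().sum() == 0

    def test_total_equals_couplet_count(self):
        rng = np.random.default_rng(5)
        regions = ["frontal", "temporal", "parietal", "insula"]
        triples = [
            (rng.choice(regions), rng.choice(regions), "Scr") for _ in range(40)
        ]
        table = region_contingency(self._couplets(triples))
        assert table.to_numpy().sum() == 40


class TestChiSquareContrast:
    def test_identical_tables_give_zero(self):
        t = pd.DataFrame([[5, 3], [2, 7]])
        res = chi_square_contrast(t, t)
        assert res.statistic == pytest.approx(0.0)
        assert (res.cells["p_adjusted"] == 1).all()

    def test_hand_computed_two_cell_case(self):
        """Stacked layout [[10, 20], [20, 10]]: Pearson chi-square = 20/3."""
        res = chi_square_contrast(np.array([[10, 20]]), np.array([[20, 10]]))
        assert res.statistic == pytest.approx(100.0 / 15.0)

    def test_matches_brute_force_pearson(self):
        """Sum (O-E)^2/E computed by explicit loops on random tables."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            seq = rng.integers(0, 20, size=(3, 3))
            scr = rng.integers(0, 20, size=(3, 3))
            if seq.sum() == 0 or scr.sum() == 0:
                continue
            obs = np.vstack([seq.reshape(-1), scr.reshape(-1)])
            keep = obs.sum(axis=0) > 0
            obs = obs[:, keep]
            n = obs.sum()
            expected_stat = 0.0
            for i in range(2):
                for j in range(obs.shape[1]):
                    e = obs[i].sum() * obs[:, j].sum() / n
                    expected_stat += (obs[i, j] - e) ** 2 / e
            res = chi_square_contrast(seq, scr)
            assert res.statistic == pytest.approx(expected_stat)

    def test_relabeling_symmetry(self):
        rng = np.random.default_rng(7)
        seq = rng.integers(1, 10, size=(4, 4))
        scr = rng.integers(1, 10, size=(4, 4))
        perm = rng.permutation(4)
        a = chi_square_contrast(seq, scr)
        b = chi_square_contrast(seq[perm][:, perm], scr[perm][:, perm])
        assert a.statistic == pytest.approx(b.statistic)

    def test_direction_labels_follow_residual_sign(self):
        res = chi_square_contrast(np.array([[30, 5]]), np.array([[5, 30]]))
        cells = res.cells.set_index("sink")
        assert cells.loc["0", "direction"] == "Seq>Scr"
        assert cells.loc["1", "direction"] == "Seq<Scr"
        assert cells["significant"].all()

    def test_all_zero_rejected(self):
        z = np.zeros((2, 2))
        with pytest.raises(ValueError, match="all-zero"):
            chi_square_contrast(z, z)


def _fisher_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher p by full enumeration over fixed margins."""
    a, b = table[0]
    c, d = table[1]
    row0, col0, n = a + b, a + c, a + b + c + d

    def prob(k):
        return (
            math.comb(col0, k)
            * math.comb(n - col0, row0 - k)
            / math.comb(n, row0)
        )

    p_obs = prob(a)
    lo = max(0, row0 - (n - col0))
    hi = min(row0, col0)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


class TestFisherLateralization:
    def _site_table(self):
        return pd.DataFrame(
            {
                "subject_id": ["S01"] * 4,
                "site_id": ["tL", "fL", "tR", "fR"],
                "region": ["temporal", "frontal", "temporal", "frontal"],
                "hemisphere": ["L", "L", "R", "R"],
                "excluded": [False] * 4,
            }
        )

    def _couplets(self, n_match, n_other, condition):
        rows = []
        for _ in range(n_match):
            rows.append(("tL", "fL", "temporal", "frontal"))
        for _ in range(n_other):
            rows.append(("tR", "fR", "temporal", "frontal"))
        return pd.DataFrame(
            [
                {
                    "subject_id": "S01",
                    "source_site": s, "sink_site": k,
                    "source_region": sr, "sink_region": kr,
                    "condition": condition, "gc": 0.2, "p_value": 0.01,
                }
                for s, k, sr, kr in rows
            ]
        )

    def test_balanced_table_gives_p_one(self):
        p, table = fisher_lateralization(
            self._couplets(5, 5, "Seq"),
            self._couplets(5, 5, "Scr"),
            self._site_table(),
            (("temporal", "L"), ("frontal", "L")),
        )
        np.testing.assert_array_equal(table, [[5, 5], [5, 5]])
        assert p == pytest.approx(1.0)

    def test_extreme_table_hand_computation(self):
        p, table = fisher_lateralization(
            self._couplets(10, 0, "Seq"),
            self._couplets(0, 10, "Scr"),
            self._site_table(),
            (("temporal", "L"), ("frontal", "L")),
        )
        np.testing.assert_array_equal(table, [[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-6)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            t = rng.integers(1, 8, size=(2, 2))
            _, p_scipy = stats.fisher_exact(t, alternative="two-sided")
            assert p_scipy == pytest.approx(_fisher_enumeration(t), rel=1e-9)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_lateralization(
                self._couplets(0, 0, "Seq"),
                self._couplets(5, 5, "Scr"),
                self._site_table(),
                (("temporal", "L"), ("frontal", "L")),
            )
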