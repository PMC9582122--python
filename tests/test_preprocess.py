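"""Re-referencing, exclusion bookkeeping, epoching and baseline correction."""
import numpy as np
import pandas as pd
import pytest

from specnarr import (
    Recording,
    baseline_correct,
    common_average_reference,
    epoch_transitions,
    exclude_sites,
    generate_schedule,
    reference_site_table,
    simulate_recording,
    small_site_table,
)
from specnarr.preprocess import baseline_correct_epochs
from specnarr.schedule import ScheduleConfig


def _toy_recording(signals: np.ndarray, excluded=None) -> Recording:
    n = signals.shape[0]
    sites = pd.DataFrame(
        {
            "subject_id": ["S01"] * n,
            "site_id": [f"c{i}" for i in range(n)],
            "region": ["frontal"] * n,
            "hemisphere": ["L", "R"] * (n // 2) + ["L"] * (n % 2),
            "excluded": excluded if excluded is not None else [False] * n,
        }
    )
    return Recording({"S01": signals.astype(np.float32)}, sites, 1000.0)


class TestCommonAverageReference:
    def test_opposite_signals_unchanged(self):
        s = np.sin(np.linspace(0, 10, 500))[None, :]
        rec = _toy_recording(np.vstack([s, -s]))
        out = common_average_reference(rec)
        np.testing.assert_allclose(out.signals["S01"], rec.signals["S01"], atol=1e-6)

    def test_identical_signals_zeroed(self):
        s = np.random.default_rng(0).normal(size=(1, 300))
        rec = _toy_recording(np.repeat(s, 3, axis=0))
        out = common_average_reference(rec)
        np.testing.assert_allclose(out.signals["S01"], 0, atol=1e-5)

    def test_cross_site_mean_is_zero(self):
        rng = np.random.default_rng(1)
        rec = _toy_recording(rng.normal(size=(5, 400)))
        out = common_average_reference(rec)
        np.testing.assert_allclose(
            out.signals["S01"].mean(axis=0), 0, atol=1e-5
        )

    def test_excluded_sites_untouched_and_not_in_reference(self):
        rng = np.random.default_rng(2)
        sig = rng.normal(size=(4, 200))
        rec = _toy_recording(sig, excluded=[False, False, False, True])
        out = common_average_reference(rec)
        np.testing.assert_array_equal(out.signals["S01"][3], rec.signals["S01"][3])
        np.testing.assert_allclose(
            out.signals["S01"][:3].mean(axis=0), 0, atol=1e-5
        )

    def test_single_site_subject_rejected(self):
        rec = _toy_recording(np.zeros((1, 100)))
        with pytest.raises(ValueError, match="at least 2"):
            common_average_reference(rec)


class TestExcludeSites:
    def test_300_of_1270_leaves_970(self):
        sites = reference_site_table()
        assert len(sites) == 1270
        assert int(sites["excluded"].sum()) == 300
        assert int((~sites["excluded"]).sum()) == 970

    def test_exclusion_flags_sites(self):
        rec = _toy_recording(np.zeros((4, 100)))
        out = exclude_sites(rec, [("S01", "c0"), ("S01", "c2")])
        assert list(out.sites["excluded"]) == [True, False, True, False]
        # original untouched
        assert not rec.sites["excluded"].any()

    def test_empty_list_is_identity(self):
        rec = _toy_recording(np.zeros((3, 100)))
        out = exclude_sites(rec, [])
        pd.testing.assert_frame_equal(out.sites, rec.sites)

    def test_unknown_id_rejected(self):
        rec = _toy_recording(np.zeros((3, 100)))
        with pytest.raises(KeyError, match="unknown site"):
            exclude_sites(rec, [("S01", "nope")])

    def test_excluding_everything_rejected(self):
        rec = _toy_recording(np.zeros((2, 100)))
        with pytest.raises(ValueError, match="zero"):
            exclude_sites(rec, [("S01", "c0"), ("S01", "c1")])


@pytest.fixture(scope="module")
def study():
    schedule = generate_schedule()
    recording, _ = simulate_recording(small_site_table(1, 2), schedule, seed=0)
    return schedule, recording


class TestEpochTransitions:
    def test_default_universe_28_per_condition_per_site(self, study):
        schedule, recording = study
        epochs = epoch_transitions(recording, schedule)
        counts = epochs.meta.groupby(["site_id", "condition"]).size()
        assert (counts == 28).all()
        assert epochs.samples.shape[1] == 600

    def test_isi_to_image_adds_six_per_condition(self, study):
        schedule, recording = study
        epochs = epoch_transitions(
            recording, schedule, classes={"image_to_image", "isi_to_image"}
        )
        counts = epochs.meta.groupby(["site_id", "condition"]).size()
        assert (counts == 34).all()

    def test_all_series_initial_classes_add_seven(self, study):
        schedule, recording = study
        epochs = epoch_transitions(
            recording, schedule,
            classes={"image_to_image", "isi_to_image", "first_of_experiment"},
        )
        counts = epochs.meta.groupby(["site_id", "condition"]).size()
        assert (counts == 35).all()

    def test_empty_class_set_gives_empty(self, study):
        schedule, recording = study
        epochs = epoch_transitions(recording, schedule, classes=set())
        assert len(epochs) == 0

    def test_event_order_does_not_matter(self, study):
        schedule, recording = study
        shuffled = list(schedule)
        np.random.default_rng(0).shuffle(shuffled)
        a = epoch_transitions(recording, schedule)
        b = epoch_transitions(recording, shuffled)
        key = ["site_id", "condition", "series_index", "position_in_series"]
        ia = np.lexsort([a.meta[k] for k in key])
        ib = np.lexsort([b.meta[k] for k in key])
        np.testing.assert_array_equal(a.samples[ia], b.samples[ib])

    def test_event_near_edge_rejected(self, study):
        schedule, recording = study
        short = Recording(
            {"S01": recording.signals["S01"][:, :2000]},
            recording.sites,
            recording.sampling_rate,
        )
        with pytest.raises(ValueError, match="recording edge"):
            epoch_transitions(short, schedule)

    def test_car_commutes_with_epoching(self, study):
        """Re-reference-then-epoch equals epoch-then-per-sample mean removal."""
        schedule, recording = study
        referenced = common_average_reference(recording)
        a = epoch_transitions(referenced, schedule)
        b = epoch_transitions(recording, schedule)
        key = ["site_id", "condition", "series_index", "position_in_series"]
        ia = np.lexsort([a.meta[k] for k in key])
        # subtract the cross-site mean within each (event, sample)
        bm = b.meta.reset_index()
        corrected = b.samples.copy()
        for _, grp in bm.groupby(["condition", "series_index", "position_in_series"]):
            idx = grp["index"].to_numpy()
            corrected[idx] -= corrected[idx].mean(axis=0, keepdims=True)
        ib = np.lexsort([b.meta[k] for k in key])
        np.testing.assert_allclose(a.samples[ia], corrected[ib], atol=1e-4)


class TestBaselineCorrect:
    def test_ramp_oracle(self):
        ramp = np.arange(600, dtype=float)
        out = baseline_correct(ramp, (-100, 100))
        np.testing.assert_allclose(out, ramp - 99.5)

    def test_constant_epoch_zeroed(self):
        out = baseline_correct(np.full(600, 3.7), (-100, 50))
        np.testing.assert_allclose(out, 0, atol=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=600)
        a = baseline_correct(x, (-100, 100))
        b = baseline_correct(x + 42.0, (-100, 100))
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(7, 600))
        out = baseline_correct(x, (-100, 50))
        np.testing.assert_allclose(out[:, :150].mean(axis=1), 0, atol=1e-12)

    @pytest.mark.parametrize("window", [(-200, 0), (400, 600), (100, 100)])
    def test_invalid_baseline_window(self, window):
        with pytest.raises(ValueError):
            baseline_correct(np.zeros(600), window)

    def test_epochset_wrapper(self, null_study):
        epochs = null_study["epochs"]
        out = baseline_correct_epochs(epochs, (-100, 100))
        np.testing.assert_allclose(
            out.samples[:, :200].mean(axis=1), 0, atol=1e-4
        )
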