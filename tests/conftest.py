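"""Shared fixtures: small synthetic studies run through the spectral pipeline.

Everything is generated at test time from seeds; session scope amortizes the
heavier generations across test modules.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from specnarr import (
    CouplingSpec,
    EffectSpec,
    NoiseSpec,
    common_average_reference,
    compute_psds,
    condition_average,
    epoch_transitions,
    generate_schedule,
    normalize_psd_set,
    project_all_loso,
    simulate_recording,
    small_site_table,
)
from specnarr.schedule import FIRST_CLASSES

ALL_IMAGE_CLASSES = set(FIRST_CLASSES) | {"image_to_image"}


def run_spectral_pipeline(recording, schedule):
    """Recording -> re-reference -> epochs -> normalized PSDs -> projections."""
    referenced = common_average_reference(recording)
    epochs = epoch_transitions(referenced, schedule, classes=ALL_IMAGE_CLASSES)
    trial_psds = normalize_psd_set(compute_psds(epochs))
    analysis = trial_psds.select(
        (trial_psds.meta["transition_class"] == "image_to_image").to_numpy()
    )
    cond_avg = condition_average(analysis)
    projections = project_all_loso(cond_avg, trial_psds)
    return projections, cond_avg, trial_psds, epochs


def make_study(
    seed: int,
    gains: EffectSpec | None = None,
    coupling: CouplingSpec | None = None,
    n_subjects: int = 2,
    sites_per_subject: int = 10,
    regions=("frontal", "temporal"),
    noise: NoiseSpec | None = None,
):
    schedule = generate_schedule()
    sites = small_site_table(n_subjects, sites_per_subject, regions)
    recording, truth = simulate_recording(
        sites, schedule, effects=gains, coupling=coupling, noise=noise, seed=seed
    )
    return schedule, recording, truth


@pytest.fixture(scope="session")
def default_schedule():
    return generate_schedule()


@pytest.fixture(scope="session")
def effect_study():
    """4 subjects x 12 frontal/temporal sites with the default region effects
    (frontal Scr>Seq rest, temporal Seq>Scr rest, equal firsts)."""
    schedule, recording, truth = make_study(
        seed=11,
        gains=EffectSpec.narrative_default(),
        n_subjects=4,
        sites_per_subject=12,
    )
    projections, cond_avg, trial_psds, epochs = run_spectral_pipeline(
        recording, schedule
    )
    return {
        "schedule": schedule,
        "recording": recording,
        "truth": truth,
        "projections": projections,
        "cond_avg": cond_avg,
        "trial_psds": trial_psds,
        "epochs": epochs,
    }


@pytest.fixture(scope="session")
def null_study():
    """2 subjects x 10 sites, all gains equal, no coupling."""
    schedule, recording, truth = make_study(seed=7, gains=EffectSpec.null())
    projections, cond_avg, trial_psds, epochs = run_spectral_pipeline(
        recording, schedule
    )
    return {
        "schedule": schedule,
        "recording": recording,
        "projections": projections,
        "cond_avg": cond_avg,
        "trial_psds": trial_psds,
        "epochs": epochs,
    }
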