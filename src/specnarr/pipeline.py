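"""End-to-end orchestration: simulate -> preprocess -> spectra -> projections
-> encoding -> decoding -> connectivity, from one YAML-serializable config
and one master seed, with a machine-readable run report."""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    chi_square_contrast,
    condition_gc,
    identify_couplets,
    region_contingency,
)
from .decoding import accuracy_curve, rank_sites, split_trials
from .encoding import encode_sites, first_vs_rest_contrast
from .io import save_epochs, save_events, save_psd_matrix, save_recording
from .pca import project_all_loso
from .preprocess import common_average_reference, epoch_transitions
from .schedule import FIRST_CLASSES, ScheduleConfig, generate_schedule
from .simulate import (
    CouplingEdge,
    CouplingSpec,
    EffectSpec,
    NoiseSpec,
    simulate_recording,
    small_site_table,
)
from .spectral import compute_psds, condition_average, normalize_psd_set

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Everything a run needs; round-trips losslessly through YAML."""

    n_subjects: int = 4
    sites_per_subject: int = 12
    regions: tuple[str, ...] = ("frontal", "temporal", "parietal", "insula")
    schedule: dict[str, Any] = field(default_factory=dict)
    gains: dict[str, float] | str = "narrative_default"
    coupling: list[dict[str, Any]] | str = "narrative_default"
    noise: dict[str, Any] = field(default_factory=dict)
    alpha: float = 0.05
    n_perm: int = 10_000
    folds: int = 10
    n_train: int = 17
    test_fraction: float = 0.2
    decode_repeats: int = 10
    decode_sizes: list[int] | None = None
    gc_order: int | None = None
    gc_max_order: int = 20
    gc_max_sites_per_subject: int = 12
    run_connectivity: bool = True

    def schedule_config(self) -> ScheduleConfig:
        return ScheduleConfig(**self.schedule)

    def effect_spec(self) -> EffectSpec:
        if self.gains == "narrative_default":
            return EffectSpec.narrative_default()
        if self.gains == "null":
            return EffectSpec.null()
        gains = {}
        for key, value in dict(self.gains).items():
            region, condition, group = key.split("/")
            gains[(region, condition, group)] = float(value)
        return EffectSpec(gains)

    def coupling_spec(self) -> CouplingSpec:
        if self.coupling == "narrative_default":
            return CouplingSpec.narrative_default()
        if self.coupling in ("none", "null"):
            return CouplingSpec.none()
        return CouplingSpec([CouplingEdge(**e) for e in self.coupling])

    def noise_spec(self) -> NoiseSpec:
        kwargs = dict(self.noise)
        if "broadband_band" in kwargs:
            kwargs["broadband_band"] = tuple(kwargs["broadband_band"])
        return NoiseSpec(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["regions"] = list(data["regions"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "regions" in data:
            data["regions"] = tuple(data["regions"])
        return cls(**data)


def run_all(config: RunConfig, seed: int, out_dir: str | Path | None = None) -> dict:
    """Run every stage in order; identical config and seed give identical
    outputs.  Returns the run report (also written to ``report.json``)."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    schedule = generate_schedule(config.schedule_config())
    sites = small_site_table(
        config.n_subjects, config.sites_per_subject, config.regions
    )
    recording, truth = simulate_recording(
        sites,
        schedule,
        effects=config.effect_spec(),
        coupling=config.coupling_spec(),
        noise=config.noise_spec(),
        seed=seed,
    )
    if out is not None:
        save_recording(recording, out, truth)
        save_events(schedule, out / "events.csv")

    referenced = common_average_reference(recording)
    all_classes = set(FIRST_CLASSES) | {"image_to_image"}
    epochs = epoch_transitions(referenced, schedule, classes=all_classes)
    if out is not None:
        save_epochs(epochs, out)

    trial_psds = normalize_psd_set(compute_psds(epochs))
    analysis = trial_psds.select(
        (trial_psds.meta["transition_class"] == "image_to_image").to_numpy()
    )
    cond_avg = condition_average(analysis)
    if out is not None:
        save_psd_matrix(cond_avg, out / "psd_condition_average.csv")

    projections = project_all_loso(cond_avg, trial_psds)
    if out is not None:
        projections.to_csv(out / "projections.csv", index=False)

    trial_ids = projections.loc[
        projections["transition_class"] == "image_to_image", "trial_id"
    ].unique()
    train_ids, test_ids = split_trials(
        trial_ids, test_fraction=config.test_fraction, seed=seed
    )
    results = encode_sites(
        projections,
        pool_trial_ids=set(train_ids),
        folds=config.folds,
        n_train=config.n_train,
        n_perm=config.n_perm,
        alpha=config.alpha,
        seed=seed,
    )
    if out is not None:
        results.to_csv(out / "encoding_results.csv", index=False)

    contrast_regions = tuple(
        r for r in ("frontal", "temporal") if r in config.regions
    )
    fr_summary = fr_tests = None
    if contrast_regions:
        fr_summary, fr_tests = first_vs_rest_contrast(
            projections, regions=contrast_regions
        )
        if out is not None:
            fr_summary.to_csv(out / "first_vs_rest_summary.csv", index=False)
            fr_tests.to_csv(out / "first_vs_rest_tests.csv", index=False)

    ranked = rank_sites(results)
    curve = accuracy_curve(
        projections,
        ranked,
        test_ids,
        sizes=config.decode_sizes,
        repeats=config.decode_repeats,
        seed=seed,
    )
    if out is not None:
        curve.to_csv(out / "decoding_curve.csv", index=False)

    report: dict[str, Any] = {
        "software_version": __version__,
        "seed": int(seed),
        "n_subjects": int(config.n_subjects),
        "n_sites": int(recording.n_sites()),
        "n_sites_included": int(recording.n_sites(included_only=True)),
        "n_events": len(schedule),
        "n_epochs": len(epochs),
        "n_trial_psds": len(trial_psds),
        "n_condition_avg_psds": len(cond_avg),
        "n_train_trials": len(train_ids),
        "n_test_trials": len(test_ids),
        "n_sites_encoded": int(len(results)),
        "n_significant_sites": int(results["significant"].sum()),
        "significant_sites": [
            f"{r.subject_id}/{r.site_id}"
            for r in results[results["significant"]].itertuples()
        ],
        "peak_decoding_accuracy": float(curve["mean_accuracy"].max()),
    }

    if config.run_connectivity:
        rng = np.random.default_rng(seed)
        keep_rows = []
        for subject, grp in epochs.meta.groupby("subject_id"):
            site_ids = sorted(grp["site_id"].unique())
            if len(site_ids) > config.gc_max_sites_per_subject:
                site_ids = sorted(
                    rng.choice(
                        site_ids, size=config.gc_max_sites_per_subject, replace=False
                    )
                )
            keep_rows.append(
                (epochs.meta["subject_id"] == subject)
                & epochs.meta["site_id"].isin(site_ids)
                & (epochs.meta["transition_class"] == "image_to_image")
            )
        gc_mask = np.logical_or.reduce([m.to_numpy() for m in keep_rows])
        gc_results = condition_gc(
            epochs.select(gc_mask),
            order=config.gc_order,
            max_order=config.gc_max_order,
        )
        couplets = identify_couplets(gc_results, alpha=config.alpha)
        seq_tab = region_contingency(couplets[couplets["condition"] == "Seq"])
        scr_tab = region_contingency(couplets[couplets["condition"] == "Scr"])
        if out is not None:
            couplets.to_csv(out / "couplets.csv", index=False)
            seq_tab.to_csv(out / "contingency_seq.csv")
            scr_tab.to_csv(out / "contingency_scr.csv")
        report["n_couplets_seq"] = int((couplets["condition"] == "Seq").sum())
        report["n_couplets_scr"] = int((couplets["condition"] == "Scr").sum())
        if seq_tab.to_numpy().sum() + scr_tab.to_numpy().sum() > 0:
            try:
                contrast = chi_square_contrast(seq_tab, scr_tab, alpha=config.alpha)
                if out is not None:
                    contrast.cells.to_csv(out / "contrast_cells.csv", index=False)
                report["contingency_chi2"] = contrast.statistic
                report["contingency_p"] = contrast.p_value
                report["significant_cells"] = [
                    f"{c.source}->{c.sink} ({c.direction})"
                    for c in contrast.cells[contrast.cells["significant"]].itertuples()
                ]
            except ValueError as err:
                log.warning("contingency contrast skipped: %s", err)

    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
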