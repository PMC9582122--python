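"""Synthetic multi-subject LFP generator with known ground truth.

Each recording site carries a 1/f ("pink") background plus a band-limited
(10-100 Hz) broadband component.  Condition- and region-specific effects are
injected by multiplying the broadband component's amplitude inside the
100-500 ms post-onset response window of every image event, with separate
gains for the first transition of an image series versus the remaining
("rest") transitions — a two-level habituation profile.  Directed coupling is
injected as a lagged linear contribution from a source site to a sink site,
active only inside the response windows of the edge's condition, so
Granger-causal ground truth is well defined.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.fft as sfft

from ._utils import child_rng
from .schedule import FIRST_CLASSES, StimulusEvent

__all__ = [
    "REGIONS",
    "SiteSpec",
    "EffectSpec",
    "CouplingEdge",
    "CouplingSpec",
    "NoiseSpec",
    "GroundTruth",
    "Recording",
    "simulate_recording",
    "reference_site_table",
    "small_site_table",
]

log = logging.getLogger(__name__)

REGIONS = (
    "frontal",
    "temporal",
    "parietal",
    "insula",
    "occipital",
    "basal_ganglia",
)

RESPONSE_WINDOW_MS = (100.0, 500.0)  # post-onset window carrying the effect


@dataclass(frozen=True)
class SiteSpec:
    subject_id: str
    site_id: str
    region: str
    hemisphere: str  # "L" | "R"
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.hemisphere not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")


class EffectSpec:
    """Per-region broadband gain for (condition x {first, rest}) transitions.

    Gains are dimensionless multipliers on the broadband component amplitude
    inside the response window; unspecified cells default to 1 (no effect).
    """

    def __init__(self, gains: Mapping[tuple[str, str, str], float] | None = None):
        self._gains: dict[tuple[str, str, str], float] = dict(gains or {})
        for key, g in self._gains.items():
            if g <= 0:
                raise ValueError(f"gain for {key} must be positive, got {g}")
            region, _cond, group = key
            if region not in REGIONS:
                raise ValueError(f"unknown region in gain key: {key}")
            if group not in ("first", "rest"):
                raise ValueError(f"transition group must be 'first' or 'rest': {key}")

    def gain(self, region: str, condition: str, group: str) -> float:
        return self._gains.get((region, condition, group), 1.0)

    def items(self):
        return self._gains.items()

    @classmethod
    def null(cls) -> "EffectSpec":
        """All gains 1: the two conditions are statistically indistinguishable."""
        return cls({})

    @classmethod
    def narrative_default(
        cls, first: float = 1.25, high: float = 1.5, low: float = 1.0
    ) -> "EffectSpec":
        """Default study effects.

        Frontal sites respond more to scrambled than sequential transitions
        after the first one (persistent contextual novelty); temporal sites
        show the mirrored preference for the coherent narrative; the first
        transition of a series is equal across conditions in both regions.
        """
        return cls(
            {
                ("frontal", "Scr", "first"): first,
                ("frontal", "Seq", "first"): first,
                ("frontal", "Scr", "rest"): high,
                ("frontal", "Seq", "rest"): low,
                ("temporal", "Scr", "first"): first,
                ("temporal", "Seq", "first"): first,
                ("temporal", "Scr", "rest"): low,
                ("temporal", "Seq", "rest"): high,
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": r, "condition": c, "transition_group": g, "gain": v}
            for (r, c, g), v in sorted(self._gains.items())
        ]
        return pd.DataFrame(
            rows, columns=["region", "condition", "transition_group", "gain"]
        )


@dataclass(frozen=True)
class CouplingEdge:
    source_region: str
    sink_region: str
    condition: str
    lag: int  # samples
    coefficient: float

    def __post_init__(self) -> None:
        if self.source_region not in REGIONS or self.sink_region not in REGIONS:
            raise ValueError("coupling edge references an unknown region")
        if self.lag < 1:
            raise ValueError("coupling lag must be >= 1 sample")
        if not abs(self.coefficient) < 1:
            raise ValueError(
                f"|coefficient| must be < 1 for stability, got {self.coefficient}"
            )


@dataclass
class CouplingSpec:
    edges: list[CouplingEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        for condition in {e.condition for e in self.edges}:
            self._toposort(condition)

    def _toposort(self, condition: str) -> list[CouplingEdge]:
        """Order edges so sources are finalized before their sinks.

        The region-level graph per condition must be acyclic; feedback loops
        would make the feed-forward injection ill-defined and are rejected.
        """
        edges = [e for e in self.edges if e.condition == condition]
        graph: dict[str, set[str]] = {}
        for e in edges:
            graph.setdefault(e.source_region, set()).add(e.sink_region)
            graph.setdefault(e.sink_region, set())
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            if state.get(node) == 1:
                raise ValueError(
                    f"coupling graph for condition {condition!r} contains a cycle "
                    f"involving region {node!r}; feedback coupling is not supported"
                )
            if state.get(node) == 2:
                return
            state[node] = 1
            for nxt in graph[node]:
                visit(nxt)
            state[node] = 2
            order.append(node)

        for node in graph:
            visit(node)
        rank = {r: i for i, r in enumerate(reversed(order))}
        return sorted(edges, key=lambda e: rank[e.source_region])

    def ordered_edges(self, condition: str) -> list[CouplingEdge]:
        return self._toposort(condition)

    @classmethod
    def none(cls) -> "CouplingSpec":
        return cls([])

    @classmethod
    def narrative_default(cls, lag: int = 5, coefficient: float = 0.5) -> "CouplingSpec":
        """Default directed effects: temporal lobe leads frontal, insular and
        parietal regions during the sequential condition; parietal leads
        temporal during the scrambled condition."""
        return cls(
            [
                CouplingEdge("temporal", "frontal", "Seq", lag, coefficient),
                CouplingEdge("temporal", "insula", "Seq", lag, coefficient),
                CouplingEdge("temporal", "parietal", "Seq", lag, coefficient),
                CouplingEdge("parietal", "temporal", "Scr", lag, coefficient),
            ]
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Background model: 1/f^exponent noise plus a 10-100 Hz broadband
    component whose amplitude carries the injected effects."""

    exponent: float = 1.0
    background_amplitude: float = 1.0
    broadband_amplitude: float = 0.5
    broadband_band: tuple[float, float] = (10.0, 100.0)
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise ValueError("1/f exponent must be >= 0")
        if self.background_amplitude < 0 or self.broadband_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        lo, hi = self.broadband_band
        if not (0 < lo < hi <= self.sampling_rate / 2):
            raise ValueError("broadband band must satisfy 0 < lo < hi <= Nyquist")


@dataclass
class GroundTruth:
    gains: pd.DataFrame  # region, condition, transition_group, gain
    edges: pd.DataFrame  # subject_id, source_site, sink_site, condition, lag, coefficient


@dataclass
class Recording:
    """Multichannel recording: one (sites x samples) array per subject plus a
    site table whose row order defines each subject's channel order."""

    signals: dict[str, np.ndarray]
    sites: pd.DataFrame
    sampling_rate: float

    def subject_sites(self, subject_id: str) -> pd.DataFrame:
        return self.sites[self.sites["subject_id"] == subject_id].reset_index(drop=True)

    @property
    def subjects(self) -> list[str]:
        return list(self.signals.keys())

    def n_sites(self, included_only: bool = False) -> int:
        if included_only:
            return int((~self.sites["excluded"]).sum())
        return len(self.sites)

    def copy(self) -> "Recording":
        return Recording(
            {s: a.copy() for s, a in self.signals.items()},
            self.sites.copy(),
            self.sampling_rate,
        )


def sites_to_frame(sites: Sequence[SiteSpec]) -> pd.DataFrame:
    frame = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "site_id": s.site_id,
                "region": s.region,
                "hemisphere": s.hemisphere,
                "excluded": bool(s.excluded),
            }
            for s in sites
        ],
        columns=["subject_id", "site_id", "region", "hemisphere", "excluded"],
    )
    if frame.duplicated(["subject_id", "site_id"]).any():
        raise ValueError("(subject_id, site_id) pairs must be unique")
    return frame


def _spectral_noise(rng: np.random.Generator, shape: tuple[int, int],
                    scale: np.ndarray, n_fft: int) -> np.ndarray:
    """Gaussian noise with amplitude spectrum ``scale``, unit variance per
    channel, drawn directly in the frequency domain (one inverse FFT)."""
    n = shape[1]
    n_bins = n_fft // 2 + 1
    spec = rng.standard_normal((shape[0], n_bins), dtype=np.float32).astype(
        np.complex64
    )
    spec.imag = rng.standard_normal((shape[0], n_bins), dtype=np.float32)
    spec *= scale.astype(np.float32)
    out = sfft.irfft(spec, n=n_fft, axis=1)[:, :n]
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int], exponent: float,
                fs: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping, unit variance per channel."""
    n_fft = sfft.next_fast_len(shape[1], real=True)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    return _spectral_noise(rng, shape, scale, n_fft)


def _band_noise(rng: np.random.Generator, shape: tuple[int, int],
                band: tuple[float, float], fs: float) -> np.ndarray:
    """Band-limited white noise, unit variance per channel."""
    n_fft = sfft.next_fast_len(shape[1], real=True)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    scale = ((freqs >= band[0]) & (freqs <= band[1])).astype(float)
    return _spectral_noise(rng, shape, scale, n_fft)


def _response_slices(events: Sequence[StimulusEvent], condition: str, fs: float,
                     n_samples: int) -> list[slice]:
    lo, hi = RESPONSE_WINDOW_MS
    out = []
    for e in events:
        if e.kind != "image" or e.condition != condition:
            continue
        a = int(round((e.onset_ms + lo) * fs / 1000.0))
        b = int(round((e.onset_ms + hi) * fs / 1000.0))
        out.append(slice(max(a, 0), min(b, n_samples)))
    return out


def simulate_recording(
    sites: Sequence[SiteSpec] | pd.DataFrame,
    schedule: Sequence[StimulusEvent],
    effects: EffectSpec | None = None,
    coupling: CouplingSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    tail_ms: float = 1000.0,
) -> tuple[Recording, GroundTruth]:
    """Simulate per-site LFP covering the schedule; same seed, same samples.

    Per-subject generators are derived from the master seed and the subject
    id, so adding a subject never changes another subject's samples.
    """
    effects = effects if effects is not None else EffectSpec.null()
    coupling = coupling if coupling is not None else CouplingSpec.none()
    noise = noise if noise is not None else NoiseSpec()
    site_table = sites if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
    if site_table.duplicated(["subject_id", "site_id"]).any():
        raise ValueError("(subject_id, site_id) pairs must be unique")
    if (~site_table["excluded"]).sum() < 1:
        raise ValueError("need at least one non-excluded site")
    if not schedule:
        raise ValueError("schedule is empty")

    fs = noise.sampling_rate
    end_ms = max(
        e.onset_ms + (6000.0 if e.kind == "gray" else 2000.0) for e in schedule
    )
    n_samples = int(round((end_ms + tail_ms) * fs / 1000.0))
    conditions = sorted({e.condition for e in schedule})
    cond_slices = {c: _response_slices(schedule, c, fs, n_samples) for c in conditions}

    # per-event gain profile is region x condition x {first, rest}
    def gain_profile(region: str) -> np.ndarray:
        prof = np.ones(n_samples)
        for e in schedule:
            if e.kind != "image":
                continue
            group = "first" if e.transition_class in FIRST_CLASSES else "rest"
            g = effects.gain(region, e.condition, group)
            if g != 1.0:
                a = int(round((e.onset_ms + RESPONSE_WINDOW_MS[0]) * fs / 1000.0))
                b = int(round((e.onset_ms + RESPONSE_WINDOW_MS[1]) * fs / 1000.0))
                prof[a:b] = g
        return prof

    signals: dict[str, np.ndarray] = {}
    edge_rows: list[dict] = []
    for subject_id, sub in site_table.groupby("subject_id", sort=True):
        sub = sub.reset_index(drop=True)
        rng = child_rng(seed, "simulate", str(subject_id))
        n_ch = len(sub)
        bg = _pink_noise(rng, (n_ch, n_samples), noise.exponent, fs)
        bb = _band_noise(rng, (n_ch, n_samples), noise.broadband_band, fs)
        sig = noise.background_amplitude * bg
        profiles = {r: gain_profile(r) for r in sub["region"].unique()}
        for ch in range(n_ch):
            sig[ch] += noise.broadband_amplitude * profiles[sub.loc[ch, "region"]] * bb[ch]

        # coupling: topological order per condition so chains propagate
        region_idx = {
            r: sub.index[sub["region"] == r].to_numpy() for r in sub["region"].unique()
        }
        for condition in conditions:
            mask = np.zeros(n_samples, dtype=bool)
            for sl in cond_slices[condition]:
                mask[sl] = True
            for edge in coupling.ordered_edges(condition):
                src_pool = region_idx.get(edge.source_region, np.array([], dtype=int))
                sink_pool = region_idx.get(edge.sink_region, np.array([], dtype=int))
                if src_pool.size == 0 or sink_pool.size == 0:
                    continue
                for sink in sink_pool:
                    choices = src_pool[src_pool != sink]
                    if choices.size == 0:
                        log.warning(
                            "no eligible source site for %s in subject %s; edge skipped",
                            edge, subject_id,
                        )
                        continue
                    src = int(rng.choice(choices))
                    shifted = np.zeros(n_samples)
                    shifted[edge.lag:] = sig[src, : n_samples - edge.lag]
                    sig[sink, mask] += edge.coefficient * shifted[mask]
                    edge_rows.append(
                        {
                            "subject_id": subject_id,
                            "source_site": sub.loc[src, "site_id"],
                            "sink_site": sub.loc[sink, "site_id"],
                            "source_region": edge.source_region,
                            "sink_region": edge.sink_region,
                            "condition": condition,
                            "lag": edge.lag,
                            "coefficient": edge.coefficient,
                        }
                    )
        signals[str(subject_id)] = sig.astype(np.float32)

    # keep the site table ordered the same way signals were generated
    ordered = (
        site_table.sort_values(["subject_id"], kind="stable")
        .reset_index(drop=True)
    )
    recording = Recording(signals, ordered, fs)
    truth = GroundTruth(
        gains=effects.to_frame(),
        edges=pd.DataFrame(
            edge_rows,
            columns=[
                "subject_id", "source_site", "sink_site", "source_region",
                "sink_region", "condition", "lag", "coefficient",
            ],
        ),
    )
    return recording, truth


# ---------------------------------------------------------------------------
# Site inventories


_REGION_CENSUS = {
    # region: (left count, right count, number of carrying subjects)
    "frontal": (176, 179, 10),
    "temporal": (201, 195, 13),
    "insula": (15, 28, 7),
    "occipital": (8, 15, 2),
    "parietal": (41, 78, 12),
    "basal_ganglia": (21, 13, 7),
}


def reference_site_table(n_excluded: int = 300) -> pd.DataFrame:
    """Synthetic 13-subject site census emulating the study's regional
    distribution of 970 analyzed sites, plus ``n_excluded`` flagged sites."""
    subjects = [f"S{i + 1:02d}" for i in range(13)]
    rows = []
    for region, (n_left, n_right, n_subj) in _REGION_CENSUS.items():
        carriers = subjects[:n_subj]
        for hemisphere, count in (("L", n_left), ("R", n_right)):
            for k in range(count):
                rows.append(
                    {
                        "subject_id": carriers[k % n_subj],
                        "region": region,
                        "hemisphere": hemisphere,
                        "excluded": False,
                    }
                )
    for k in range(n_excluded):
        rows.append(
            {
                "subject_id": subjects[k % len(subjects)],
                "region": ("temporal", "frontal")[k % 2],
                "hemisphere": ("L", "R")[(k // 2) % 2],
                "excluded": True,
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(["subject_id", "region", "hemisphere"], kind="stable")
    frame = frame.reset_index(drop=True)
    frame["site_id"] = [
        f"{sub}-c{idx:03d}"
        for sub, idx in zip(
            frame["subject_id"], frame.groupby("subject_id").cumcount()
        )
    ]
    return frame[["subject_id", "site_id", "region", "hemisphere", "excluded"]]


def small_site_table(
    n_subjects: int = 2,
    sites_per_subject: int = 10,
    regions: Sequence[str] = ("frontal", "temporal"),
) -> pd.DataFrame:
    """Compact inventory for desk-scale runs: regions cycle within subject."""
    rows = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        for c in range(sites_per_subject):
            rows.append(
                {
                    "subject_id": subject,
                    "site_id": f"{subject}-c{c:03d}",
                    "region": regions[c % len(regions)],
                    "hemisphere": ("L", "R")[c % 2],
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows)
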