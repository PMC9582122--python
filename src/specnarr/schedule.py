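"""Stimulus schedule for the two-condition visual-narrative task.

The task presents 7 series of 5 cartoon images (2 s each), with a 6 s gray
screen after every series, first with the images in scrambled order across
stories (``Scr``) and then in each story's chronological order (``Seq``).
Every image onset is tagged with the transition it realizes: the very first
image of a condition block, a gray-screen-to-image transition at the start of
a later series, or a within-series image-to-image transition.  Gray-screen
onsets are tagged ``image_to_isi``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CONDITIONS",
    "TRANSITION_CLASSES",
    "FIRST_CLASSES",
    "ScheduleConfig",
    "StimulusEvent",
    "generate_schedule",
    "events_to_frame",
    "frame_to_events",
]

CONDITIONS = ("Scr", "Seq")
TRANSITION_CLASSES = (
    "first_of_experiment",
    "isi_to_image",
    "image_to_image",
    "image_to_isi",
)
#: classes that realize the first (gray-to-image) transition of an image series
FIRST_CLASSES = ("first_of_experiment", "isi_to_image")


@dataclass(frozen=True)
class ScheduleConfig:
    """Timing parameters of the block-design presentation.

    Defaults are the study conditions: 7 series x 5 images x 2000 ms, 6000 ms
    inter-series gray screens, scrambled block before sequential block.
    ``lead_in_ms`` shifts the first onset away from the recording start so
    that peri-onset windows never clip the recording edge.
    """

    n_series: int = 7
    images_per_series: int = 5
    image_duration_ms: float = 2000.0
    isi_duration_ms: float = 6000.0
    condition_order: tuple[str, str] = ("Scr", "Seq")
    lead_in_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_series < 0 or self.images_per_series < 0:
            raise ValueError("series/image counts must be non-negative")
        if self.image_duration_ms <= 0 or self.isi_duration_ms <= 0:
            raise ValueError("durations must be positive")
        if self.lead_in_ms < 0:
            raise ValueError("lead_in_ms must be non-negative")
        if len(self.condition_order) != 2 or len(set(self.condition_order)) != 2:
            raise ValueError("condition_order must be two distinct labels")


@dataclass(frozen=True)
class StimulusEvent:
    onset_ms: float
    kind: str  # "image" | "gray"
    condition: str
    series_index: int  # 0-based
    position_in_series: int | None  # 0-based; None for gray events
    transition_class: str

    def __post_init__(self) -> None:
        if self.kind not in ("image", "gray"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.transition_class not in TRANSITION_CLASSES:
            raise ValueError(f"unknown transition class {self.transition_class!r}")


def generate_schedule(config: ScheduleConfig = ScheduleConfig()) -> list[StimulusEvent]:
    """Lay out both condition blocks on one recording clock.

    Per block: ``n_series`` series of ``images_per_series`` image events at
    ``image_duration_ms`` spacing, each series followed by one gray event of
    ``isi_duration_ms``.  The second block starts where the first ends.
    """
    events: list[StimulusEvent] = []
    t = float(config.lead_in_ms)
    for condition in config.condition_order:
        for series in range(config.n_series):
            for pos in range(config.images_per_series):
                if series == 0 and pos == 0:
                    klass = "first_of_experiment"
                elif pos == 0:
                    klass = "isi_to_image"
                else:
                    klass = "image_to_image"
                events.append(
                    StimulusEvent(t, "image", condition, series, pos, klass)
                )
                t += config.image_duration_ms
            events.append(
                StimulusEvent(t, "gray", condition, series, None, "image_to_isi")
            )
            t += config.isi_duration_ms
    return events


def events_to_frame(events: Iterable[StimulusEvent]) -> pd.DataFrame:
    rows = [
        {
            "onset_ms": e.onset_ms,
            "kind": e.kind,
            "condition": e.condition,
            "series_index": e.series_index,
            "position_in_series": e.position_in_series,
            "transition_class": e.transition_class,
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "onset_ms",
            "kind",
            "condition",
            "series_index",
            "position_in_series",
            "transition_class",
        ],
    )


def frame_to_events(frame: pd.DataFrame) -> list[StimulusEvent]:
    events = []
    for row in frame.itertuples(index=False):
        pos = row.position_in_series
        pos = None if pd.isna(pos) else int(pos)
        events.append(
            StimulusEvent(
                float(row.onset_ms),
                str(row.kind),
                str(row.condition),
                int(row.series_index),
                pos,
                str(row.transition_class),
            )
        )
    return events
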