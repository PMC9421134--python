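"""Stressful-event identification and resting/reactivity segmentation.

Two event sources exist: self-marked events (a tap on the chest sensor
when the wearer starts to feel stressed) and device-detected physically
stressful events (sustained bouts of moderate-to-vigorous activity,
>= 3 MET for >= 5 min).  Both are anchored to a marker minute m; the
resting window is minutes [m-5, m-1] and the reactivity window is
[m+1, m+5] — the tap minute itself is transitional and belongs to
neither.  The reactivity outcome is the raw RMSSD difference
(reactivity - resting), with a 0/1 direction dummy (1 = increase).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hrv import SEGMENT_MINUTES, Segment, segment_rmssd

__all__ = [
    "StressMarker",
    "EventRecord",
    "filter_markers",
    "detect_physical_events",
    "build_event_record",
]

log = logging.getLogger(__name__)

#: Moderate-activity cut-off (MET) for device-detected events.
MET_THRESHOLD = 3.0
#: Minimum bout duration (minutes) for a device-detected event.
MIN_BOUT_MINUTES = 5
#: Minimum self-reported event duration (minutes); shorter events excluded.
MIN_EVENT_DURATION = 5.0


@dataclass
class StressMarker:
    person_id: str
    minute: int  # minute index on the person's recording grid
    source: str  # "self" | "device"
    excluded_reason: str = "none"  # none|not_worn|same_segment|accidental|too_short

    @property
    def kept(self) -> bool:
        return self.excluded_reason == "none"


@dataclass
class EventRecord:
    """One analyzable stressful event: the reactivity-model row."""

    person_id: str
    event_id: int
    marker: StressMarker
    resting: Segment
    reactivity: Segment
    delta_rmssd: float
    direction: int  # 1 = RMSSD increased during the event, 0 = decreased
    missing: bool
    missing_reason: str = ""


def filter_markers(
    markers: Sequence[StressMarker],
    minutes: pd.DataFrame,
    accident_flags: Sequence[bool],
    diary_durations: Sequence[float],
) -> list[StressMarker]:
    """Apply the four marker-validity rules and record exclusion reasons.

    (a) marker set while the sensor was not worn -> ``not_worn``;
    (c) marker reported in the diary as set by accident -> ``accidental``;
    (d) matched diary duration < 5 min -> ``too_short`` (markers without
    a matched duration are kept — the rule cannot be evaluated);
    (b) marker falling inside the reactivity 5-min segment of the
    previous *kept* marker -> ``same_segment``, applied last and
    chronologically so survivors are maximal and deterministic.

    Each excluded marker carries exactly one reason, the first that
    fires in the order a, c, d, b.
    """
    markers = sorted(markers, key=lambda m: m.minute)
    worn = minutes.loc[minutes["worn"].astype(bool), "minute"]
    worn_set = set(int(v) for v in worn)

    out: list[StressMarker] = []
    for mk, acc, dur in zip(markers, accident_flags, diary_durations, strict=True):
        reason = "none"
        if mk.minute not in worn_set:
            reason = "not_worn"
        elif acc:
            reason = "accidental"
        elif dur is not None and np.isfinite(dur) and dur < MIN_EVENT_DURATION:
            reason = "too_short"
        out.append(StressMarker(mk.person_id, mk.minute, mk.source, reason))

    last_kept: StressMarker | None = None
    for mk in out:
        if mk.excluded_reason != "none":
            continue
        if (
            last_kept is not None
            and last_kept.minute + 1 <= mk.minute <= last_kept.minute + SEGMENT_MINUTES
        ):
            mk.excluded_reason = "same_segment"
        else:
            last_kept = mk
    return out


def detect_physical_events(
    minutes: pd.DataFrame,
    threshold: float = MET_THRESHOLD,
    min_duration: int = MIN_BOUT_MINUTES,
    kept_self_minutes: Iterable[int] = (),
) -> list[StressMarker]:
    """Locate sustained high-MET bouts and mark their first minute.

    A bout is a maximal run of consecutive worn minutes with
    ``met >= threshold``; runs shorter than ``min_duration`` are
    discarded.  Runs that overlap the reactivity window [m+1, m+5] of a
    kept self-marker yield no device marker (the event is already
    represented).
    """
    person = str(minutes["person_id"].iloc[0]) if "person_id" in minutes else ""
    df = minutes.sort_values("minute")
    mins = df["minute"].to_numpy(dtype=int)
    hot = (df["met"].to_numpy(dtype=float) >= threshold) & df["worn"].to_numpy(dtype=bool)

    react_windows = [(m + 1, m + SEGMENT_MINUTES) for m in kept_self_minutes]
    out: list[StressMarker] = []
    i = 0
    n = len(mins)
    while i < n:
        if not hot[i]:
            i += 1
            continue
        j = i
        # consecutive minute indices keep the run alive; a gap breaks it
        while j + 1 < n and hot[j + 1] and mins[j + 1] == mins[j] + 1:
            j += 1
        run_start, run_end = int(mins[i]), int(mins[j])
        if run_end - run_start + 1 >= min_duration:
            overlaps = any(run_start <= hi and run_end >= lo for lo, hi in react_windows)
            if not overlaps:
                out.append(StressMarker(person, run_start, "device"))
        i = j + 1
    return out


def build_event_record(
    marker: StressMarker,
    minutes: pd.DataFrame,
    event_id: int = 0,
    min_coverage: float = 0.8,
) -> EventRecord:
    """Build the resting/reactivity pair and reactivity outcome for a kept marker.

    The record is flagged missing (and later deleted listwise) when
    either segment's RMSSD is undefined, including markers set within
    5 min of the recording start where no resting window exists.
    """
    m = marker.minute
    resting = segment_rmssd(minutes, m - SEGMENT_MINUTES, min_coverage)
    reactivity = segment_rmssd(minutes, m + 1, min_coverage)
    missing = not (resting.defined and reactivity.defined)
    reason = ""
    if missing:
        parts = []
        if not resting.defined:
            parts.append(f"resting:{resting.reason}")
        if not reactivity.defined:
            parts.append(f"reactivity:{reactivity.reason}")
        reason = ";".join(parts)
        delta, direction = float("nan"), 0
    else:
        delta = reactivity.rmssd - resting.rmssd
        if delta == 0.0:
            log.warning(
                "event %s person %s: reactivity equals resting RMSSD; "
                "direction coded 0 (decrease)",
                event_id,
                marker.person_id,
            )
        direction = int(delta > 0)
    return EventRecord(
        person_id=marker.person_id,
        event_id=event_id,
        marker=marker,
        resting=resting,
        reactivity=reactivity,
        delta_rmssd=delta,
        direction=direction,
        missing=missing,
        missing_reason=reason,
    )
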