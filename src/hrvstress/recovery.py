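"""Recovery time: diary-to-marker matching and sliding-window return-to-baseline.

Recovery is the number of minutes after a stressful event's end until
vagally-mediated HRV returns to the pre-event resting level.  The end
of the event comes from the bihourly diary (self-reported duration
added to the marker minute).  From the end, 5-min RMSSD windows are
slid forward in 1-min steps; the first shift k at which the window's
RMSSD crosses the resting RMSSD in the restorative direction gives
recovery_minutes = k.  Two censoring mechanisms apply: a subsequent
marker intruding before a window qualifies (pile-up) and more than
120 min elapsing (timeout).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .hrv import SEGMENT_MINUTES, Segment, segment_rmssd

__all__ = [
    "DiaryEventReport",
    "RecoveryResult",
    "RECOVERY_TIMEOUT",
    "MATCH_WINDOW",
    "match_reports_to_markers",
    "locate_event_end",
    "compute_recovery",
]

#: Censoring horizon (minutes of elapsed shift k).
RECOVERY_TIMEOUT = 120
#: Diary report <-> marker maximum separation (minutes, inclusive).
MATCH_WINDOW = 120


@dataclass(frozen=True)
class DiaryEventReport:
    person_id: str
    diary_minute: int
    reported_start_minute: int
    reported_duration: float  # minutes; NaN when the field was left blank


@dataclass(frozen=True)
class RecoveryResult:
    event_id: int
    recovery_minutes: float  # defined iff status == "reached"
    status: str  # reached | pileup | timeout | unmatched | missing_hrv
    n_windows_checked: int
    n_windows_skipped: int = 0
    recovery_met: float = float("nan")  # mean MET over the recovery phase


def match_reports_to_markers(
    reports: list[DiaryEventReport],
    marker_minutes: list[int],
    window: int = MATCH_WINDOW,
) -> list[int | None]:
    """One-to-one matching of diary reports to kept markers.

    Reports are processed chronologically; each takes the still-free
    marker closest in time to its reported start, provided the distance
    is at most ``window`` minutes (inclusive).  Equidistant candidates
    resolve to the earlier marker.  Returns, per report, the matched
    marker minute or None.
    """
    order = sorted(range(len(reports)), key=lambda i: (reports[i].diary_minute, reports[i].reported_start_minute))
    free = sorted(marker_minutes)
    matched: list[int | None] = [None] * len(reports)
    for i in order:
        start = reports[i].reported_start_minute
        best = None
        best_d = None
        for m in free:
            d = abs(m - start)
            if d <= window and (best_d is None or d < best_d):
                best, best_d = m, d  # earlier marker wins ties (free is sorted)
        if best is not None:
            matched[i] = best
            free.remove(best)
    return matched


def locate_event_end(marker_minute: int, reported_duration: float) -> int:
    """End of the event: marker minute plus the reported duration.

    Fractional durations are ceiled to the 60-s grid.  A missing
    duration cannot anchor a recovery phase and raises ValueError (the
    caller records an unmatched-duration outcome).
    """
    if reported_duration is None or not math.isfinite(reported_duration):
        raise ValueError("reported duration missing; recovery phase undefined")
    if reported_duration < 0:
        raise ValueError("reported duration must be non-negative")
    return int(marker_minute + math.ceil(reported_duration))


def compute_recovery(
    end_minute: int,
    resting: Segment,
    direction: int,
    minutes: pd.DataFrame,
    next_marker_minute: int | None = None,
    event_id: int = 0,
    timeout: int = RECOVERY_TIMEOUT,
    min_coverage: float = 0.8,
) -> RecoveryResult:
    """Scan 1-min-shifted 5-min windows after the event end.

    For k = 0, 1, ...: the window covers minutes [end+k, end+k+4].  A
    decrease event (direction 0) recovers when the window RMSSD rises
    back to >= the resting RMSSD; an increase event (direction 1) when
    it falls back to <= resting.  Equality counts as recovered.  At each
    k the pile-up censor is checked first: a subsequent marker at a
    minute < end+k+5 censors the scan.  k > ``timeout`` censors as
    timeout.  Windows with undefined RMSSD are skipped (k advances) and
    counted.  An end minute beyond the recording is ``missing_hrv``.
    """
    if not resting.defined:
        raise ValueError("resting segment undefined; cannot compute recovery")
    last_minute = int(minutes["minute"].max()) if len(minutes) else -1
    if end_minute > last_minute:
        return RecoveryResult(event_id, float("nan"), "missing_hrv", 0, 0)

    n_checked = 0
    n_skipped = 0
    for k in range(0, timeout + 1):
        if next_marker_minute is not None and next_marker_minute < end_minute + k + SEGMENT_MINUTES:
            return RecoveryResult(event_id, float("nan"), "pileup", n_checked, n_skipped)
        n_checked += 1
        seg = segment_rmssd(minutes, end_minute + k, min_coverage)
        if not seg.defined:
            n_skipped += 1
            continue
        recovered = seg.rmssd >= resting.rmssd if direction == 0 else seg.rmssd <= resting.rmssd
        if recovered:
            met = _recovery_met(minutes, end_minute, end_minute + k + SEGMENT_MINUTES - 1)
            return RecoveryResult(event_id, float(k), "reached", n_checked, n_skipped, met)
    return RecoveryResult(event_id, float("nan"), "timeout", n_checked, n_skipped)


def _recovery_met(minutes: pd.DataFrame, start: int, stop: int) -> float:
    """Mean MET from event end to the minute recovery was reached (inclusive)."""
    sel = minutes[(minutes["minute"] >= start) & (minutes["minute"] <= stop)]
    if sel.empty:
        return float("nan")
    return float(sel["met"].mean())
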