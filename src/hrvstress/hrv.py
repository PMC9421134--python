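"""RR-interval screening, 60-s aggregation, and 5-min RMSSD segments.

The working resolution of the whole pipeline is the minute: beats are
screened at beat level, collapsed to per-minute sufficient statistics
(valid-beat count, sum of squared successive differences, pair count),
and RMSSD is then pooled over five consecutive minutes.  Pooling the
sufficient statistics is algebraically identical to computing RMSSD
directly on the concatenated within-minute successive differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RRSeries",
    "Segment",
    "SEGMENT_MINUTES",
    "screen_rr",
    "aggregate_minutes",
    "segment_rmssd",
    "ln_transform",
]

#: Segment length in minutes; fixed by convention for short-term RMSSD.
SEGMENT_MINUTES = 5

#: Physiologically plausible absolute RR range (ms) used during screening.
RR_ABS_RANGE = (300.0, 2000.0)


@dataclass
class RRSeries:
    """Timestamped inter-beat intervals with a per-beat validity mask.

    Parameters
    ----------
    beat_time
        Seconds since the person's recording start, strictly increasing.
    rr
        Inter-beat (RR) intervals in milliseconds, all positive.
    valid
        Boolean mask; beats flagged ``False`` are artifacts and are
        ignored by every downstream computation.
    """

    beat_time: np.ndarray
    rr: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_time = np.asarray(self.beat_time, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.rr.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.beat_time.shape != self.rr.shape or self.rr.shape != self.valid.shape:
            raise ValueError("beat_time, rr and valid must have equal length")
        if self.rr.size and np.any(self.rr <= 0):
            raise ValueError("RR intervals must be positive")
        if self.beat_time.size > 1 and np.any(np.diff(self.beat_time) <= 0):
            raise ValueError("beat_time must be strictly increasing")

    def __len__(self) -> int:
        return self.rr.size


@dataclass(frozen=True)
class Segment:
    """A 5-min analysis window with pooled RMSSD and segment covariates.

    ``rmssd``/``ln_rmssd`` are NaN when the window is unusable (unworn
    minutes, insufficient beat coverage, or zero variability for the log).
    """

    start_minute: int
    rmssd: float
    ln_rmssd: float
    mean_met: float
    supine_minutes: float
    n_valid_beats: int
    defined: bool
    reason: str = ""  # why undefined: "", "unworn", "coverage", "no_beats"

    @property
    def length(self) -> int:
        return SEGMENT_MINUTES


def screen_rr(
    series: RRSeries,
    max_rel_change: float = 0.25,
    rr_range: tuple[float, float] = RR_ABS_RANGE,
) -> RRSeries:
    """Screen RR intervals for artifacts.

    A beat is invalid when its RR lies outside ``rr_range`` or when its
    relative change from the *previous valid* beat exceeds
    ``max_rel_change``.  The first in-range beat is valid by definition
    (there is nothing to compare it against).  Ordering is preserved;
    only the validity mask changes.
    """
    if len(series) == 0:
        raise ValueError("cannot screen an empty RR series")
    rr = series.rr
    lo, hi = rr_range
    valid = np.zeros(rr.size, dtype=bool)
    prev = -1.0  # last accepted RR, <0 while none seen
    for i in range(rr.size):
        x = rr[i]
        if x < lo or x > hi:
            continue
        if prev < 0 or abs(x - prev) / prev <= max_rel_change:
            valid[i] = True
            prev = x
    return RRSeries(series.beat_time.copy(), rr.copy(), valid)


def aggregate_minutes(series: RRSeries, activity: pd.DataFrame) -> pd.DataFrame:
    """Collapse a screened RR series to per-minute sufficient statistics.

    ``activity`` must carry one row per minute with columns
    ``minute``, ``met``, ``supine_fraction``, ``worn``.  The output has
    one row per activity minute with ``n_valid_beats``, ``sum_rr``,
    ``sum_sq_succ_diff`` and ``n_succ_pairs``.

    A successive pair is two *adjacent* beats that are both valid and
    whose beat times fall in the same minute; removed artifacts break
    pairs, and pairs straddling a minute boundary count for neither
    minute.  Minutes flagged unworn contribute zero beats regardless of
    any (spurious) RR data inside them.
    """
    required = {"minute", "met", "supine_fraction", "worn"}
    missing = required - set(activity.columns)
    if missing:
        raise ValueError(f"activity table missing columns: {sorted(missing)}")
    act = activity.sort_values("minute").reset_index(drop=True)
    out = act[["minute", "met", "supine_fraction", "worn"]].copy()
    out["minute"] = out["minute"].astype(int)
    n = len(series)
    minute_of = np.floor(series.beat_time / 60.0).astype(int) if n else np.array([], int)

    if n and len(act):
        lo = int(out["minute"].min())
        hi = int(out["minute"].max())
        if minute_of.min() > hi or minute_of.max() < lo:
            raise ValueError("RR series and activity table cover disjoint time ranges")

    worn_minutes = set(out.loc[out["worn"].astype(bool), "minute"].tolist())
    usable = series.valid & np.isin(minute_of, list(worn_minutes) or [-1])

    stats = pd.DataFrame(
        {
            "minute": minute_of[usable],
            "rr": series.rr[usable],
        }
    )
    agg = stats.groupby("minute")["rr"].agg(n_valid_beats="count", sum_rr="sum")

    # adjacent usable beats in the same minute
    if n > 1:
        pair = usable[:-1] & usable[1:] & (minute_of[:-1] == minute_of[1:])
        d = series.rr[1:] - series.rr[:-1]
        pairs = pd.DataFrame({"minute": minute_of[:-1][pair], "d2": d[pair] ** 2})
        pagg = pairs.groupby("minute")["d2"].agg(sum_sq_succ_diff="sum", n_succ_pairs="count")
    else:
        pagg = pd.DataFrame(columns=["sum_sq_succ_diff", "n_succ_pairs"])

    out = out.merge(agg, on="minute", how="left").merge(pagg, on="minute", how="left")
    for col in ("n_valid_beats", "n_succ_pairs"):
        out[col] = out[col].fillna(0).astype(int)
    for col in ("sum_rr", "sum_sq_succ_diff"):
        out[col] = out[col].fillna(0.0)
    return out


def segment_rmssd(
    minutes: pd.DataFrame,
    start_minute: int,
    min_coverage: float = 0.8,
) -> Segment:
    """Pooled RMSSD over the five minutes starting at ``start_minute``.

    RMSSD = sqrt( Σ sum_sq_succ_diff / Σ n_succ_pairs ) over the window.
    The segment is undefined when any of its minutes is unworn or absent
    from the minute table, or when the valid-beat count falls below
    ``min_coverage`` of the expected count (300 s divided by the mean
    valid RR observed in the window).
    """
    idx = np.arange(start_minute, start_minute + SEGMENT_MINUTES)
    window = minutes[minutes["minute"].isin(idx)].set_index("minute")

    def _undef(reason: str, mean_met: float = np.nan, supine: float = np.nan) -> Segment:
        return Segment(start_minute, np.nan, np.nan, mean_met, supine, 0, False, reason)

    if len(window) < SEGMENT_MINUTES or not window["worn"].astype(bool).all():
        return _undef("unworn")
    mean_met = float(window["met"].mean())
    supine = float(window["supine_fraction"].sum())
    n_beats = int(window["n_valid_beats"].sum())
    if n_beats == 0:
        return _undef("no_beats", mean_met, supine)
    mean_rr_ms = float(window["sum_rr"].sum()) / n_beats
    expected = 300.0 * 1000.0 / mean_rr_ms
    if n_beats < min_coverage * expected:
        return _undef("coverage", mean_met, supine)
    n_pairs = int(window["n_succ_pairs"].sum())
    if n_pairs == 0:
        return _undef("coverage", mean_met, supine)
    rmssd = float(np.sqrt(window["sum_sq_succ_diff"].sum() / n_pairs))
    return Segment(
        start_minute,
        rmssd,
        ln_transform(rmssd),
        mean_met,
        supine,
        n_beats,
        True,
        "",
    )


def ln_transform(rmssd: float) -> float:
    """Natural log of RMSSD; 0 or non-finite maps to NaN (flagged missing)."""
    if not np.isfinite(rmssd) or rmssd <= 0:
        return float("nan")
    return float(np.log(rmssd))
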