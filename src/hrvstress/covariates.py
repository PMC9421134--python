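"""Covariate coding, outlier handling, centering, and analysis-table assembly.

Event-level covariates come from the bihourly diaries: substance use
(caffeine, alcohol, nicotine) and anticipated stress count as present
when any positive diary report's 2-h look-back window overlaps the
±2 h around the event; ambient noise uses the preceding 2 h only.
Person-level covariates are chronic stress (PSS-10, standardized),
BMI, and weekly moderate-to-vigorous physical activity.  Outliers on
continuous measures are winsorized at ±3 SD; resting lnRMSSD is
group-mean (within-person) centered, all other continuous covariates
grand-mean centered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "MET_IMPROBABLE",
    "code_event_flags",
    "winsorize_3sd",
    "center",
    "screen_met",
    "score_pss10",
    "standardize",
    "assemble_analysis_tables",
]

#: Upper plausibility bound for MET (three times peak functional capacity).
MET_IMPROBABLE = 79.8

#: Diary look-back span in minutes ("in the last 2 h").
DIARY_LOOKBACK = 120

#: PSS-10 positively worded items (0-based indices), reverse-scored.
PSS10_REVERSED = (3, 4, 6, 7)

FLAG_COLUMNS = ("caffeine", "alcohol", "nicotine", "anticipated_stress", "ambient_noise")


def code_event_flags(event_minute: int, diaries: pd.DataFrame) -> dict[str, int]:
    """Dummy-code substance/anticipation/noise exposure around an event.

    ``diaries`` holds one row per prompt with column ``diary_minute``
    and the 0/1 flag columns.  A prompt's reporting window is the
    closed interval [diary_minute - 120, diary_minute].  Substance and
    anticipation flags become 1 iff a positive prompt's window overlaps
    [event - 120, event + 120]; ambient noise iff it overlaps
    [event - 120, event].
    """
    flags = {c: 0 for c in FLAG_COLUMNS}
    if diaries.empty:
        return flags
    d = diaries["diary_minute"].to_numpy(dtype=float)
    win_lo, win_hi = d - DIARY_LOOKBACK, d
    sym = (win_lo <= event_minute + DIARY_LOOKBACK) & (win_hi >= event_minute - DIARY_LOOKBACK)
    pre = (win_lo <= event_minute) & (win_hi >= event_minute - DIARY_LOOKBACK)
    for col in FLAG_COLUMNS:
        if col not in diaries.columns:
            continue
        pos = diaries[col].fillna(0).to_numpy(dtype=float) > 0
        mask = pre if col == "ambient_noise" else sym
        flags[col] = int(bool(np.any(pos & mask)))
    return flags


def winsorize_3sd(values: pd.Series | np.ndarray) -> pd.Series:
    """Single-pass ±3 SD winsorization.

    Mean and SD are taken over the finite values *before* replacement;
    values beyond mean ± 3 SD are set to the bound.  Constant series
    (SD 0) are returned unchanged.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    finite = s.dropna()
    if finite.size < 2:
        return s
    m, sd = finite.mean(), finite.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return s
    return s.clip(lower=m - 3 * sd, upper=m + 3 * sd)


def center(values: pd.Series, groups: pd.Series | None = None) -> tuple[pd.Series, pd.Series | float]:
    """Group-mean (per person) or grand-mean center a series.

    Returns the centered series and the subtracted mean(s): a scalar
    grand mean or a per-group Series, kept as metadata so raw scale can
    be restored.
    """
    if groups is None:
        m = values.mean()
        return values - m, float(m)
    means = values.groupby(groups).transform("mean")
    per_group = values.groupby(groups).mean()
    return values - means, per_group


def screen_met(met: pd.Series | np.ndarray, bound: float = MET_IMPROBABLE) -> pd.Series:
    """Flag physiologically improbable MET values (> bound, strict) as missing."""
    s = pd.Series(np.asarray(met, dtype=float))
    return s.mask(s > bound)


def score_pss10(items: pd.DataFrame) -> pd.Series:
    """Total PSS-10 score (0-40) from ten 0-4 item responses.

    Columns are taken in order as items 1-10; the positively worded
    items (4, 5, 7, 8) are reverse-scored (4 - x) before summing.  Any
    missing item makes the person's total missing.
    """
    if items.shape[1] != 10:
        raise ValueError("PSS-10 requires exactly 10 item columns")
    vals = items.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 4:
        raise ValueError("PSS-10 item responses must lie in 0-4")
    scored = vals.copy()
    for j in PSS10_REVERSED:
        scored[:, j] = 4 - scored[:, j]
    total = scored.sum(axis=1)  # NaN propagates -> person-level missing
    return pd.Series(total, index=items.index, name="pss10_total")


def standardize(values: pd.Series) -> pd.Series:
    """z-scores against the sample mean and SD (ddof=1)."""
    finite = values.dropna()
    sd = finite.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a constant or empty series")
    return (values - finite.mean()) / sd


def assemble_analysis_tables(
    events: pd.DataFrame,
    recoveries: pd.DataFrame,
    persons: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the two model-ready tables with listwise deletion.

    ``events``: one row per built event with columns person_id,
    event_id, delta_rmssd, resting_rmssd, reactivity_rmssd, direction,
    resting_met, reactivity_met, resting_supine, reactivity_supine,
    minute, start_minute (person's first recording minute), and the
    diary flag columns.  ``recoveries``: event_id, recovery_minutes,
    status, recovery_met.  ``persons``: person_id, pss10_total, bmi,
    mvpa_hours.

    Processing order: screen improbable MET, log-transform resting
    RMSSD, winsorize continuous measures at ±3 SD, group-mean center
    resting lnRMSSD within person, standardize chronic stress, grand-
    mean center remaining continuous covariates, then delete any row
    with a missing model variable.
    """
    ev = events.copy()
    if ev.empty:
        raise ValueError("no events to assemble")

    for c in ("resting_met", "reactivity_met"):
        ev[c] = screen_met(ev[c])
    ev["resting_lnrmssd"] = np.log(ev["resting_rmssd"].where(ev["resting_rmssd"] > 0))
    ev["time_in_study"] = (ev["minute"] - ev["start_minute"]) / 1440.0

    pers = persons.copy()
    pers["chronic_stress_z"] = standardize(pers["pss10_total"])
    ev = ev.merge(
        pers[["person_id", "chronic_stress_z", "bmi", "mvpa_hours"]],
        on="person_id",
        how="left",
    )

    wins_cols = [
        "delta_rmssd",
        "resting_lnrmssd",
        "resting_met",
        "reactivity_met",
        "resting_supine",
        "reactivity_supine",
        "bmi",
        "mvpa_hours",
    ]
    for c in wins_cols:
        ev[c] = winsorize_3sd(ev[c])

    ev["resting_lnrmssd_c"], _ = center(ev["resting_lnrmssd"], ev["person_id"])
    grand_cols = [
        "resting_met",
        "reactivity_met",
        "resting_supine",
        "reactivity_supine",
        "time_in_study",
        "bmi",
        "mvpa_hours",
    ]
    for c in grand_cols:
        ev[c + "_c"], _ = center(ev[c])

    react_cols = [
        "person_id",
        "event_id",
        "delta_rmssd",
        "direction",
        "resting_lnrmssd_c",
        "resting_met_c",
        "reactivity_met_c",
        "resting_supine_c",
        "reactivity_supine_c",
        "time_in_study_c",
        "caffeine",
        "alcohol",
        "nicotine",
        "anticipated_stress",
        "ambient_noise",
        "mvpa_hours_c",
        "bmi_c",
        "chronic_stress_z",
    ]
    reactivity_table = ev[react_cols].dropna().reset_index(drop=True)
    if reactivity_table.empty:
        raise ValueError("reactivity table empty after listwise deletion")

    rec = recoveries.merge(
        ev[
            [
                "event_id",
                "person_id",
                "direction",
                "resting_lnrmssd_c",
                "resting_met_c",
                "time_in_study_c",
            ]
        ],
        on="event_id",
        how="inner",
    )
    rec["recovery_met"] = screen_met(rec["recovery_met"])
    rec["recovery_met_c"], _ = center(rec["recovery_met"])
    rec_cols = [
        "person_id",
        "event_id",
        "recovery_minutes",
        "status",
        "direction",
        "resting_lnrmssd_c",
        "resting_met_c",
        "recovery_met_c",
        "time_in_study_c",
    ]
    recovery_table = rec[rec_cols].reset_index(drop=True)
    return reactivity_table, recovery_table
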