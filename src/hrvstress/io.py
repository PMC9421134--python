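"""CSV dialects for the ambulatory tables.

All tables are plain comma-separated UTF-8 with ISO-8601 timestamps.
Times are stored against a nominal study epoch (a Monday at 00:00, the
study's first recording day) and normalized on read to seconds (beats,
markers) or whole minutes (activity, diaries) since that epoch.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["STUDY_EPOCH", "TABLE_NAMES", "write_dataset", "read_tables", "ValidationError"]

log = logging.getLogger(__name__)

STUDY_EPOCH = pd.Timestamp("2000-01-03T00:00:00")

TABLE_NAMES = ("rr", "activity", "markers", "diary_prompts", "diary_events", "persons")


class ValidationError(ValueError):
    """Schema or value violation in an input table, with file/row context."""


def _to_iso_seconds(seconds: pd.Series) -> pd.Series:
    ts = STUDY_EPOCH + pd.to_timedelta(np.round(seconds * 1000.0).astype("int64"), unit="ms")
    return ts.dt.strftime("%Y-%m-%dT%H:%M:%S.%f")


def _to_iso_minutes(minutes: pd.Series) -> pd.Series:
    ts = STUDY_EPOCH + pd.to_timedelta(minutes.astype("int64"), unit="m")
    return ts.dt.strftime("%Y-%m-%dT%H:%M:%S")


def _from_iso(col: pd.Series, path: Path, name: str) -> pd.Series:
    try:
        ts = pd.to_datetime(col, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable timestamps in column {name}: {exc}") from exc
    return (ts - STUDY_EPOCH).dt.total_seconds()


def write_dataset(dataset: dict[str, pd.DataFrame], outdir: str | Path) -> dict[str, Path]:
    """Write the six study tables as CSV; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rr = dataset["rr"].copy()
    rr["time"] = _to_iso_seconds(rr.pop("time_s"))
    _write(rr[["person_id", "time", "rr_ms"]], outdir / "rr.csv", paths, "rr")

    act = dataset["activity"].copy()
    act["time"] = _to_iso_minutes(act.pop("minute"))
    act["worn"] = act["worn"].astype(int)
    _write(act[["person_id", "time", "met", "supine_fraction", "worn"]], outdir / "activity.csv", paths, "activity")

    mk = dataset["markers"].copy()
    mk["time"] = _to_iso_seconds(mk.pop("time_s"))
    _write(mk[["person_id", "time", "source"]], outdir / "markers.csv", paths, "markers")

    dp = dataset["diary_prompts"].copy()
    dp["time"] = _to_iso_minutes(dp.pop("diary_minute"))
    cols = ["person_id", "time"] + [c for c in dp.columns if c not in ("person_id", "time")]
    _write(dp[cols], outdir / "diary_prompts.csv", paths, "diary_prompts")

    de = dataset["diary_events"].copy()
    de["diary_time"] = _to_iso_minutes(de.pop("diary_minute"))
    de["reported_start"] = _to_iso_minutes(de.pop("reported_start_minute"))
    de = de.drop(columns=[c for c in ("true_event_id",) if c in de.columns])
    _write(
        de[["person_id", "diary_time", "reported_start", "reported_duration", "accident"]],
        outdir / "diary_events.csv",
        paths,
        "diary_events",
    )

    _write(dataset["persons"], outdir / "persons.csv", paths, "persons")
    return paths


def _write(df: pd.DataFrame, path: Path, paths: dict[str, Path], name: str) -> None:
    df.to_csv(path, index=False, lineterminator="\n")
    paths[name] = path


def read_tables(indir: str | Path) -> dict[str, pd.DataFrame]:
    """Load and validate the six study tables.

    Violations (missing columns, unparseable timestamps, non-positive
    RR) raise :class:`ValidationError` naming the file and offending
    rows.  Timestamps are normalized to seconds/minutes since the
    study epoch.
    """
    indir = Path(indir)
    out: dict[str, pd.DataFrame] = {}

    rr = _load(indir / "rr.csv", ["person_id", "time", "rr_ms"])
    rr["time_s"] = _from_iso(rr.pop("time"), indir / "rr.csv", "time")
    bad = rr.index[~(rr["rr_ms"] > 0)].tolist()
    if bad:
        raise ValidationError(f"{indir / 'rr.csv'}: non-positive rr_ms at rows {bad[:10]} (2-based incl. header)")
    out["rr"] = rr[["person_id", "time_s", "rr_ms"]]

    act = _load(indir / "activity.csv", ["person_id", "time", "met", "supine_fraction", "worn"])
    act["minute"] = (_from_iso(act.pop("time"), indir / "activity.csv", "time") / 60.0).round().astype(int)
    bad = act.index[act["met"] < 0].tolist()
    if bad:
        raise ValidationError(f"{indir / 'activity.csv'}: negative MET at rows {bad[:10]}")
    act["worn"] = act["worn"].astype(bool)
    out["activity"] = act[["person_id", "minute", "met", "supine_fraction", "worn"]]

    mk = _load(indir / "markers.csv", ["person_id", "time", "source"])
    mk["time_s"] = _from_iso(mk.pop("time"), indir / "markers.csv", "time")
    recorded = act.groupby("person_id")["minute"].agg(["min", "max"])
    mk_minute = np.floor(mk["time_s"] / 60.0).astype(int)
    for i, row in mk.iterrows():
        pid = row["person_id"]
        if pid not in recorded.index or not (
            recorded.loc[pid, "min"] <= mk_minute[i] <= recorded.loc[pid, "max"]
        ):
            log.warning("markers.csv row %d: marker outside any recording day; will be excluded as not_worn", i + 2)
    out["markers"] = mk[["person_id", "time_s", "source"]]

    dp = _load(indir / "diary_prompts.csv", ["person_id", "time"])
    dp["diary_minute"] = (_from_iso(dp.pop("time"), indir / "diary_prompts.csv", "time") / 60.0).round().astype(int)
    out["diary_prompts"] = dp

    de = _load(indir / "diary_events.csv", ["person_id", "diary_time", "reported_start", "reported_duration", "accident"])
    de["diary_minute"] = (_from_iso(de.pop("diary_time"), indir / "diary_events.csv", "diary_time") / 60.0).round().astype(int)
    de["reported_start_minute"] = (
        _from_iso(de.pop("reported_start"), indir / "diary_events.csv", "reported_start") / 60.0
    ).round().astype(int)
    out["diary_events"] = de[["person_id", "diary_minute", "reported_start_minute", "reported_duration", "accident"]]

    out["persons"] = _load(indir / "persons.csv", ["person_id"])
    return out


def _load(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise ValidationError(f"missing input table: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df
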