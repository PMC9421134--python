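"""Stage orchestration: raw tables -> analysis tables -> fitted models.

Each stage is a pure function over DataFrames so it can be tested and
run in isolation; :func:`run_pipeline` chains them, writes every
intermediate table, and emits a manifest with per-stage attrition
counts (mirroring the study's data-loss accounting) and content
hashes, so identical config + seed reproduces identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import events as ev
from . import hrv
from . import io as hio
from . import models as mod
from . import recovery as rec
from .config import StudyConfig

__all__ = [
    "PipelineError",
    "screen_stage",
    "events_stage",
    "recovery_stage",
    "assemble_stage",
    "fit_stage",
    "run_pipeline",
]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def screen_stage(dataset: dict[str, pd.DataFrame], cfg: StudyConfig) -> pd.DataFrame:
    """Artifact-screen each person's RR series and aggregate to minutes."""
    frames = []
    for pid, act in dataset["activity"].groupby("person_id", sort=True):
        rrp = dataset["rr"][dataset["rr"]["person_id"] == pid]
        if rrp.empty:
            minutes = act.copy()
            for c, v in (("n_valid_beats", 0), ("sum_rr", 0.0), ("sum_sq_succ_diff", 0.0), ("n_succ_pairs", 0)):
                minutes[c] = v
        else:
            series = hrv.RRSeries(rrp["time_s"].to_numpy(), rrp["rr_ms"].to_numpy())
            screened = hrv.screen_rr(series, cfg.max_rel_change, (cfg.rr_min, cfg.rr_max))
            minutes = hrv.aggregate_minutes(screened, act.drop(columns="person_id"))
            minutes.insert(0, "person_id", pid)
        frames.append(minutes)
    return pd.concat(frames, ignore_index=True)


def _provisional_diary_attrs(
    marker_minutes: list[int], reports: pd.DataFrame, window: int
) -> tuple[list[bool], list[float]]:
    """Per-marker accident flag and duration from the nearest diary report."""
    accidents, durations = [], []
    for m in marker_minutes:
        if reports.empty:
            accidents.append(False)
            durations.append(float("nan"))
            continue
        d = (reports["reported_start_minute"] - m).abs()
        i = d.idxmin()
        if d.loc[i] <= window:
            accidents.append(bool(reports.loc[i, "accident"]))
            durations.append(float(reports.loc[i, "reported_duration"]))
        else:
            accidents.append(False)
            durations.append(float("nan"))
    return accidents, durations


def events_stage(
    dataset: dict[str, pd.DataFrame], minutes: pd.DataFrame, cfg: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter markers, add device-detected events, build event records.

    Returns (events table, exclusion log).  The events table carries
    raw segment values plus the diary-coded covariate flags; rows with
    an unusable segment are flagged missing and dropped downstream.
    """
    event_rows, excl_rows = [], []
    event_id = 0
    for pid, mper in minutes.groupby("person_id", sort=True):
        mper = mper.reset_index(drop=True)
        start_minute = int(mper["minute"].min())
        mk = dataset["markers"][dataset["markers"]["person_id"] == pid]
        reports = dataset["diary_events"][dataset["diary_events"]["person_id"] == pid].reset_index(drop=True)
        prompts = dataset["diary_prompts"][dataset["diary_prompts"]["person_id"] == pid]

        raw = [
            ev.StressMarker(pid, int(np.floor(t / 60.0)), s)
            for t, s in zip(mk["time_s"], mk["source"])
        ]
        raw.sort(key=lambda m: m.minute)
        acc, dur = _provisional_diary_attrs([m.minute for m in raw], reports, cfg.diary_match_window)
        filtered = ev.filter_markers(raw, mper, acc, dur)
        for m in filtered:
            if not m.kept:
                excl_rows.append({"person_id": pid, "minute": m.minute, "source": m.source, "reason": m.excluded_reason})

        kept_self = [m.minute for m in filtered if m.kept and m.source == "self"]
        device = ev.detect_physical_events(
            mper, cfg.met_threshold, cfg.min_bout_minutes, kept_self
        )
        all_kept = sorted(
            [m for m in filtered if m.kept] + device, key=lambda m: m.minute
        )
        for m in all_kept:
            record = ev.build_event_record(m, mper, event_id, cfg.min_coverage)
            flags = cov.code_event_flags(m.minute, prompts)
            event_rows.append(
                {
                    "person_id": pid,
                    "event_id": event_id,
                    "minute": m.minute,
                    "start_minute": start_minute,
                    "source": m.source,
                    "resting_rmssd": record.resting.rmssd,
                    "reactivity_rmssd": record.reactivity.rmssd,
                    "delta_rmssd": record.delta_rmssd,
                    "direction": record.direction,
                    "resting_met": record.resting.mean_met,
                    "reactivity_met": record.reactivity.mean_met,
                    "resting_supine": record.resting.supine_minutes,
                    "reactivity_supine": record.reactivity.supine_minutes,
                    "missing": record.missing,
                    "missing_reason": record.missing_reason,
                    **flags,
                }
            )
            event_id += 1
    events = pd.DataFrame(event_rows)
    exclusions = pd.DataFrame(excl_rows, columns=["person_id", "minute", "source", "reason"])
    return events, exclusions


def recovery_stage(
    dataset: dict[str, pd.DataFrame],
    minutes: pd.DataFrame,
    events: pd.DataFrame,
    cfg: StudyConfig,
) -> pd.DataFrame:
    """Match diary reports to kept self-markers and compute recovery times.

    Device-detected events carry no self-reported duration, so recovery
    is computed for diary-matched self-marked events only.
    """
    rows = []
    for pid, eper in events.groupby("person_id", sort=True):
        mper = minutes[minutes["person_id"] == pid].reset_index(drop=True)
        reports_df = dataset["diary_events"]
        reports_df = reports_df[(reports_df["person_id"] == pid) & (reports_df["accident"] == 0)]
        reports = [
            rec.DiaryEventReport(pid, int(r.diary_minute), int(r.reported_start_minute), float(r.reported_duration))
            for r in reports_df.itertuples()
        ]
        self_events = eper[eper["source"] == "self"].sort_values("minute")
        all_marker_minutes = sorted(eper["minute"].tolist())
        matched = rec.match_reports_to_markers(
            reports, self_events["minute"].tolist(), cfg.diary_match_window
        )
        for rep, mmin in zip(reports, matched):
            if mmin is None:
                rows.append({"person_id": pid, "event_id": -1, "recovery_minutes": float("nan"),
                             "status": "unmatched", "recovery_met": float("nan")})
                continue
            erow = self_events[self_events["minute"] == mmin].iloc[0]
            if erow["missing"] or not np.isfinite(rep.reported_duration):
                rows.append({"person_id": pid, "event_id": int(erow["event_id"]),
                             "recovery_minutes": float("nan"), "status": "missing_hrv",
                             "recovery_met": float("nan")})
                continue
            end = rec.locate_event_end(mmin, rep.reported_duration)
            later = [m for m in all_marker_minutes if m > mmin]
            next_marker = min(later) if later else None
            resting = hrv.segment_rmssd(mper, mmin - hrv.SEGMENT_MINUTES, cfg.min_coverage)
            result = rec.compute_recovery(
                end, resting, int(erow["direction"]), mper, next_marker,
                int(erow["event_id"]), cfg.recovery_timeout, cfg.min_coverage,
            )
            rows.append({"person_id": pid, "event_id": result.event_id,
                         "recovery_minutes": result.recovery_minutes,
                         "status": result.status, "recovery_met": result.recovery_met})
    return pd.DataFrame(rows, columns=["person_id", "event_id", "recovery_minutes", "status", "recovery_met"])


def assemble_stage(
    events: pd.DataFrame, recoveries: pd.DataFrame, persons: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score person covariates and build the two model-ready tables."""
    pss_cols = [f"pss_{i}" for i in range(1, 11)]
    pers = persons.copy()
    pers["pss10_total"] = cov.score_pss10(pers[pss_cols])
    usable = events[~events["missing"]].reset_index(drop=True)
    return cov.assemble_analysis_tables(usable, recoveries.drop(columns=["person_id"]), pers)


def fit_stage(
    reactivity_table: pd.DataFrame, recovery_table: pd.DataFrame, cfg: StudyConfig
) -> tuple[mod.FitResult, mod.FitResult]:
    react = mod.fit_reactivity(reactivity_table, mod.ReactivityModelSpec(terms=list(cfg.reactivity_terms)))
    recov = mod.fit_recovery(recovery_table, mod.RecoveryModelSpec(terms=list(cfg.recovery_terms)))
    return react, recov


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def run_pipeline(cfg: StudyConfig) -> dict:
    """Run every stage, write outputs and the run manifest; return the manifest."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "read"
    try:
        dataset = hio.read_tables(cfg.input_dir)
        stage = "screen"
        minutes = screen_stage(dataset, cfg)
        _write_csv(minutes, outdir / "minutes.csv")
        stage = "events"
        events, exclusions = events_stage(dataset, minutes, cfg)
        _write_csv(events, outdir / "events.csv")
        _write_csv(exclusions, outdir / "exclusions.csv")
        stage = "recover"
        recoveries = recovery_stage(dataset, minutes, events, cfg)
        _write_csv(recoveries, outdir / "recovery.csv")
        stage = "assemble"
        react_tab, recov_tab = assemble_stage(events, recoveries, dataset["persons"])
        _write_csv(react_tab, outdir / "reactivity_table.csv")
        _write_csv(recov_tab, outdir / "recovery_table.csv")
        stage = "fit"
        react_fit, recov_fit = fit_stage(react_tab, recov_tab, cfg)
        _write_csv(react_fit.params, outdir / "reactivity_fit.csv")
        _write_csv(recov_fit.params, outdir / "recovery_fit.csv")
        (outdir / "report.txt").write_text(
            mod.summarize(react_fit) + "\n\n" + mod.summarize(recov_fit) + "\n"
        )
    except Exception as exc:  # noqa: BLE001 - annotate failures with the stage
        raise PipelineError(stage, exc) from exc

    status_counts = recoveries["status"].value_counts().to_dict()
    reason_counts = exclusions["reason"].value_counts().to_dict()
    manifest = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "stages": {
            "persons": int(dataset["activity"]["person_id"].nunique()),
            "markers_total": int(len(dataset["markers"])),
            "markers_excluded": {k: int(v) for k, v in sorted(reason_counts.items())},
            "markers_kept_self": int((events["source"] == "self").sum()),
            "device_events": int((events["source"] == "device").sum()),
            "events_built": int(len(events)),
            "events_missing_hrv": int(events["missing"].sum()),
            "diary_reports": int(len(dataset["diary_events"])),
            "recovery_status": {k: int(v) for k, v in sorted(status_counts.items())},
            "reactivity_rows": int(len(react_tab)),
            "recovery_rows_uncensored": int((recov_tab["status"] == "reached").sum()),
            "model_n": {
                "reactivity": {"obs": react_fit.n_obs, "persons": react_fit.n_persons},
                "recovery": {"obs": recov_fit.n_obs, "persons": recov_fit.n_persons},
            },
        },
        "outputs": {
            p.name: _sha(p)
            for p in sorted(outdir.glob("*.csv"))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
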