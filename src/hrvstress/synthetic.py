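"""Synthetic ambulatory cohorts with known ground truth.

Emulates a 4-day waking-hours wearable study: each person wears an ECG
chest sensor, taps it when a stressful event starts, answers bihourly
diaries (8/day, 2 h apart from 08:00) reporting event start times and
durations with recall noise, and accumulates minute-level activity
(MET, supine position, wear state).  Heart-beat data are generated so
that per-minute RMSSD tracks a target trajectory exactly in
expectation: beats are mean RR plus independent Gaussian perturbations
with sigma = target / sqrt(2), because the RMS of differences of two
independent N(0, sigma^2) draws is sigma*sqrt(2).

Two simulation scales coexist:

* :func:`simulate_cohort` — full beat-level datasets for end-to-end
  pipeline runs at small n;
* :func:`simulate_reactivity_table` / :func:`simulate_recovery_table`
  — event-table-level draws from the same structural equations, for
  parameter-recovery studies at many replicates.

All structural coefficients live in :class:`SimConfig` and are echoed
into :class:`GroundTruth` so estimates can be compared to truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "simulate_cohort",
    "synthesize_rr",
    "inject_event_response",
    "simulate_reactivity_table",
    "simulate_recovery_table",
]


class ConfigError(ValueError):
    """Degenerate or inconsistent simulation configuration."""


def _default_prevalences() -> dict[str, float]:
    # per-diary-prompt report probabilities, roughly matching observed
    # event-level prevalences (caffeine 27%, alcohol 4%, nicotine 8%,
    # anticipated stress 27%, noise 8% across ±2 h windows)
    return {
        "caffeine": 0.10,
        "alcohol": 0.015,
        "nicotine": 0.03,
        "anticipated_stress": 0.10,
        "ambient_noise": 0.03,
    }


@dataclass
class SimConfig:
    """Study-design and structural parameters of the simulated cohort.

    Defaults reproduce the source study's design: 4 recording days,
    waking window 08:00-22:00, ~2 self-marked events/day (8 markers
    over 4 days on average), event durations lognormal with mean 21 and
    SD 30 min (clipped to 1-240), resting RMSSD lognormal across
    persons around 40 ms, and reactivity/recovery structural
    coefficients of the magnitudes estimated in the source cohort.
    """

    n_persons: int = 20
    n_days: int = 4
    waking_start_hour: float = 8.0
    waking_end_hour: float = 22.0
    events_per_day_rate: float = 2.0
    event_duration_lognormal: tuple[float, float] = (2.49, 1.05)  # (meanlog, sdlog) min
    base_rmssd_lognormal: tuple[float, float] = (3.56, 0.45)  # across persons, ln-ms
    within_person_rest_sd: float = 0.30  # ln-ms, event-to-event resting wobble
    mean_rr: float = 800.0  # ms

    # reactivity structural equation (ms of RMSSD change)
    beta_intercept: float = -7.06
    beta_resting: float = -14.06  # per ln-unit of centered resting lnRMSSD
    beta_met: float = -3.55  # per MET above met_reference
    beta_interaction: float = -3.85  # per (ln-unit x MET)
    person_intercept_sd: float = 6.07  # ms, between-person
    reactivity_noise_sd: float = 12.16  # ms, residual
    met_reference: float = 1.7  # MET level at which beta_resting applies

    # recovery structural equation (log minutes)
    gamma_intercept: float = math.log(8.72)
    gamma_resting: float = math.log(4.30)
    gamma_direction: float = math.log(0.88)
    gamma_interaction: float = math.log(0.24)
    gamma_resting_met: float = math.log(1.44)
    gamma_recovery_met: float = math.log(1.11)
    gamma_time: float = math.log(1.02)
    recovery_person_sd: float = 0.70  # ln-minutes, between-person
    recovery_halflife: float = 10.0  # minutes, post-event exponential return
    recovery_timeout: int = 120  # minutes, censoring horizon
    pileup_rate: float = 0.017  # table-level pile-up censoring probability

    # diary recall noise and data-quality knobs
    diary_time_noise_sd: float = 10.0  # minutes
    diary_duration_noise_sd: float = 5.0  # minutes
    accident_marker_rate: float = 0.2  # extra accidental markers per person-day
    missing_fraction: float = 0.0  # proportion of waking minutes unworn
    artifact_fraction: float = 0.0  # proportion of beats corrupted
    covariate_prevalences: dict[str, float] = field(default_factory=_default_prevalences)

    # background activity
    met_baseline: float = 1.3
    met_bout_rate_per_day: float = 1.5
    met_bout_level: tuple[float, float] = (3.0, 7.0)
    met_bout_minutes: tuple[int, int] = (5, 30)

    seed: int = 0

    def validate(self) -> None:
        if self.n_persons < 1 or self.n_days < 1:
            raise ConfigError("n_persons and n_days must be >= 1")
        if not (0 <= self.waking_start_hour < self.waking_end_hour <= 24):
            raise ConfigError("waking window must be a non-empty interval within a day")
        if self.events_per_day_rate < 0:
            raise ConfigError("events_per_day_rate must be >= 0")
        if self.recovery_halflife <= 0:
            raise ConfigError("recovery_halflife must be positive")
        for name in ("missing_fraction", "artifact_fraction", "pileup_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        for k, v in self.covariate_prevalences.items():
            if not (0 <= v <= 1):
                raise ConfigError(f"covariate prevalence {k} must lie in [0, 1]")
        if not (400 <= self.mean_rr <= 1500):
            raise ConfigError("mean_rr must lie in 400-1500 ms")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    persons: pd.DataFrame  # person_id, base_lnrmssd, u_reactivity, u_recovery
    events: pd.DataFrame  # scheduled self-marked events with true parameters
    fixed_effects: dict[str, float]
    variances: dict[str, float]
    bouts: pd.DataFrame | None = None  # scheduled high-MET bouts (device events)


# ---------------------------------------------------------------------------
# beat-level synthesis


def synthesize_rr(
    target_rmssd: np.ndarray,
    minute_index: np.ndarray,
    mean_rr: float = 800.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate beats whose per-minute RMSSD matches ``target_rmssd``.

    Parameters
    ----------
    target_rmssd
        Target RMSSD (ms) per minute, aligned with ``minute_index``;
        must be non-negative (0 gives a constant RR stream).
    minute_index
        Absolute minute indices (need not be contiguous).
    mean_rr
        Mean inter-beat interval, ms; must be plausible (400-1500).

    Returns ``(beat_time_s, rr_ms)``.  Per minute, beats are
    ``mean_rr + N(0, sigma^2)`` with ``sigma = target / sqrt(2)``;
    beats run past the minute boundary are dropped, so pairs never
    straddle minutes.
    """
    rng = rng or np.random.default_rng()
    target = np.asarray(target_rmssd, dtype=float)
    if np.any(target < 0) or np.any(~np.isfinite(target)):
        raise ValueError("target RMSSD trajectory must be finite and non-negative")
    if not (400 <= mean_rr <= 1500):
        raise ValueError("mean_rr outside plausible range 400-1500 ms")
    minute_index = np.asarray(minute_index, dtype=int)
    n_min = minute_index.size
    n_per = int(math.ceil(61000.0 / mean_rr))
    sigma = target / math.sqrt(2.0)
    rr = mean_rr + rng.standard_normal((n_min, n_per)) * sigma[:, None]
    rr = np.maximum(rr, 250.0)  # hard floor; RR must stay positive
    t = minute_index[:, None] * 60.0 + np.cumsum(rr, axis=1) / 1000.0
    keep = t < (minute_index[:, None] + 1) * 60.0
    return t[keep], rr[keep]


def inject_event_response(
    rest_centered: float,
    met_during: float,
    direction_for_recovery: int,
    config: SimConfig,
    rng: np.random.Generator,
    u_reactivity: float = 0.0,
    u_recovery: float = 0.0,
) -> tuple[float, int]:
    """Draw one event's reactivity change (ms) and recovery minutes.

    Reactivity: linear in centered resting lnRMSSD, MET above the
    reference level, and their product, plus person intercept and
    Gaussian noise.  Recovery: Poisson with log-mean linear in centered
    rest and the direction dummy (plus interaction), truncation at the
    timeout is flagged by the caller, never resampled.
    """
    met_c = met_during - config.met_reference
    delta = (
        config.beta_intercept
        + u_reactivity
        + config.beta_resting * rest_centered
        + config.beta_met * met_c
        + config.beta_interaction * rest_centered * met_c
        + rng.normal(0.0, config.reactivity_noise_sd)
    )
    log_mu = (
        config.gamma_intercept
        + u_recovery
        + config.gamma_resting * rest_centered
        + config.gamma_direction * direction_for_recovery
        + config.gamma_interaction * rest_centered * direction_for_recovery
    )
    recovery = int(rng.poisson(math.exp(log_mu)))
    return float(delta), recovery


# ---------------------------------------------------------------------------
# cohort simulation


def _waking_minutes(config: SimConfig, day: int) -> np.ndarray:
    start = int(day * 1440 + config.waking_start_hour * 60)
    end = int(day * 1440 + config.waking_end_hour * 60)
    return np.arange(start, end)


def _schedule_events(config: SimConfig, rng: np.random.Generator) -> list[tuple[int, float]]:
    """Event (start_minute, duration) pairs for one person, separated >= 12 min
    and >= 10 min from the waking-window edges."""
    out: list[tuple[int, float]] = []
    for day in range(config.n_days):
        n = rng.poisson(config.events_per_day_rate)
        if n == 0:
            continue
        mins = _waking_minutes(config, day)
        lo, hi = mins[0] + 10, mins[-1] - 10
        if hi <= lo:
            continue
        starts = np.sort(rng.integers(lo, hi + 1, size=n))
        kept: list[int] = []
        for s in starts:
            if not kept or s - kept[-1] >= 12:
                kept.append(int(s))
        meanlog, sdlog = config.event_duration_lognormal
        for s in kept:
            dur = float(np.clip(rng.lognormal(meanlog, sdlog), 1.0, 240.0))
            out.append((s, dur))
    return out


def _met_trajectory(
    config: SimConfig, minutes: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Minute-level MET with scheduled activity bouts.

    Returns the MET array plus the bout list as (start_minute,
    end_minute, level); bouts are what the pipeline later detects as
    physically stressful events.
    """
    met = config.met_baseline + 0.1 * np.abs(rng.standard_normal(minutes.size))
    bouts: list[tuple[int, int, float]] = []
    n_bouts = rng.poisson(config.met_bout_rate_per_day * config.n_days)
    for _ in range(n_bouts):
        length = int(rng.integers(config.met_bout_minutes[0], config.met_bout_minutes[1] + 1))
        if minutes.size <= length + 20:
            continue
        i = int(rng.integers(10, minutes.size - length - 10))
        # only apply the bout to a contiguous stretch of minutes
        if minutes[i + length - 1] - minutes[i] == length - 1:
            level = float(rng.uniform(*config.met_bout_level))
            met[i : i + length] = level
            bouts.append((int(minutes[i]), int(minutes[i + length - 1]), level))
    return met, sorted(bouts)


def simulate_cohort(config: SimConfig) -> tuple[dict[str, pd.DataFrame], GroundTruth]:
    """Generate a full multi-person dataset plus its ground truth.

    Returns a dict of tables — ``rr``, ``activity``, ``markers``,
    ``diary_prompts``, ``diary_events``, ``persons`` — and a
    :class:`GroundTruth`.  Identical config (including seed) yields
    byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    rr_rows, act_rows, marker_rows = [], [], []
    prompt_rows, diary_rows, person_rows = [], [], []
    truth_person, truth_event, truth_bout = [], [], []
    event_counter = 0

    for p in range(config.n_persons):
        pid = f"P{p:03d}"
        prng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        base_ln = prng.normal(*config.base_rmssd_lognormal)
        u_re = prng.normal(0.0, config.person_intercept_sd)
        u_rec = prng.normal(0.0, config.recovery_person_sd)
        truth_person.append({"person_id": pid, "base_lnrmssd": base_ln, "u_reactivity": u_re, "u_recovery": u_rec})

        minutes = np.concatenate([_waking_minutes(config, d) for d in range(config.n_days)])
        met, bouts = _met_trajectory(config, minutes, prng)
        supine = np.where(prng.random(minutes.size) < 0.03, prng.uniform(0.2, 1.0, minutes.size), 0.0)
        worn = np.ones(minutes.size, dtype=bool)
        if config.missing_fraction > 0:
            n_missing = int(round(config.missing_fraction * minutes.size))
            lost = 0
            while lost < n_missing:
                blk = int(prng.integers(3, 12))
                i = int(prng.integers(0, minutes.size - blk))
                worn[i : i + blk] = False
                lost = int((~worn).sum())

        target = np.exp(base_ln) * np.ones(minutes.size)
        pos = {int(m): i for i, m in enumerate(minutes)}

        # physical-exertion response: vmHRV drops during high-MET bouts
        # following the same structural equation, returning exponentially
        # afterwards (these become the device-detected events downstream)
        for b_start, b_end, level in bouts:
            rest_dev = prng.normal(0.0, config.within_person_rest_sd)
            rest_level = math.exp(base_ln + rest_dev)
            delta_b, _ = inject_event_response(rest_dev, level, 0, config, prng, u_re, u_rec)
            bout_level = max(rest_level + delta_b, 2.0)
            for m in range(b_start, b_end + 1):
                if m in pos:
                    target[pos[m]] = bout_level
            for m in range(b_end + 1, b_end + 31):
                if m in pos:
                    target[pos[m]] = rest_level + (bout_level - rest_level) * 0.5 ** (
                        (m - b_end) / config.recovery_halflife
                    )
            truth_bout.append(
                {
                    "person_id": pid,
                    "start_minute": b_start,
                    "end_minute": b_end,
                    "met_level": level,
                    "rest_lnrmssd": base_ln + rest_dev,
                    "delta_true": delta_b,
                }
            )

        events = _schedule_events(config, prng)
        start_minute_of_person = int(minutes[0])
        for start, dur in events:
            end = start + int(math.ceil(dur))
            rest_dev = prng.normal(0.0, config.within_person_rest_sd)
            rest_ln = base_ln + rest_dev
            rest_level = math.exp(rest_ln)
            # MET during the reactivity window
            react_idx = [pos[m] for m in range(start + 1, start + 6) if m in pos]
            met_during = float(np.mean(met[react_idx])) if react_idx else config.met_baseline
            delta, _ = inject_event_response(rest_dev, met_during, 0, config, prng, u_re, u_rec)
            react_level = max(rest_level + delta, 2.0)
            direction = int(delta > 0)
            _, recovery_true = inject_event_response(rest_dev, met_during, direction, config, prng, u_re, u_rec)
            truncated = recovery_true > config.recovery_timeout

            for m in range(start - 5, start):
                if m in pos:
                    target[pos[m]] = rest_level
            for m in range(start, end + 1):
                if m in pos:
                    target[pos[m]] = react_level
            for m in range(end + 1, end + recovery_true + 1):
                if m in pos:
                    target[pos[m]] = rest_level + (react_level - rest_level) * 0.5 ** (
                        (m - end) / config.recovery_halflife
                    )
            for m in range(end + recovery_true + 1, end + recovery_true + 10):
                if m in pos:
                    target[pos[m]] = rest_level

            marker_rows.append({"person_id": pid, "time_s": start * 60.0 + 1.0, "source": "self"})
            truth_event.append(
                {
                    "person_id": pid,
                    "event_id": event_counter,
                    "start_minute": start,
                    "end_minute": end,
                    "duration": dur,
                    "rest_lnrmssd": rest_ln,
                    "rest_centered": rest_dev,
                    "met_during": met_during,
                    "delta_true": delta,
                    "direction_true": direction,
                    "recovery_true": recovery_true,
                    "truncated": truncated,
                    "time_in_study_days": (start - start_minute_of_person) / 1440.0,
                }
            )
            event_counter += 1

        # accidental markers: taps later disavowed in the diary
        n_acc = prng.poisson(config.accident_marker_rate * config.n_days)
        accident_minutes = []
        for _ in range(n_acc):
            m = int(prng.choice(minutes))
            accident_minutes.append(m)
            marker_rows.append({"person_id": pid, "time_s": m * 60.0 + 1.0, "source": "self"})

        beat_t, beat_rr = synthesize_rr(target, minutes, config.mean_rr, prng)
        if config.artifact_fraction > 0:
            bad = prng.random(beat_rr.size) < config.artifact_fraction
            beat_rr = np.where(bad, beat_rr * prng.choice([0.45, 1.9], size=beat_rr.size), beat_rr)
        # drop beats in unworn minutes (device off)
        worn_set = set(minutes[worn].tolist())
        keep = np.isin(np.floor(beat_t / 60.0).astype(int), list(worn_set) or [-1])
        rr_rows.append(pd.DataFrame({"person_id": pid, "time_s": beat_t[keep], "rr_ms": beat_rr[keep]}))
        act_rows.append(
            pd.DataFrame(
                {"person_id": pid, "minute": minutes, "met": met, "supine_fraction": supine, "worn": worn}
            )
        )

        # bihourly diaries: 8 prompts/day, 2 h apart, first at 08:00
        prev_prompt = None
        for d in range(config.n_days):
            for h in range(8, 23, 2):
                pm = d * 1440 + h * 60
                flags = {
                    k: int(prng.random() < v) for k, v in config.covariate_prevalences.items()
                }
                lookback_start = prev_prompt if prev_prompt is not None else d * 1440
                n_reported = 0
                for ev in truth_event:
                    if ev["person_id"] != pid:
                        continue
                    if lookback_start <= ev["start_minute"] < pm:
                        rep_start = int(round(ev["start_minute"] + prng.normal(0, config.diary_time_noise_sd)))
                        rep_dur = max(1.0, ev["duration"] + prng.normal(0, config.diary_duration_noise_sd))
                        diary_rows.append(
                            {
                                "person_id": pid,
                                "diary_minute": pm,
                                "reported_start_minute": rep_start,
                                "reported_duration": round(rep_dur),
                                "accident": 0,
                                "true_event_id": ev["event_id"],
                            }
                        )
                        n_reported += 1
                for am in accident_minutes:
                    if lookback_start <= am < pm:
                        diary_rows.append(
                            {
                                "person_id": pid,
                                "diary_minute": pm,
                                "reported_start_minute": am,
                                "reported_duration": float("nan"),
                                "accident": 1,
                                "true_event_id": -1,
                            }
                        )
                        n_reported += 1
                prompt_rows.append({"person_id": pid, "diary_minute": pm, "n_events": n_reported, **flags})
                prev_prompt = pm
        accident_minutes.clear()

        # person-level covariates: latent chronic stress drives PSS items
        latent = prng.normal(0.0, 1.0)
        items = np.clip(np.round(1.6 + 0.8 * latent + prng.normal(0, 0.9, 10)), 0, 4).astype(int)
        stored = items.copy()
        for j in (3, 4, 6, 7):  # positively worded items stored pre-reversal
            stored[j] = 4 - items[j]
        person_rows.append(
            {
                "person_id": pid,
                **{f"pss_{i + 1}": int(stored[i]) for i in range(10)},
                "bmi": float(np.round(prng.normal(23.0, 3.0), 1)),
                "mvpa_hours": float(np.round(np.abs(prng.normal(5.0, 3.0)), 1)),
                "age": int(prng.integers(18, 60)),
                "sex": str(prng.choice(["f", "m"])),
            }
        )

    dataset = {
        "rr": pd.concat(rr_rows, ignore_index=True) if rr_rows else pd.DataFrame(columns=["person_id", "time_s", "rr_ms"]),
        "activity": pd.concat(act_rows, ignore_index=True),
        "markers": pd.DataFrame(marker_rows, columns=["person_id", "time_s", "source"]),
        "diary_prompts": pd.DataFrame(prompt_rows),
        "diary_events": pd.DataFrame(
            diary_rows,
            columns=["person_id", "diary_minute", "reported_start_minute", "reported_duration", "accident", "true_event_id"],
        ),
        "persons": pd.DataFrame(person_rows),
    }
    truth = GroundTruth(
        persons=pd.DataFrame(truth_person),
        events=pd.DataFrame(
            truth_event,
            columns=[
                "person_id", "event_id", "start_minute", "end_minute", "duration",
                "rest_lnrmssd", "rest_centered", "met_during", "delta_true",
                "direction_true", "recovery_true", "truncated", "time_in_study_days",
            ],
        ),
        fixed_effects={
            "beta_intercept": config.beta_intercept,
            "beta_resting": config.beta_resting,
            "beta_met": config.beta_met,
            "beta_interaction": config.beta_interaction,
            "gamma_intercept": config.gamma_intercept,
            "gamma_resting": config.gamma_resting,
            "gamma_direction": config.gamma_direction,
            "gamma_interaction": config.gamma_interaction,
        },
        variances={
            "person_intercept": config.person_intercept_sd**2,
            "residual": config.reactivity_noise_sd**2,
            "recovery_person_intercept": config.recovery_person_sd**2,
        },
        bouts=pd.DataFrame(
            truth_bout,
            columns=["person_id", "start_minute", "end_minute", "met_level",
                     "rest_lnrmssd", "delta_true"],
        ),
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# table-level simulation for replicate studies


def _sample_met(rng: np.random.Generator, n: int) -> np.ndarray:
    """Event-level MET: mostly sedentary with an active tail (M~1.7, SD~1.3)."""
    return 1.0 + rng.gamma(0.36, 1.95, size=n)


def simulate_reactivity_table(
    config: SimConfig,
    seed: int,
    n_persons: int = 60,
    events_per_person_mean: float = 10.0,
) -> pd.DataFrame:
    """Event-level reactivity table drawn from the structural equations.

    Produces exactly the columns the reactivity model consumes, with
    covariates centered the way the assembly stage centers them, so
    fitted coefficients estimate the configured betas directly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_persons):
        pid = f"P{p:03d}"
        u = rng.normal(0.0, config.person_intercept_sd)
        n_ev = max(2, rng.poisson(events_per_person_mean))
        c = rng.normal(0.0, config.within_person_rest_sd, n_ev)
        c = c - c.mean()  # group-mean centering, as in the pipeline
        met = _sample_met(rng, n_ev)
        met_c = met - config.met_reference
        eps = rng.normal(0.0, config.reactivity_noise_sd, n_ev)
        delta = (
            config.beta_intercept
            + u
            + config.beta_resting * c
            + config.beta_met * met_c
            + config.beta_interaction * c * met_c
            + eps
        )
        for j in range(n_ev):
            rows.append(
                {
                    "person_id": pid,
                    "event_id": p * 1000 + j,
                    "delta_rmssd": delta[j],
                    "direction": int(delta[j] > 0),
                    "resting_lnrmssd_c": c[j],
                    "reactivity_met_c": met_c[j],
                    "resting_met_c": rng.normal(0.0, 0.5),
                    "resting_supine_c": rng.normal(0.0, 0.3),
                    "reactivity_supine_c": rng.normal(0.0, 0.3),
                    "time_in_study_c": rng.uniform(-2.0, 2.0),
                    "caffeine": int(rng.random() < 0.27),
                    "alcohol": int(rng.random() < 0.04),
                    "nicotine": int(rng.random() < 0.08),
                    "anticipated_stress": int(rng.random() < 0.27),
                    "ambient_noise": int(rng.random() < 0.08),
                    "mvpa_hours_c": rng.normal(0.0, 3.0),
                    "bmi_c": rng.normal(0.0, 3.0),
                    "chronic_stress_z": rng.normal(0.0, 1.0),
                }
            )
    return pd.DataFrame(rows)


def simulate_recovery_table(
    config: SimConfig,
    seed: int,
    n_persons: int = 60,
    events_per_person_mean: float = 10.0,
) -> pd.DataFrame:
    """Recovery-minutes table with the model's censoring semantics.

    Counts exceeding the timeout are flagged ``timeout``; a small
    configured fraction is flagged ``pileup``.  Neither is resampled.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_persons):
        pid = f"P{p:03d}"
        u = rng.normal(0.0, config.recovery_person_sd)
        n_ev = max(2, rng.poisson(events_per_person_mean))
        for j in range(n_ev):
            c = rng.normal(0.0, config.within_person_rest_sd)
            direction = int(rng.random() < 0.5)
            rmet_c = rng.normal(0.0, 0.5)
            recmet_c = rng.normal(0.0, 0.4)
            t_c = rng.uniform(-2.0, 2.0)
            log_mu = (
                config.gamma_intercept
                + u
                + config.gamma_resting * c
                + config.gamma_direction * direction
                + config.gamma_interaction * c * direction
                + config.gamma_resting_met * rmet_c
                + config.gamma_recovery_met * recmet_c
                + config.gamma_time * t_c
            )
            y = int(rng.poisson(math.exp(log_mu)))
            if rng.random() < config.pileup_rate:
                status = "pileup"
            elif y > config.recovery_timeout:
                status = "timeout"
            else:
                status = "reached"
            rows.append(
                {
                    "person_id": pid,
                    "event_id": p * 1000 + j,
                    "recovery_minutes": float(y) if status == "reached" else float("nan"),
                    "status": status,
                    "direction": direction,
                    "resting_lnrmssd_c": c,
                    "resting_met_c": rmet_c,
                    "recovery_met_c": recmet_c,
                    "time_in_study_c": t_c,
                }
            )
    return pd.DataFrame(rows)
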