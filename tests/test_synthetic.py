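"""The synthetic cohort generator: determinism, calibration, schedule integrity."""

import math

import numpy as np
import pandas as pd
import pytest

from hrvstress.hrv import RRSeries, aggregate_minutes, segment_rmssd
from hrvstress.synthetic import (
    ConfigError,
    SimConfig,
    inject_event_response,
    simulate_cohort,
    simulate_recovery_table,
    synthesize_rr,
)

from conftest import make_activity


def small_config(**kw):
    defaults = dict(n_persons=3, n_days=2, seed=11)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_days": 0},
            {"waking_start_hour": 22, "waking_end_hour": 8},
            {"missing_fraction": 1.5},
            {"recovery_halflife": 0.0},
            {"mean_rr": 200.0},
        ],
    )
    def test_degenerate_configs_rejected(self, kw):
        with pytest.raises(ConfigError):
            SimConfig(**kw).validate()


class TestSimulateCohort:
    def test_zero_event_rate_gives_zero_markers(self):
        cfg = small_config(events_per_day_rate=0.0, accident_marker_rate=0.0)
        ds, truth = simulate_cohort(cfg)
        assert len(ds["markers"]) == 0
        assert len(truth.events) == 0

    def test_determinism_under_seed(self):
        cfg1, cfg2 = small_config(), small_config()
        ds1, t1 = simulate_cohort(cfg1)
        ds2, t2 = simulate_cohort(cfg2)
        for k in ds1:
            pd.testing.assert_frame_equal(ds1[k], ds2[k])
        pd.testing.assert_frame_equal(t1.events, t2.events)

    def test_marker_rate_matches_configuration(self):
        cfg = SimConfig(n_persons=50, n_days=4, events_per_day_rate=2.0,
                        accident_marker_rate=0.0, seed=3)
        _, truth = simulate_cohort(cfg)
        per_person = truth.events.groupby("person_id").size().reindex(
            truth.persons["person_id"], fill_value=0
        )
        # scheduling thins events closer than 12 min, so the realized rate
        # sits slightly below 8/person; allow 3 standard errors around it
        expected = 8.0
        se = math.sqrt(expected / 50)
        assert per_person.mean() == pytest.approx(expected, abs=3 * se + 0.5)

    def test_every_marker_at_scheduled_event_start(self):
        cfg = small_config(accident_marker_rate=0.0)
        ds, truth = simulate_cohort(cfg)
        marker_minutes = np.floor(ds["markers"]["time_s"] / 60.0).astype(int)
        assert sorted(marker_minutes.tolist()) == sorted(
            truth.events["start_minute"].tolist()
        )

    def test_diary_reports_map_one_to_one_to_true_events(self):
        cfg = small_config(accident_marker_rate=0.0)
        ds, truth = simulate_cohort(cfg)
        de = ds["diary_events"]
        assert de["true_event_id"].is_unique
        assert set(de["true_event_id"]) == set(truth.events["event_id"])

    def test_clean_config_yields_computable_segments(self):
        """Without missingness/artifacts every event has usable segments."""
        cfg = small_config(missing_fraction=0.0, artifact_fraction=0.0)
        ds, truth = simulate_cohort(cfg)
        for pid, act in ds["activity"].groupby("person_id"):
            rrp = ds["rr"][ds["rr"]["person_id"] == pid]
            series = RRSeries(rrp["time_s"].to_numpy(), rrp["rr_ms"].to_numpy())
            minutes = aggregate_minutes(series, act.drop(columns="person_id"))
            for _, ev in truth.events[truth.events["person_id"] == pid].iterrows():
                m = int(ev["start_minute"])
                assert segment_rmssd(minutes, m - 5).defined
                assert segment_rmssd(minutes, m + 1).defined

    def test_truth_fixed_effects_echo_config(self):
        cfg = small_config()
        _, truth = simulate_cohort(cfg)
        assert truth.fixed_effects["beta_resting"] == cfg.beta_resting
        assert truth.variances["person_intercept"] == cfg.person_intercept_sd**2


class TestSynthesizeRR:
    def test_zero_target_constant_series(self, rng):
        t, rr = synthesize_rr(np.zeros(3), np.arange(3), 800.0, rng)
        assert np.allclose(rr, 800.0)

    def test_nonpositive_trajectory_rejected(self, rng):
        with pytest.raises(ValueError):
            synthesize_rr(np.array([40.0, -1.0]), np.arange(2), 800.0, rng)
        with pytest.raises(ValueError):
            synthesize_rr(np.array([40.0]), np.arange(1), 200.0, rng)

    def test_sigma_sqrt2_identity_monte_carlo(self):
        """Mean realized RMSSD over many seeds matches the 40-ms target."""
        target = np.full(10, 40.0)
        vals = []
        for seed in range(120):
            rng = np.random.default_rng(seed)
            t, rr = synthesize_rr(target, np.arange(10), 800.0, rng)
            d = np.diff(rr)
            same_minute = np.floor(t / 60.0).astype(int)
            keep = same_minute[1:] == same_minute[:-1]
            vals.append(np.sqrt(np.mean(d[keep] ** 2)))
        assert 36.0 <= np.mean(vals) <= 44.0

    def test_step_trajectory_lowers_rmssd(self):
        target = np.r_[np.full(10, 40.0), np.full(10, 20.0)]
        hits = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            t, rr = synthesize_rr(target, np.arange(20), 800.0, rng)
            minutes = aggregate_minutes(
                RRSeries(t, rr), make_activity(range(20))
            )
            early = segment_rmssd(minutes, 0, 0.5).rmssd
            late = segment_rmssd(minutes, 11, 0.5).rmssd
            hits += late < early
        assert hits >= 0.95 * n_seeds

    def test_calibration_tracks_trajectory(self):
        """Per-minute realized RMSSD within 15% of target, averaged over seeds."""
        target = np.array([20.0, 35.0, 50.0, 65.0, 80.0])
        realized = np.zeros_like(target)
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t, rr = synthesize_rr(target, np.arange(5), 800.0, rng)
            minute = np.floor(t / 60.0).astype(int)
            for i in range(5):
                d = np.diff(rr[minute == i])
                realized[i] += np.sqrt(np.mean(d**2))
        realized /= n_seeds
        assert np.all(np.abs(realized - target) / target < 0.15)


class TestInjectEventResponse:
    def test_all_zero_betas_zero_delta(self, rng):
        cfg = SimConfig(beta_intercept=0, beta_resting=0, beta_met=0,
                        beta_interaction=0, reactivity_noise_sd=0)
        delta, _ = inject_event_response(0.5, 3.0, 0, cfg, rng)
        assert delta == 0.0

    def test_met_linearity(self, rng):
        cfg = SimConfig(beta_intercept=0, beta_resting=0, beta_met=-5.0,
                        beta_interaction=0, reactivity_noise_sd=0)
        d1, _ = inject_event_response(0.0, 1.0, 0, cfg, rng)
        d3, _ = inject_event_response(0.0, 3.0, 0, cfg, rng)
        assert d3 - d1 == pytest.approx(-10.0)

    def test_recovery_log_mean_closed_form(self):
        """Poisson draws with log-mean 2.0 average to e^2 within 3 SE."""
        cfg = SimConfig(gamma_intercept=2.0, gamma_resting=0, gamma_direction=0,
                        gamma_interaction=0)
        rng = np.random.default_rng(99)
        draws = np.array(
            [inject_event_response(0.0, 1.7, 0, cfg, rng)[1] for _ in range(10_000)]
        )
        mu = math.e**2
        se = math.sqrt(mu / draws.size)
        assert abs(draws.mean() - mu) <= 3 * se


class TestRecoveryTable:
    def test_censoring_proportions_match_configuration(self):
        cfg = SimConfig(pileup_rate=0.05)
        t = simulate_recovery_table(cfg, seed=5, n_persons=120, events_per_person_mean=10)
        n = len(t)
        pile = (t["status"] == "pileup").mean()
        se = math.sqrt(0.05 * 0.95 / n)
        assert abs(pile - 0.05) <= 3.5 * se
        reached = t[t["status"] == "reached"]
        assert (reached["recovery_minutes"] <= cfg.recovery_timeout).all()

    def test_statuses_exhaustive(self):
        t = simulate_recovery_table(SimConfig(), seed=6, n_persons=30)
        assert set(t["status"]) <= {"reached", "pileup", "timeout"}
        assert t.loc[t["status"] != "reached", "recovery_minutes"].isna().all()
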