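"""Multilevel model fitting: recovery of known effects, cross-validation
against an independent mixed-model implementation, and report layout."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from hrvstress.glmm import fit_poisson_glmm
from hrvstress.models import (
    ReactivityModelSpec,
    RecoveryModelSpec,
    fit_reactivity,
    fit_recovery,
    summarize,
)
from hrvstress.synthetic import SimConfig, simulate_reactivity_table, simulate_recovery_table


def null_config(**kw):
    base = dict(
        beta_intercept=0.0, beta_resting=0.0, beta_met=0.0, beta_interaction=0.0,
        gamma_resting=0.0, gamma_direction=0.0, gamma_interaction=0.0,
        gamma_resting_met=0.0, gamma_recovery_met=0.0, gamma_time=0.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestReactivityModel:
    def test_null_effects_center_on_zero(self):
        ests = []
        for r in range(12):
            t = simulate_reactivity_table(null_config(), seed=300 + r, n_persons=40)
            f = fit_reactivity(t).params.set_index("term")
            ests.append(f.loc["resting_lnrmssd_c", "estimate"])
        se_mean = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests)) <= 2.5 * se_mean + 0.05

    def test_recovers_structural_betas(self):
        t = simulate_reactivity_table(SimConfig(), seed=77, n_persons=120,
                                      events_per_person_mean=12)
        f = fit_reactivity(t).params.set_index("term")
        assert f.loc["resting_lnrmssd_c", "estimate"] == pytest.approx(-14.06, rel=0.15)
        assert f.loc["reactivity_met_c", "estimate"] == pytest.approx(-3.55, rel=0.20)

    def test_zero_between_person_variance_boundary(self):
        cfg = SimConfig(person_intercept_sd=0.0)
        t = simulate_reactivity_table(cfg, seed=9, n_persons=50)
        fit = fit_reactivity(t)
        assert fit.variance_components["person_intercept"] <= 5.0

    def test_interaction_reparameterization_shifts_main_effect(self):
        """Shifting the moderator by c changes the resting slope by c*interaction."""
        t = simulate_reactivity_table(SimConfig(), seed=13, n_persons=60)
        spec = ReactivityModelSpec(terms=["resting_lnrmssd_c", "reactivity_met_c",
                                          "resting_lnrmssd_c:reactivity_met_c"])
        f1 = fit_reactivity(t, spec).params.set_index("term")
        shift = 2.0
        t2 = t.copy()
        t2["reactivity_met_c"] = t2["reactivity_met_c"] + shift
        f2 = fit_reactivity(t2, spec).params.set_index("term")
        inter = f1.loc["resting_lnrmssd_c:reactivity_met_c", "estimate"]
        expected = f1.loc["resting_lnrmssd_c", "estimate"] - shift * inter
        assert f2.loc["resting_lnrmssd_c", "estimate"] == pytest.approx(expected, rel=1e-3)

    def test_rank_deficient_design_names_aliased_term(self):
        t = simulate_reactivity_table(SimConfig(), seed=21, n_persons=20)
        t["dup"] = t["resting_lnrmssd_c"]
        spec = ReactivityModelSpec(terms=["resting_lnrmssd_c", "dup"])
        with pytest.raises(ValueError, match="alias"):
            fit_reactivity(t, spec)

    def test_too_few_persons_rejected(self):
        t = simulate_reactivity_table(SimConfig(), seed=2, n_persons=1)
        with pytest.raises(ValueError, match="persons"):
            fit_reactivity(t)


class TestRecoveryModel:
    def test_null_irrs_near_one(self):
        irrs = []
        for r in range(10):
            t = simulate_recovery_table(null_config(), seed=400 + r, n_persons=40)
            f = fit_recovery(t).params.set_index("term")
            irrs.append(f.loc["resting_lnrmssd_c", "irr"])
        assert np.mean(irrs) == pytest.approx(1.0, abs=0.08)

    def test_censored_rows_excluded_from_fit(self):
        t = simulate_recovery_table(SimConfig(pileup_rate=0.3), seed=8, n_persons=40)
        fit = fit_recovery(t)
        assert fit.n_obs == int((t["status"] == "reached").sum())

    def test_all_zero_outcome_rejected(self):
        t = simulate_recovery_table(SimConfig(), seed=3, n_persons=10)
        t["recovery_minutes"] = 0.0
        with pytest.raises(ValueError):
            fit_recovery(t)

    def test_doubling_counts_scales_intercept_only(self):
        t = simulate_recovery_table(SimConfig(), seed=15, n_persons=50)
        f1 = fit_recovery(t).params.set_index("term")
        t2 = t.copy()
        t2["recovery_minutes"] = t2["recovery_minutes"] * 2
        f2 = fit_recovery(t2).params.set_index("term")
        assert f2.loc["Intercept", "estimate"] - f1.loc["Intercept", "estimate"] == pytest.approx(np.log(2), abs=0.02)
        assert f2.loc["resting_lnrmssd_c", "irr"] == pytest.approx(
            f1.loc["resting_lnrmssd_c", "irr"], rel=0.03
        )

    def test_sigma_fixed_at_zero_reproduces_plain_poisson(self):
        """Holding the random-intercept SD at 0 collapses to an ordinary GLM."""
        cfg = SimConfig(recovery_person_sd=1e-8)
        t = simulate_recovery_table(cfg, seed=31, n_persons=60)
        t = t[t["status"] == "reached"]
        X = sm.add_constant(t[["resting_lnrmssd_c", "direction"]].to_numpy())
        glm = sm.GLM(t["recovery_minutes"], X, family=sm.families.Poisson()).fit()
        mm = fit_poisson_glmm(
            t["recovery_minutes"].to_numpy(), X, t["person_id"].to_numpy(),
            exog_names=["const", "rest", "dir"], sigma_fixed=0.0,
        )
        assert np.allclose(mm.params, glm.params, atol=1e-5)
        assert np.allclose(mm.bse, glm.bse, rtol=1e-3)
        # the free fit on near-homogeneous persons stays close too
        free = fit_poisson_glmm(
            t["recovery_minutes"].to_numpy(), X, t["person_id"].to_numpy(),
            exog_names=["const", "rest", "dir"],
        )
        assert np.allclose(free.params, glm.params, atol=0.05)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestAgainstLme4:
    def test_poisson_glmm_matches_glmer(self, tmp_path):
        """The in-package adaptive-quadrature fit reproduces lme4::glmer."""
        t = simulate_recovery_table(SimConfig(), seed=42, n_persons=40,
                                    events_per_person_mean=8)
        t = t[t["status"] == "reached"]
        csv = tmp_path / "d.csv"
        t.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(recovery_minutes ~ resting_lnrmssd_c * direction +
                       resting_met_c + recovery_met_c + time_in_study_c +
                       (1 | person_id), data = d, family = poisson, nAGQ = 15)
            co <- summary(m)$coefficients
            write.csv(data.frame(term = rownames(co), est = co[, 1], se = co[, 2]),
                      "{tmp_path / 'out.csv'}", row.names = FALSE)
        """))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ours = fit_recovery(t).params.set_index("term")
        theirs = pd.read_csv(tmp_path / "out.csv").set_index("term")
        mapping = {
            "Intercept": "(Intercept)",
            "resting_lnrmssd_c": "resting_lnrmssd_c",
            "direction": "direction",
            "resting_lnrmssd_c:direction": "resting_lnrmssd_c:direction",
        }
        for ot, rt in mapping.items():
            assert ours.loc[ot, "estimate"] == pytest.approx(theirs.loc[rt, "est"], abs=1e-3)
            assert ours.loc[ot, "se"] == pytest.approx(theirs.loc[rt, "se"], rel=1e-2)


class TestSummarize:
    def test_recovery_report_on_irr_scale(self):
        t = simulate_recovery_table(SimConfig(), seed=1, n_persons=30)
        fit = fit_recovery(t)
        text = summarize(fit)
        assert "IRR" in text and "Intercept" in text
        assert "person_intercept" in text

    def test_reactivity_report_has_variances(self):
        t = simulate_reactivity_table(SimConfig(), seed=1, n_persons=30)
        fit = fit_reactivity(t)
        text = summarize(fit)
        assert "Est" in text and "residual" in text

    def test_intercept_only_model(self):
        t = simulate_reactivity_table(SimConfig(), seed=1, n_persons=30)
        spec = ReactivityModelSpec(terms=["1"])
        fit = fit_reactivity(t, spec)
        assert len(fit.params) == 1
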