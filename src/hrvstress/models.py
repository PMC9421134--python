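"""The two multilevel models: RMSSD reactivity and RMSSD recovery.

Reactivity (continuous ms change in RMSSD during an event relative to
the preceding resting level) is modeled with a linear mixed model with
a person random intercept, the within-person-centered resting lnRMSSD,
the event's MET level, their interaction, and the measurement
covariates.  Recovery (minutes until RMSSD returns to the resting
level) is a count outcome modeled with a Poisson random-intercept
model on the log link; censored recoveries (pile-up / timeout) are
excluded, and estimates are reported as incidence-rate ratios.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from patsy import dmatrix

from .glmm import fit_poisson_glmm

log = logging.getLogger(__name__)

__all__ = [
    "ReactivityModelSpec",
    "RecoveryModelSpec",
    "FitResult",
    "fit_reactivity",
    "fit_recovery",
    "summarize",
]

#: Full covariate set for the reactivity model.  Nicotine is
#: available in the tables but excluded by default (rarely reported;
#: destabilizes estimation in sparse cohorts).
REACTIVITY_TERMS = [
    "resting_lnrmssd_c",
    "reactivity_met_c",
    "resting_lnrmssd_c:reactivity_met_c",
    "resting_met_c",
    "resting_supine_c",
    "reactivity_supine_c",
    "time_in_study_c",
    "caffeine",
    "alcohol",
    "anticipated_stress",
    "ambient_noise",
    "mvpa_hours_c",
    "bmi_c",
    "chronic_stress_z",
]

#: Reduced covariate set of the recovery model (larger sets failed to
#: converge in the source cohort and are not the default).
RECOVERY_TERMS = [
    "resting_lnrmssd_c",
    "direction",
    "resting_lnrmssd_c:direction",
    "resting_met_c",
    "recovery_met_c",
    "time_in_study_c",
]


@dataclass
class ReactivityModelSpec:
    outcome: str = "delta_rmssd"
    terms: list[str] = field(default_factory=lambda: list(REACTIVITY_TERMS))
    group: str = "person_id"
    reml: bool = True

    @property
    def formula(self) -> str:
        return f"{self.outcome} ~ {' + '.join(self.terms)}"


@dataclass
class RecoveryModelSpec:
    outcome: str = "recovery_minutes"
    terms: list[str] = field(default_factory=lambda: list(RECOVERY_TERMS))
    group: str = "person_id"
    nagq: int = 15

    @property
    def formula(self) -> str:
        return f"{self.outcome} ~ {' + '.join(self.terms)}"


@dataclass
class FitResult:
    """Uniform fit report for both models.

    ``params`` has one row per fixed-effect term with estimate, SE,
    p-value and 95% interval (plus IRR columns for the recovery
    model).  ``variance_components`` maps component name to variance.
    """

    model: str  # "reactivity" | "recovery"
    params: pd.DataFrame
    variance_components: dict[str, float]
    n_obs: int
    n_persons: int
    converged: bool
    loglike: float
    message: str = ""


def _drop_constant_terms(table: pd.DataFrame, terms: list[str]) -> tuple[list[str], list[str]]:
    """Remove covariates with no variation (non-identifiable in this sample).

    Rarely reported binary exposures can be all-zero in a small cohort;
    they carry no information and alias the intercept.  Interactions
    lose any dropped component.  Returns (kept, dropped).
    """
    dropped = [
        t for t in terms
        if ":" not in t and t in table.columns and table[t].nunique(dropna=True) <= 1
    ]
    kept = [
        t for t in terms
        if t not in dropped and not (":" in t and any(p in dropped for p in t.split(":")))
    ]
    return kept, dropped


def _check_nesting(table: pd.DataFrame, group: str) -> None:
    counts = table.groupby(group).size()
    if len(counts) < 2 or (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 persons with at least 2 events each")


def fit_reactivity(table: pd.DataFrame, spec: ReactivityModelSpec | None = None) -> FitResult:
    """Linear mixed model of RMSSD reactivity with a person random intercept.

    Fit by REML; fixed-effect p-values use the normal (Wald z)
    approximation.  A boundary random-intercept variance (-> 0) is
    reported as-is, not hidden.
    """
    spec = spec or ReactivityModelSpec()
    _check_nesting(table, spec.group)
    terms, dropped = _drop_constant_terms(table, spec.terms)
    if dropped:
        log.warning("dropping constant covariates with no variation: %s", dropped)
    spec = ReactivityModelSpec(spec.outcome, terms, spec.group, spec.reml)
    _check_rank(table, spec.terms)
    model = smf.mixedlm(spec.formula, data=table, groups=table[spec.group])
    fit = None
    for method in ("lbfgs", "bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                candidate = model.fit(reml=spec.reml, method=method)
        except np.linalg.LinAlgError:
            continue
        fit = candidate
        if candidate.converged:
            break
    if fit is None:
        raise RuntimeError("mixed model estimation failed with every optimizer")

    names = list(fit.fe_params.index)
    est = fit.fe_params.to_numpy()
    se = fit.bse_fe.to_numpy()
    z = stats.norm.ppf(0.975)
    params = pd.DataFrame(
        {
            "term": names,
            "estimate": est,
            "se": se,
            "p": 2 * stats.norm.sf(np.abs(est / se)),
            "ci_low": est - z * se,
            "ci_high": est + z * se,
        }
    )
    vc = {
        "person_intercept": float(fit.cov_re.iloc[0, 0]),
        "residual": float(fit.scale),
    }
    return FitResult(
        model="reactivity",
        params=params,
        variance_components=vc,
        n_obs=int(fit.nobs),
        n_persons=int(table[spec.group].nunique()),
        converged=bool(fit.converged),
        loglike=float(fit.llf),
    )


def fit_recovery(table: pd.DataFrame, spec: RecoveryModelSpec | None = None) -> FitResult:
    """Poisson random-intercept model of recovery minutes, reported as IRRs.

    Only uncensored recoveries (status ``reached``) enter the fit; the
    outcome must be non-negative integers (minutes on the 60-s grid).
    """
    spec = spec or RecoveryModelSpec()
    df = table
    if "status" in df.columns:
        df = df[df["status"] == "reached"]
    model_cols = [spec.group, spec.outcome] + [t for t in spec.terms if ":" not in t]
    df = df[model_cols].dropna().reset_index(drop=True)
    if df.empty:
        raise ValueError("recovery table has no complete uncensored rows")
    _check_nesting(df, spec.group)
    terms, dropped = _drop_constant_terms(df, spec.terms)
    if dropped:
        log.warning("dropping constant covariates with no variation: %s", dropped)
    spec = RecoveryModelSpec(spec.outcome, terms, spec.group, spec.nagq)
    _check_rank(df, spec.terms)

    X = dmatrix("1 + " + " + ".join(spec.terms), df, return_type="dataframe")
    fit = fit_poisson_glmm(
        df[spec.outcome].to_numpy(),
        X.to_numpy(),
        df[spec.group].to_numpy(),
        exog_names=list(X.columns),
        nagq=spec.nagq,
    )
    params = fit.summary_frame()
    vc = {"person_intercept": fit.sigma**2}
    return FitResult(
        model="recovery",
        params=params,
        variance_components=vc,
        n_obs=fit.n_obs,
        n_persons=fit.n_groups,
        converged=fit.converged,
        loglike=fit.loglike,
        message=fit.message,
    )


def _check_rank(table: pd.DataFrame, terms: list[str]) -> None:
    """Fail early on aliased (rank-deficient) fixed-effect designs."""
    X = dmatrix("1 + " + " + ".join(terms), table.dropna(), return_type="dataframe")
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        aliased = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def summarize(fit: FitResult, float_fmt: str = "{:.3f}") -> str:
    """Plain-text report: fixed effects, variance components, sample sizes."""
    lines = [f"Model: {fit.model}", "-" * 72]
    df = fit.params.copy()
    if fit.model == "recovery" and "irr" in df.columns:
        show = df[["term", "irr", "se", "p", "irr_low", "irr_high"]]
        header = f"{'term':<40}{'IRR':>9}{'SE':>9}{'p':>9}{'LL':>9}{'UL':>9}"
    else:
        show = df[["term", "estimate", "se", "p", "ci_low", "ci_high"]]
        header = f"{'term':<40}{'Est':>9}{'SE':>9}{'p':>9}{'LL':>9}{'UL':>9}"
    lines.append(header)
    for _, row in show.iterrows():
        vals = "".join(f"{float_fmt.format(v):>9}" for v in row.iloc[1:])
        lines.append(f"{row.iloc[0]:<40}{vals}")
    lines.append("Random effects (variances):")
    for k, v in fit.variance_components.items():
        lines.append(f"  {k:<30}{float_fmt.format(v):>9}")
    lines.append(f"n_observations = {fit.n_obs}; n_persons = {fit.n_persons}")
    lines.append(f"converged = {fit.converged}; logLik = {float_fmt.format(fit.loglike)}")
    return "\n".join(lines)
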