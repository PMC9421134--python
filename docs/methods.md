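# Methods

This note documents the models, conventions, and numerical choices
behind `hrvstress`, and what the synthetic cohorts do and do not
establish about real data.

## Signal model and RMSSD segmentation

The pipeline starts at RR intervals (ms); R-peak detection and
amplitude-based screening are upstream of its scope. Artifact
screening keeps a beat when it lies in [300, 2000] ms and differs from
the **previous valid** beat by at most a relative fraction
(`max_rel_change`, default 0.25). The first in-range beat is valid by
definition. Both parameters are configurable; the defaults follow
common ambulatory practice for relative-change beat filters. The
comparison against the last accepted beat (rather than the immediate
predecessor) prevents a single ectopic from invalidating the rest of a
minute.

Screened beats are collapsed to 60-s records holding the valid-beat
count, the sum of valid RR, and the sum and count of squared
successive differences. A successive pair requires two *adjacent*
beats, both valid, both inside the same minute: removed artifacts
break pairs, and pairs straddling a minute boundary count for neither
minute. Pooling across minute boundaries is a genuine convention
choice; the within-minute convention makes the minute record a
self-contained sufficient statistic and is applied consistently in the
generator, the pipeline, and the test oracles.

Segment RMSSD over five consecutive minutes is
`sqrt(Σ ssd / Σ pairs)` — algebraically identical to RMSSD computed on
the concatenated within-minute differences, which is what the
brute-force oracle in the tests verifies. A segment is missing when
any minute is unworn or absent, or when the valid-beat count falls
below `min_coverage` (default 0.8) of the expected count, where the
expectation is 300 s divided by the segment's own mean valid RR. The
0.8 default is a package choice: the upstream convention is listwise
deletion of unusable segments without a published threshold. RMSSD 0
(constant RR, which arises only in toy inputs) maps to missing
lnRMSSD rather than −∞. Logs are natural logs throughout.

## Events

Markers are floored to whole minutes on the 60-s grid. The marker
minute itself is transitional and belongs to neither window: resting is
[m−5, m−1], reactivity [m+1, m+5]. Validity rules are applied in the
order not-worn, accidental, too-short (matched diary duration < 5 min,
strict), then same-segment; the same-segment rule runs chronologically
against the previous *kept* marker's reactivity window, which keeps the
maximal set of events and is deterministic. Each excluded marker
carries exactly one reason. Markers without a matched diary duration
are kept (the duration rule cannot be evaluated, and reactivity does
not need it).

Device-detected physically stressful events are maximal runs of worn
minutes with MET ≥ 3.0 lasting ≥ 5 min; the marker sits at the run's
first minute, and runs overlapping a kept self-marker's reactivity
window are suppressed rather than double-counted. Their resting window
is the 5 min immediately preceding the run, symmetric with
self-markers.

ΔRMSSD and the direction dummy are computed on the raw (not log)
RMSSD scale. An exact tie ΔRMSSD = 0 is coded as a decrease (0) with a
logged warning; ties do not occur in continuous data but need a
deterministic rule for synthetic inputs.

## Recovery

Diary reports are matched to kept self-markers one-to-one in
chronological order; each report takes the free marker closest to its
reported start time, within ±120 min inclusive, with equidistant ties
resolved to the earlier marker (the conservative causal candidate).
The event end is the marker minute plus the reported duration, ceiled
to the grid. From the end, 5-min windows shifted in 1-min steps are
scanned: a decrease event recovers at the first shift k whose window
RMSSD is ≥ the resting RMSSD, an increase event at the first k with
window ≤ resting; equality counts as recovered. At each k the pile-up
censor is evaluated *before* the window: a subsequent marker inside
the current window invalidates it. k may reach 120; k = 121 censors as
timeout (consistent with observed recoveries up to 111 min in the kind
of cohort this emulates). Windows with missing RMSSD are skipped and
counted. Device-detected events have no self-reported duration, so
recovery is computed for diary-matched self-marked events only.

## Covariates and assembly

Substance and anticipation flags are 1 when any positive diary
prompt's 2-h look-back window (a closed interval) overlaps the closed
±2 h around the event; ambient noise uses the preceding 2 h only.
MET values above 79.8 (three times typical peak functional capacity)
are physiologically improbable and flagged missing. PSS-10 chronic
stress is scored 0–4 per item with the four positively worded items
reverse-coded (total 0–40) and standardized; any missing item makes
the person missing. Winsorization at ±3 SD uses the pre-replacement
mean and SD in a single pass, applied per variable on the event-level
table after the log transform of resting RMSSD and before centering
(the ordering is a package decision; the upstream description does not
fix it). Resting lnRMSSD is group-mean centered within person; other
continuous covariates are grand-mean centered; chronic stress enters
as z-scores. Time in study is days since the person's first recording
minute. Rows with any missing model variable are deleted listwise.

## Models

The reactivity model is a person-random-intercept linear mixed model
fit by REML through `statsmodels` MixedLM, with an optimizer fallback
chain (lbfgs → bfgs → powell → Nelder–Mead) because boundary variance
estimates can destabilize individual optimizers. Fixed-effect p-values
and intervals use the normal (Wald z) approximation; no
degrees-of-freedom correction is applied, and this choice is
documented rather than claimed equivalent to Satterthwaite-type
inference. Boundary random-intercept variances (→ 0) are reported
as-is.

The recovery model is a Poisson random-intercept regression on the log
link, maximum likelihood via 1-D adaptive Gauss–Hermite quadrature
(default 15 nodes): per person the integrand collapses to
`exp(B + S·u − A·e^u − u²/2σ²)`, whose mode has a closed-form Newton
iteration, and quadrature nodes are centered and scaled there. The
optimizer works on (β, log σ) with BFGS and a Nelder–Mead polish;
standard errors come from the numerical Hessian at the optimum (σ's SE
by the delta method). No Python package in the stack fits this model
by maximum likelihood, so it is implemented here and cross-validated
in the tests against `lme4::glmer(nAGQ = 15)`, agreeing to ~1e-3 in
estimates and standard errors. Censored recoveries (pile-up, timeout)
are excluded from the fit; estimates are reported as incidence-rate
ratios. Covariates with no variation in the sample (e.g. an exposure
nobody reported) are non-identifiable, alias the intercept, and are
dropped with a warning — mirroring how such covariates must be handled
in small ambulatory cohorts; genuinely collinear non-constant designs
still raise an error naming the aliased terms. Random slopes are
deliberately out of scope (intercept-only random effects).

## Synthetic cohorts

The generator reproduces the study design it targets: 4 recording
days, waking window 08:00–22:00, 8 diary prompts/day 2 h apart from
08:00, ~2 self-marked events/day (≈ 8 markers per person over 4 days),
event durations lognormal(meanlog 2.49, sdlog 1.05) clipped to
[1, 240] min (mean ≈ 21, SD ≈ 30), and resting RMSSD lognormal across
persons (meanlog 3.56 ≈ 35 ms median, between-person sdlog 0.45,
within-person event-to-event sd 0.30 ln-units). The within-person
dispersion is a package choice — only total event-level dispersion
(SD ≈ 24 ms) is observable in published tables — and no fidelity claim
is attached to the split.

Beats are mean RR plus independent Gaussian perturbations with
σ = target RMSSD / √2 per minute, which makes the per-minute RMSSD
target exact in expectation (differences of two independent
N(0, σ²) draws have RMS σ√2) without modeling spectral HRV structure.
Events impose a resting plateau, a reactivity level shifted by the
structural ΔRMSSD (floored at 2 ms), a plateau until the event end,
and an exponential return (half-life 10 min) truncated by the drawn
recovery time; high-MET activity bouts impose the same structural
response (vmHRV drops during exertion), which is what the
device-detected event path later rediscovers. Recovery times are drawn
Poisson with log-mean linear in centered resting lnRMSSD and the
direction dummy; draws past 120 min are flagged, never resampled, so
analysis-side censoring semantics match the generator's.

Structural coefficients default to the magnitudes estimated in the
motivating cohort: reactivity β (intercept −7.06, resting −14.06
ms/ln-unit, MET −3.55 ms/MET, interaction −3.85), person intercept SD
6.07 ms, residual SD 12.16 ms; recovery log-rate coefficients
(intercept ln 8.72, resting ln 4.30, direction ln 0.88, interaction
ln 0.24). The MET terms act on MET centered at 1.7 (the typical event
MET level), so the coefficients are directly the estimands of the
fitted models, which center MET at the sample mean. The recovery
model's between-person SD defaults to 0.7 ln-minutes: the motivating
cohort's fitted value (variance 2.03) would push most simulated counts
past the 120-min truncation, which contradicts its own observed ~7%
censoring; 0.7 keeps the simulated censoring rate near that level.

Two simulation scales exist by design. Parameter-recovery and
type-I-error studies draw event-level tables directly from the
structural equations (60 persons × ~10 events, 50–200 replicates),
which keeps replicate studies tractable on one CPU; the full beat-level
path (RR synthesis → screening → segmentation → matching → models) is
exercised end-to-end at 8–12 persons. Passing tests therefore
establish internal consistency — the pipeline recovers what the
generator planted, the arithmetic matches independent oracles — not
fidelity to real physiology: the generator has no circadian or
respiratory structure, no LF/HF spectral content, diary noise is
Gaussian, and missingness is random blocks rather than
movement-artifact bursts.

## Numerical and degenerate-input conventions

- All timestamps are floored to the 60-s grid; minute windows are
  half-open [start, start+5) in code, written as inclusive minute
  lists above.
- Determinism: one integer seed drives every draw; identical
  configuration and seed give byte-identical datasets, tables, and run
  manifests (content-hashed in the manifest).
- Empty or degenerate configurations (zero days, empty waking window,
  rates outside [0,1]) raise configuration errors; an empty analysis
  table after listwise deletion is an explicit error rather than an
  empty fit.
- The acceptance script scales its replicate counts (40 fits per
  model, 100 null replicates) to run in a few minutes on one CPU; the
  test suite uses 80/50/200 replicates for the corresponding checks.

## Known limitations

- Inference for the linear mixed model uses Wald z tests; with few
  persons these are mildly anticonservative.
- The recovery model treats censored recoveries by exclusion, not with
  a survival likelihood — matching the analysis it implements, not
  best practice for censored counts.
- Breathing pace is intentionally absent as a covariate (it is not
  measurable reliably enough in this design), and nicotine is coded
  but excluded from default formulas (too rare to estimate stably);
  both can be re-enabled through the model-term configuration.
- The diary-to-marker matcher is greedy chronological one-to-one; a
  global assignment could differ on adversarial fixtures.
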