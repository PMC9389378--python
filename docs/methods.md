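# Methods

This note documents the model implemented in `hfsim`: its structure,
assumptions, parameter defaults, numerical choices, and the limits of what
its synthetic inputs can show.

## Model structure

`hfsim` is a continuous-time, patient-level discrete event simulation with a
lifetime horizon (no administrative censoring). Three arms are simulated for
every patient with common random numbers: usual care (UC), home
telemonitoring (HTM), and telemonitoring plus a diagnostic alarm algorithm
(HTM_DA).

Per patient and arm the engine maintains three candidate events:

1. **Death** `T_D`, drawn once at baseline by inverse-CDF sampling from the
   death model (base case Weibull, shape 1.2, scale 4.0 years).
2. **Next hospitalization** `T_H`, drawn from the hospitalization model
   (base case log-normal, μ = −1.3, σ = 0.9 on log-years) conditionally on
   survival past the current time, and redrawn after every admission or
   averted admission. It is deliberately *not* redrawn after outpatient
   visits, which are pure cost/monitoring events.
3. **Next outpatient visit**, deterministic at the arm's fixed interval
   (2.81 months UC, 1.69 months HTM-based); only mean intervals are
   available, so no stochastic gap is modeled.

The earliest candidate is processed (tie-break order: death,
hospitalization, visit). A realized admission draws in-hospital death from a
logistic model (covariates: age, sex, myocardial infarction, chronic atrial
fibrillation, diabetes, COPD, number of *previous* hospitalizations —
evaluated with the count before the current admission). In-hospital death
terminates the trajectory even if `T_D` lies further out; this
double-counting of mortality is inherent to combining an all-cause
time-to-death equation with a per-admission mortality model and is accepted
as conservative. A trajectory always ends in exactly one death event; a
guard aborts after 10⁶ events.

Treatment effects are proportional hazards, `S_arm(t) = S_0(t)^HR`, applied
numerically on the hazard for all six supported families (exponential,
Weibull, log-normal, log-logistic, Gompertz, generalized gamma) — including
the AFT-form families where this is a convention rather than the natural
parameter effect. Negative-shape Gompertz is rejected because its defective
survival mass is incompatible with a lifetime horizon. Default hazard
ratios for HTM-based arms: 0.70 (death), 0.92 (hospitalization); covariate
log-hazard-ratios default to empty (arm effect only).

### Diagnostic algorithm

The alarm is a binary daily test with sensitivity `se` and false-positive
rate `fpr`. An imminent admission is averted with probability
`se × p_avoidable` (defaults 0.52 and 0.50, so 0.26 overall). An averted
admission is charged one alarm-management contact (€18.38) and has no other
consequence; whether a true-positive alarm should carry further contact
costs is unspecified upstream, and one fee is the assumption here. False
alarms accrue as the deterministic expectation `fpr × days` over each
inter-event gap — matching the worked expectation of 3 alarms for
`fpr = 0.03` over 100 days — and are charged at the gap midpoint
(configurable via the event payload convention; a stochastic alarm count
would add noise without changing means).

### Common random numbers

Each patient owns four random substreams (death, hospitalization sequence,
alarm interception, in-hospital death), seeded by
`(seed, patient_index, purpose)` and recreated identically per arm. The
in-hospital-death uniform is consumed even for averted admissions so the
streams stay aligned across arms. Consequences, verified by tests:

- a null algorithm (`se = 0, fpr = 0`) reproduces the HTM trajectory
  event-for-event;
- realized + averted admissions under HTM_DA equal realized admissions
  under HTM per patient, *exactly when in-hospital mortality is disabled* —
  with mortality on, an averted admission can extend life and the identity
  becomes an inequality (HTM_DA ≥ HTM in admission opportunities);
- averted-admission counts are monotone in sensitivity.

## Synthetic population

The generator draws the five continuous covariates from truncated normals
(defaults: EF ∈ [5, 60] %, age ∈ [18, 100] y, SBP ∈ [60, 220] mmHg,
BMI ∈ [12, 60] kg/m², creatinine ∈ [30, 500] µmol/L), NYHA class from the
four-category multinomial (18.5 / 43.4 / 31.0 / 7.1 %), and the nine binary
characteristics independently at their configured prevalences. Because
clipping a normal shifts its mean (for creatinine by ≈ +2.7 µmol/L under the
default bounds), the truncated-normal *location* is re-solved so the
distribution's mean equals the configured mean exactly.

Only marginal moments are published, so covariates are independent by
default; a Gaussian-copula hook accepts a rank-correlation matrix for the
continuous block. NYHA is not derived from other covariates. Baseline
working status is drawn as `P(working) = NYHA-specific share × age-sex labor
participation` and is frozen thereafter (no long-term productivity losses).
Subgroup pairs split at age 65 and EF 25 with boundary patients in the upper
group, keeping each pair an exhaustive partition; with the NYHA classes and
nine binary pairs this yields the 26 named subgroups.

What the generator does *not* emulate: covariate correlation (by default),
covariate evolution over time (other than the admission count), and any
joint distribution features of the real trial population. Passing tests
demonstrate internal consistency of the simulator and fidelity to the
configured marginals — not predictive validity for real patients.

## Costs and discounting

Unit costs are the 2020 Dutch figures (outpatient visit €44.50 UC / €43.30
HTM; other care contacts €188.38 / €623.61 per year; hospitalization
€4,404.46; device €1,257.75/yr; alarm management €18.38; drugs €286.44/yr;
travel €3.75 / €4.68; informal care €2,098.28/yr). Costs discount at 4%/yr
and effects at 1.5%/yr (differential discounting per the Dutch guideline;
the orientation is configurable). Discounting uses the annual-compounding
factor `(1+r)^(−t)` in continuous time; yearly flows integrate to the closed
form `c[(1+r)^(−t0) − (1+r)^(−t1)]/ln(1+r)`.

Productivity losses use the friction-cost method: one friction month of
age-sex-specific wages per admission of a working patient, zero from age 65.
Future unrelated medical costs accrue from an age-sex table as the patient
ages through bands. The wage, participation and unrelated-cost tables are
illustrative values of realistic Dutch magnitude (their sources are not
published at usable granularity); all are configurable. The healthcare
perspective drops travel, informal care, productivity, and unrelated costs.
Informal care uses a single population-average yearly amount (no significant
NYHA differences were reported upstream).

## Utilities and QALYs

Baseline utility is NYHA-specific (0.87976 / 0.71178 / 0.61405 / 0.49228).
Each of the first three realized hospitalizations applies a *permanent*
multiplicative step-down of 0.82 (reading "decrease in utility" as a state
change, analogous to a NYHA step; a transient-decrement mode is available as
a scenario flag). Utility is capped from above by the Ara–Brazier
general-population curve `0.9508566 + 0.0212126·male − 0.0002587·age −
0.0000332·age²` (published general-population coefficients, shipped as the
default because the source's exact equation is in an unavailable
supplement), clamped to [0, 1]; the cap also supplies the aging decrement.

Discounted QALYs integrate the utility path piecewise-analytically: between
hospitalizations utility is `min(constant, quadratic-in-age)`; segments are
split at the real roots of the quadratic against the constant and the [0, 1]
clamps, and each branch integrates against `e^(−ln(1+r)·t)` in closed form
(polynomial × exponential antiderivatives). Tests verify agreement with
adaptive quadrature to 10⁻⁶.

## Cost-effectiveness, uncertainty, and value of information

Incremental analysis sorts arms by QALYs (ties by lower cost), removes
strictly dominated arms, then iteratively flags extended dominance until
frontier ICERs are non-decreasing. Report rounding: costs to whole euros,
QALYs to 2 decimals, ICERs to whole €/QALY; internal math is full precision.
The willingness-to-pay threshold comes from the proportional shortfall
`(q_remaining − q_disease)/q_remaining` via right-closed Dutch bands
0.10–0.40 → €20,000, 0.41–0.70 → €50,000, 0.71–1.00 → €80,000 (the band
table itself is configurable; below the lowest band the lookup returns a
"no reimbursement-relevant burden" marker).

The probabilistic sensitivity analysis is a double loop (reference sizes:
inner 100 patients resampled with replacement, outer 500 parameter draws;
tests and examples use smaller sizes chosen so the default suite runs in
well under a minute of PSA time). Normal parameters draw directly
(probability-like ones truncated to their valid range); gamma and beta
parameters are moment-matched from (mean, SE); survival-model coefficients
are excluded from the PSA and covered by scenario switches instead.
Acceptability curves split exact NMB ties equally so probabilities sum to
one. EVPI per patient is `mean_i max_a NMB − max_a mean_i NMB`; the
population EVPI multiplies by the discounted eligible population
(53,140 … 61,019 over five years at 4%, first cohort one year out,
≈ 253,116 — within rounding of the published 253,118).

One-way sensitivity analysis runs each bounded parameter at its 95% CI
bounds with common random numbers (pure-cost parameters provably leave
QALYs untouched) and sorts by ICER range. The ROC sweep re-runs the model
at each (fpr, sensitivity) operating point with the same seed and reports
the ICER-minimizing point; monotone-violating ROC input is rejected rather
than silently sorted. Subgroups filter a 10,000-patient generated pool and
resample 1,000 patients per run (the base-case run size).

## Illustrative coefficients and known limitations

The fitted time-to-event and in-hospital-mortality equations of the
originating trial model are not published. The shipped defaults are
**illustrative**: Weibull(1.2, 4.0) death, log-normal(−1.3, 0.9)
hospitalization, logistic intercept −4.8 with small positive comorbidity
coefficients, calibrated only so the usual-care arm shows a realistic
severe-heart-failure profile (≈ 2.4 undiscounted life years, ≈ 1.7
admissions/year, ≈ 40 % of deaths in hospital). Absolute euro/QALY outputs
of the default configuration therefore characterize the model mechanics,
not the trial; analyses that depend on these coefficients (base-case ICERs,
CEAC probabilities, EVPI magnitudes) should be interpreted accordingly, and
users with access to fitted equations can supply them through the
configuration.

Other limitations: no adherence, nurse-workflow or alarm-triage modeling;
no NYHA transitions (utility class fixed at baseline); no drug-level cost
optimization; deterministic visit schedule; independence of baseline
covariates by default.
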