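# hfsim

Patient-level discrete event simulation (DES) and full cost-effectiveness
analysis of **home telemonitoring (HTM)** for chronic heart failure, with and
without a **diagnostic alarm algorithm (DA)**, versus usual care (UC), from a
Dutch societal perspective.

The package is written for health economists and methodologists who want a
transparent, testable implementation of this class of model: a
continuous-time microsimulation of outpatient visits, hospitalizations and
death per patient, full cost and QALY accounting, incremental
cost-effectiveness with extended dominance, probabilistic and deterministic
sensitivity analysis, value-of-information analysis, an ROC operating-point
sweep for the alarm algorithm, and a 26-subgroup analysis — all driven by a
synthetic cohort generator that emulates the published baseline table of a
severe heart-failure trial population.

## The model

Each simulated patient carries baseline covariates (age, sex, ejection
fraction, NYHA class, comorbidities, …) drawn from configured marginal
moments. Under each arm the engine processes, in chronological order:

- **Death** at time `T_D` from a parametric survival model (base case:
  Weibull), drawn once at baseline;
- **Hospitalizations** at times drawn from a second parametric model (base
  case: log-normal), redrawn conditionally on survival past the current time
  after every admission or averted admission.  Each realized admission
  triggers a Bernoulli in-hospital-death draw from a logistic model in the
  patient's covariates and prior admission count;
- **Outpatient visits** at a fixed arm-specific interval (UC 2.81 months;
  HTM-based arms 1.69 months).

Treatment effects are proportional hazards, `S_arm(t) = S_0(t)^HR`. The
alarm algorithm is a binary test with sensitivity `se` and daily
false-positive rate `fpr`: an imminent admission is averted with probability
`se × p_avoidable` (base case `0.52 × 0.50 = 0.26`), and false alarms accrue
as the deterministic expectation `fpr × gap-days` (e.g. `0.03 × 100 = 3`),
each costed at the alarm-management fee.

Costs (2020 €, societal perspective: care, device, drugs, travel, informal
care, friction-cost productivity losses, future unrelated medical costs) are
discounted at 4%/yr; health effects at 1.5%/yr. Utility is NYHA-specific,
stepped down by a factor 0.82 at each of the first three hospitalizations,
and capped by an age–sex general-population utility curve. Cost-effectiveness
uses ICER = Δcost/ΔQALY with extended dominance on the efficient frontier,
and the Dutch proportional-shortfall threshold bands
(€20,000/€50,000/€80,000 per QALY).

The shipped event-time and logistic coefficients are **illustrative, not
fitted** — the originating trial equations are unpublished — and are
calibrated only to give realistic magnitudes (usual-care life expectancy
≈ 2.4 undiscounted years, ≈ 1.7 admissions/year). See `docs/methods.md`.

## Worked example

```python
import hfsim

config = hfsim.default_config()
cohort = hfsim.generate_population(config.population, 1_000, seed=2026,
                                   productivity=config.productivity)
out = hfsim.simulate_cohort(cohort, config, seed=1)
table = hfsim.incremental_analysis(list(out.per_arm.values()))
```

With the default configuration this prints (see `examples/base_case.py`):

```
arm       cost (EUR)     LY   QALY  visits/y  hosp/y averted/y
UC             40182   2.38   1.11      4.07    1.69      0.00
HTM            52212   3.04   1.39      6.94    1.39      0.00
HTM_DA         53494   3.45   1.63      6.96    0.97      0.35

dominance: {'UC': 'efficient', 'HTM': 'extendedly_dominated', 'HTM_DA': 'efficient'}
HTM_DA vs UC: +EUR 13311, +0.52 QALY -> ICER EUR 25759/QALY
proportional shortfall under usual care: 92.2% -> threshold EUR 80000/QALY
```

Read: telemonitoring alone is *extendedly dominated* (a mix of usual care
and the algorithm arm beats it), and the algorithm arm buys one QALY for
about €26k — well below the €80,000 willingness-to-pay implied by the 92%
proportional shortfall of this population. The `examples/` directory holds
one short script per capability: cohort generation, the base case, the
tornado/PSA/EVPI pipeline, the ROC sweep, and subgroups/scenarios.

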