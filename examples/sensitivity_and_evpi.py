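"""Deterministic and probabilistic sensitivity analysis plus value of information.

Runs a one-way (tornado) analysis over the parameter bounds, a small
double-loop probabilistic sensitivity analysis (inner patient resample,
outer parameter draw), acceptability curves, and the per-patient and
population expected value of perfect information.  Sizes are kept small so
the script finishes in well under a minute; scale ``PSAConfig`` up (inner
100 / outer 500) for production-quality curves.
"""

import hfsim
from hfsim.uncertainty import EVPIConfig, PSAConfig

config = hfsim.default_config()
cohort = hfsim.generate_population(
    config.population, 200, seed=3, productivity=config.productivity
)
dists = hfsim.default_distributions()

tornado = hfsim.run_dsa(config, cohort[:60], dists, seed=4)
print("tornado (top 5 by ICER range, EUR/QALY):")
for _, row in tornado.head(5).iterrows():
    print(f"  {row['parameter']:38s} {row['icer_low']:8.0f} .. {row['icer_high']:8.0f}")

psa = hfsim.run_psa(PSAConfig(inner_n_patients=50, outer_iterations=60, seed=5), dists, config, cohort)
curves = hfsim.ceac(psa, [0, 20_000, 50_000, 80_000, 120_000])
print("\nacceptability (P most cost-effective):")
print(curves.pivot(index="lambda", columns="arm", values="probability").round(2))

lam = 80_000.0
evpi_pp = hfsim.evpi_per_patient(psa, lam)
pop = hfsim.discounted_population(EVPIConfig())
print(f"\nEVPI per patient at EUR {lam:.0f}/QALY: EUR {evpi_pp:.0f}")
print(f"discounted eligible population over 5 years: {pop:,d}")
print(f"population EVPI: EUR {hfsim.population_evpi(evpi_pp, pop):,.0f}")
print("\nThe population EVPI is the ceiling on what further research into these"
      "\nparameters could be worth for the projected eligible patients.")
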