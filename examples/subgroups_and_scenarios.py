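"""Subgroup analysis over the 26 named patient subgroups and structural scenarios.

Each subgroup is a filter on the generated pool (age and ejection-fraction
splits, NYHA classes, each binary characteristic present/absent); the
scenario runs vary structural assumptions (perspective, cost bounds,
outpatient intervals, event-time family).  All runs share the base-case
seed, so differences are attributable to the varied inputs.
"""

import hfsim

config = hfsim.default_config()

subgroups = hfsim.run_subgroups(config, seed=8, n_pool=4_000, n_run=300)
print(f"{'subgroup':28s} {'ICER vs UC':>11s} {'vs base %':>9s}")
for r in subgroups:
    if not r.per_arm:
        print(f"{r.scenario:28s} {'-':>11s} {r.note}")
        continue
    pct = f"{r.pct_change_vs_base:+.1f}" if r.pct_change_vs_base is not None else "-"
    print(f"{r.scenario:28s} {r.icer_vs_uc:11.0f} {pct:>9s}")

cohort = hfsim.generate_population(
    config.population, 300, seed=9, productivity=config.productivity
)
scenarios = hfsim.run_scenarios(hfsim.builtin_scenarios(config), config, cohort, seed=10)
print(f"\n{'scenario':32s} {'ICER vs UC':>11s} {'vs base %':>9s}")
for r in scenarios:
    pct = f"{r.pct_change_vs_base:+.1f}" if r.pct_change_vs_base is not None else "-"
    print(f"{r.scenario:32s} {r.icer_vs_uc:11.0f} {pct:>9s}")

print("\nPositive percentages mean the subgroup/scenario is less cost-effective"
      "\nthan the base case for the algorithm arm versus usual care.")
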