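"""Compare the four intervention scenarios under both condition sets.

Each scenario is simulated against business as usual; reductions are percent
of the baseline cumulative 2021-2030 counts (positive = fewer harms) and
percentage points of 2030 high-distress prevalence.
"""

from mhsd import (
    CovidConditions,
    ModelParameters,
    apply_scenario,
    builtin_scenarios,
    compare,
    outcome_summary,
    run,
)

params = ModelParameters()
specs = builtin_scenarios()

for label, conditions in (("pre-pandemic", CovidConditions.pre()),
                          ("post-pandemic", CovidConditions.post())):
    summaries = {
        name: outcome_summary(run(apply_scenario(params, spec, conditions)))
        for name, spec in specs.items()
    }
    base = summaries["business_as_usual"]
    print(f"\n=== {label} (baseline: {base.self_harm_hospitalizations:.0f} self-harm, "
          f"{base.suicide_deaths:.0f} suicides, {base.ed_presentations:.0f} ED) ===")
    print(f"{'scenario':28s} {'self-harm':>9s} {'suicide':>8s} {'ED':>7s} {'prev pp':>8s}")
    for name in ("capacity_growth_20", "standard_telehealth",
                 "tech_enabled_coordination"):
        c = compare(base, summaries[name])
        print(f"{name:28s} {c.pct_reduction_self_harm:8.2f}% "
              f"{c.pct_reduction_suicide:7.2f}% {c.pct_reduction_ed:6.2f}% "
              f"{c.pp_reduction_prevalence:8.2f}")

print("\nTechnology-enabled care coordination dominates because it acts on")
print("recovery, referral and disengagement simultaneously; growing existing")
print("capacity only relaxes the binding service constraints at the margin.")
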