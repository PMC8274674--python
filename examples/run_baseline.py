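"""Simulate the business-as-usual baseline and read the decade forecast.

Runs the calibrated regional model from 2011 to 2030 at the 1/16-week
reporting step and prints the cumulative 2021-2030 outcome counters and the
high-distress prevalence endpoints.  These are the quantities every scenario
is compared against.
"""

from mhsd import ModelParameters, outcome_summary, run

params = ModelParameters()
trajectory = run(params)
s = outcome_summary(trajectory)

print("Business as usual, pre-pandemic conditions, 2021-2030:")
print(f"  self-harm hospitalizations : {s.self_harm_hospitalizations:8.0f}")
print(f"  suicide deaths             : {s.suicide_deaths:8.0f}")
print(f"  mental-health ED visits    : {s.ed_presentations:8.0f}")
print(f"  high-distress prevalence   : {s.prevalence_start_pct:.2f}% (2021)"
      f" -> {s.prevalence_end_pct:.2f}% (2030)")
print()
print("Counts are cumulative person-events over the nine reporting years;")
print("prevalence is the share of adults with K10 scores of 22-50.")
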