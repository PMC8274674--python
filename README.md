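# mhsd — regional mental-health system dynamics

`mhsd` is a capacity-constrained stock-and-flow simulator of a regional
mental-health system, built for health-planning analysts who want to compare
service-level intervention strategies on population outcomes: suicide
attempts (proxied by self-harm hospitalizations), suicide deaths,
mental-health emergency-department (ED) presentations, and the prevalence of
high psychological distress.

The model represents a coastal Australian catchment of ~502,000 people and
five interacting sectors:

* **population** — four age groups (0–14, 15–24, 25–64, 65+) with births, net
  migration, mortality and aging;
* **psychological distress** — adults partitioned by Kessler-10 band: low
  (K10 10–15), moderate (16–21), high/very high (22–50), with first-order
  onset, escalation and remission transitions;
* **social determinants** — unemployment, homelessness, substance misuse,
  domestic violence, early-life adversity and a sense-of-community index,
  combined into a multiplicative pressure on distress onset, suicide attempts
  and service disengagement;
* **service system** — GP, psychiatrist/allied, community mental health,
  online, ED, inpatient and outpatient channels, each with weekly capacity,
  waiting lists, disengagement and a per-service recovery probability;
  capacities of the first three grow by fixed yearly increments;
* **suicidal behaviour** — attempts arise (mostly) from the high-distress
  band; a hospitalized fraction becomes self-harm hospitalizations, a
  case-fatality fraction becomes deaths.

## Model core

Stocks evolve by explicit Euler at Δt = 1/16 week (0.4375 days), the
step at which all outputs are reported:

```
x(t+Δt) = x(t) + Δt · (Σ inflows − Σ outflows)
```

with outflows rationed proportionally so no stock goes negative.  Service
channels are queues under a hard capacity cap,
`served = min(demand + waiting/τ, capacity)`, and each delivered service
moves its recipient one distress band down with probability `p_rec`.
Social-determinant pressure is a power product,
`Π_d (level_d / ref_d)^{w_d} · (ref_soc / soc)^{w_soc}`, equal to 1 at
baseline.  An intervention covering a fraction `u(t)` of services with
per-service multiplier `m` acts through the blend `1 + u(t)·(m − 1)`.

Four built-in scenarios start in 2021: business as usual; a 20% faster
service-capacity growth rate; standard telehealth; and technology-enabled
care coordination (multiplicative effects on recovery 1.177, specialist
referral 1.266 for high-distress GP consultations, disengagement 0.520,
substance-use relapse 0.869, and 1.10 on several supporting pathways, at
70% maximum uptake).  Each can be run under pre- or post-pandemic
socioeconomic conditions (unemployment shock ×15 decaying at 0.05/week,
youth job-loss ratio 5, sense-of-community index 9.61 → 8.24 for two years).

## Worked example

```python
from mhsd import ModelParameters, outcome_summary, run

summary = outcome_summary(run(ModelParameters()))
print(summary.self_harm_hospitalizations)  # 12275.3
print(summary.suicide_deaths)              # 953.1
print(summary.ed_presentations)            # 81263.1
print(summary.prevalence_start_pct)        # 17.60
print(summary.prevalence_end_pct)          # 15.60
```

Under business as usual the calibrated model forecasts ≈12,275 self-harm
hospitalizations, ≈953 suicide deaths and ≈81,263 mental-health ED
presentations cumulatively over 2021–2030, with high-distress prevalence
declining from 17.60% of adults in 2021 to 15.60% in 2030 as service
capacity outgrows demand.  `examples/compare_scenarios.py` then prints the
scenario table — e.g. technology-enabled care coordination reduces the
decade's self-harm hospitalizations by 8.6% (2.4 percentage points of 2030
prevalence), versus 2.0% for standard telehealth and 1.1% for 20% faster
capacity growth, an ordering that survives post-pandemic conditions.

The other scripts in `examples/` demonstrate uptake sweeps, Latin-hypercube
uncertainty intervals, calibration and the synthetic-data generator.  A thin
CLI mirrors them: `mhsd run|calibrate|sensitivity|sweep-uptake|report|make-synthetic`.

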