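# Methods

## Model and assumptions

`mhsd` implements a deterministic continuous-time stock-and-flow (system
dynamics) model of a regional mental-health system, integrated by explicit
Euler at a fixed step of 1/16 week.  Time is measured in weeks with a model
year of exactly 52 weeks, so calendar decimal years map linearly onto step
counts (832 steps/year) and the 2011–2030 horizon is 15,808 steps.  People
are continuous quantities; counts are rounded only at reporting.

The five sectors and their couplings:

* **Population.**  Age-group stocks 0–14, 15–24, 25–64, 65+ with constant
  births and net migration (persons/week), per-group mortality
  (fraction/week), and aging chains at 1/(band width) per week.  The initial
  total is 502,524 with shares 17/11/50/22%.  Adults (15+) carry distress;
  the 0–14 group feeds the adult bands through aging.
* **Psychological distress.**  Adults in three Kessler-10 bands.  Onset
  (low→moderate) and escalation (moderate→high) are first-order per-capita
  rates scaled by determinant pressure; spontaneous remission moves people
  down.  Demographic flows into and out of the bands mirror the population
  sector's adult flows exactly (entrant distress split fixed; mortality
  proportional to band shares), so band totals equal the adult population to
  floating-point precision at every step — the conservation invariant the
  test suite checks at 1e-6.
* **Social determinants.**  Unemployment, homelessness and active substance
  misuse are stocks with constant inflows and first-order outflows; domestic
  violence and early-life adversity are static indices; sense of community
  is a time-profiled index.  Reference levels are the deterministic baseline
  equilibria (e.g. unemployment ref = job-loss inflow / employment-initiation
  rate), which makes every pressure multiplier exactly 1 on the undisturbed
  baseline.  Pressure is a Cobb–Douglas power product with separate weight
  sets for distress onset, suicide attempts and service disengagement —
  the pathway structure behind these couplings is only qualitatively known,
  so the weights are explicit, bounded parameters rather than claims.
* **Service system.**  Seven channels.  GP is the first contact: demand is
  per-capita help-seeking from the moderate and high bands.  Each
  capacitated channel (GP, psychiatrist+allied, community mental health)
  has a waiting list drained first (`served = min(demand + waiting/τ,
  capacity)`, τ = 1 week), with queue disengagement at a pressure-scaled
  weekly rate.  Referrals out of served GP consultations route high-band
  patients to specialist care and community services and moderate-band
  patients to online services.  ED demand is generated by the suicidality
  sector; a fraction of served ED presentations becomes psychiatric
  inpatient admissions with outpatient follow-up.  Every delivered service
  moves its recipient one band down with a per-channel recovery
  probability.  GP and specialist capacities grow linearly (125.85 and
  216.31 services/week added per year; community growth is 0 at baseline) —
  these yearly increments are the capacity-scenario levers, applied from the
  intervention start year.
* **Suicidal behaviour.**  Attempts/week = pressure × (3.37e-4·High +
  1.55e-5·Moderate).  Self-harm hospitalizations = hospitalized fraction
  (default 1, the attempt proxy) × attempts; deaths = case fatality
  (0.0776) × attempts; MH-related ED presentations = one crisis presentation
  per attempt + 2.00e-3/week per high-distress person.  The ED *outcome*
  counter is deliberately kept independent of the ED *service channel*
  bookkeeping so treatment-pathway changes cannot silently alter the
  reported burden definition.

### Why the baseline declines

GP and community capacities are binding (queues persist) through the whole
horizon while capacity grows linearly, so service recoveries per adult rise
steadily; that is the mechanism behind the forecast decline of high-distress
prevalence from 17.60% (2021) to 15.60% (2030).  It is also what gives the
capacity-growth scenario a strictly positive effect and what lets recovery-
and referral-multiplier interventions dominate it.

## Scenarios and pandemic conditions

Interventions begin in 2021 with a one-year linear uptake ramp (the ramp
length is not specified by the published scenario tables; one year is this
package's default and is configurable).  A multiplier `m` on a covered
service blends with uncovered care as `1 + u(t)·(m − 1)` — the population-mix
average of covered and uncovered services, the minimal interpretation of a
"maximum rate per service".  The specialist-referral multiplier applies only
to high/very-high-distress GP consultations; moderate-band referrals are
untouched.  The standard-telehealth scenario keeps its published non-unit
recovery/disengagement/relapse/capacity values but uses a referral
multiplier of 1.00: remote delivery of existing care models changes neither
referral behaviour nor providers, and the tabulated 10.00 is treated as a
transcription outlier (it remains reachable by constructing a
`ScenarioSpec` explicitly).

Post-pandemic conditions install three shocks at 2020.25: the unemployment
inflow is multiplied by 15 with the excess decaying exponentially at
0.05/week; the youth share of job losses is additionally scaled by a ratio
of 5 decaying at the same rate; and the sense-of-community index ramps from
9.61 to 8.24 over one year, holds for two years of social disconnection,
then ramps back over one year.  Pre-pandemic conditions install nothing and
are bit-identical to an unshocked run (a tested invariant).

## Integration scheme

The default integrator is explicit Euler with proportional outflow
rationing, matching common system-dynamics practice.  A fixed-step classical
RK4 scheme is available as a config option: first-order Euler's analytic
error on a 0.1/week decay over 52 weeks at the 1/16-week step is
k²·T·Δt/2 ≈ 1.6%, so analyses that need better than ~1% pointwise accuracy
at this step should select RK4 (error ~1e-10 on the same problem).  All
cumulative counters change by well under 1% when the Euler step is halved,
which bounds the discretization error of every reported count.

## Calibration

Free parameters (default set of ten: the two onset rates, two help-seeking
rates, attempt rate, case fatality, ED rate, crisis share and the two
initial distress-split fractions) are fitted by minimizing a weighted sum of
squared relative errors against (a) five decade-forecast anchors —
cumulative 2021–2030 self-harm hospitalizations, suicide deaths, ED
presentations, and 2021/2030 high-distress prevalence — and (b) a
2011–2017 yearly historic series.  The optimizer is multi-start bounded
Nelder-Mead (up to 10 Latin-hypercube starts, 250 evaluations each); start 0
is the incoming parameter set, and the multi-start loop ends early once all
scalar anchors are inside their 1% tolerances.  Historic points carry low
weight (0.005 vs 1.0) and a 5% tolerance because the packaged series is
synthetic and Poisson-noisy; the convergence flag reports *all* targets, so
a fit can satisfy every anchor and still report `converged=False` when the
noise floor of the historic series exceeds 5%.  The packaged defaults are
the product of this calibration, so refitting from scratch reproduces the
anchors to well within 1% in a few hundred model evaluations (~1 minute).

Objective terms use relative errors, making the fit invariant to each
target's units; a zero-valued target falls back to absolute error.

## Sensitivity analysis

Uncertainty in the direct intervention-effect multipliers is propagated by
Latin-hypercube sampling (scipy's implementation): 100 draws by default from
independent uniforms spanning ±20% of each nominal multiplier, exactly one
draw per equal-probability stratum.  Multipliers below 1 (reductions) are
perturbed by ±20% of their own value and remain positive.  Each draw reruns
the scenario against the fixed business-as-usual baseline (which does not
depend on the sampled multipliers and is computed once); every comparison
metric is summarized by its 2.5th and 97.5th empirical percentiles
(numpy's default linear/type-7 quantiles).  The bands are parameter-
uncertainty intervals, not confidence intervals, and may span zero for weak
scenarios.  Which multipliers were perturbed in the original analysis is
ambiguous; the default design covers all nine direct effects.

## Synthetic data

Real regional registries are not public, so the generator emulates their
statistical shape: linear yearly trends 2011–2017 with Poisson noise for
counts and Gaussian noise (σ = 0.02) on the logit of prevalence.  Default
trend levels are the calibrated model's own baseline output for those years
(≈1,500 self-harm hospitalizations, ≈117 suicide deaths, ≈10,000 ED
presentations, ≈1,200 psychiatric admissions per year, prevalence ≈21→18%),
so the joint anchor-plus-historic objective is internally consistent.  The
generator reproduces trend means and Poisson mean-variance scaling (tested
over 1,000 regenerations) and is bit-deterministic per seed.  What it does
not emulate: seasonality, reporting artefacts, registry revisions, and
cross-indicator correlation — so passing calibration tests demonstrates the
machinery works on data of this shape, not that the model is validated
against the region's real series.

## Numerical choices and degenerate inputs

* Outflow rationing scales all outflows of a nearly-empty stock by a common
  factor within the step; recorded stocks are therefore never negative for
  any in-bounds parameter draw (property-tested).
* Auxiliary expressions guard divisions (`max(x, ε)`) and determinant levels
  (`max(stock, 1)`), so empty determinant stocks degrade gracefully instead
  of raising.
* Non-finite flow evaluations abort the run naming the flow and time.
* Waiting lists are shadow queues: queued people remain in their distress
  band, so queue bookkeeping cannot violate people conservation.
* Suicide deaths are debited from both the high-distress band and the 25–64
  population stock with the same expression, preserving the band/population
  identity exactly.
* Parameter recovery tests run the full calibration machinery on a coarser
  step (1/4 week) — the package's standard reduced configuration for
  self-consistency problems, where discretization bias cancels because the
  targets are generated and refit under the same configuration.

## Known limitations

* Functional forms (first-order transitions, Cobb–Douglas pressure, linear
  uptake blending) are the simplest structures consistent with the published
  qualitative couplings; the original regional model's full equation set is
  not public, so quantitative scenario effects here agree with the published
  ones in ordering and rough magnitude, not digit-for-digit.
* The prevalence denominator is the modelled adult (15+) population, since
  K10 is an adult instrument; child and adolescent distress is out of scope.
* One homogeneous region: no spatial structure, no individual heterogeneity
  (an agent-based representation would be the natural extension for
  uptake-heterogeneity questions).
* The ED-as-service and ED-as-outcome constructs are deliberately separate;
  if the original model unified them, absolute ED counts are not comparable
  construct-for-construct.
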