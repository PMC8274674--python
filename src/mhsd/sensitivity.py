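"""Latin-hypercube sensitivity analysis over intervention-effect parameters.

Parameter uncertainty in the direct intervention effects is propagated by
drawing stratified samples from independent uniform distributions spanning
a ±`half_width` band around each nominal multiplier, re-running the scenario
against the (fixed) business-as-usual baseline for each draw, and summarising
every comparison metric by its 2.5th and 97.5th empirical percentiles.  The
resulting band is a parameter-uncertainty interval, *not* a confidence
interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .engine import IntegrationConfig
from .model import outcome_summary, run
from .params import ModelParameters
from .scenarios import CovidConditions, ScenarioSpec, apply_scenario, compare

__all__ = ["LHSDesign", "IntervalEstimate", "lhs_sample", "run_sensitivity",
           "SAMPLEABLE_EFFECTS"]

# the direct intervention-effect multipliers eligible for perturbation
SAMPLEABLE_EFFECTS = (
    "m_rec", "m_ref", "m_dis", "m_aod", "m_rel", "m_emp", "m_home", "m_cap", "m_onl",
)


@dataclass(frozen=True)
class LHSDesign:
    """A Latin-hypercube design over named positive nominal values.

    Each parameter's ``n_samples`` draws occupy distinct equal-probability
    strata of ``Uniform(nominal·(1−h), nominal·(1+h))`` with exactly one
    draw per stratum; strata permutations are independent across parameters.
    """

    nominals: dict[str, float]
    n_samples: int = 100
    half_width: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if not 0.0 <= self.half_width < 1.0:
            raise ValueError("half_width must lie in [0, 1) to keep values positive")
        if any(v <= 0 for v in self.nominals.values()):
            raise ValueError("nominal values must be positive")


@dataclass(frozen=True)
class IntervalEstimate:
    """Central estimate with a 2.5-97.5 percentile parameter-uncertainty band."""

    central: float
    lower: float
    upper: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower percentile exceeds upper percentile")


def lhs_sample(design: LHSDesign) -> pd.DataFrame:
    """Draw the design: one row per sample, one column per parameter."""
    names = list(design.nominals)
    sampler = qmc.LatinHypercube(d=len(names), seed=design.seed)
    unit = sampler.random(design.n_samples)
    data = {}
    for j, name in enumerate(names):
        nom = design.nominals[name]
        data[name] = nom * (1.0 - design.half_width + 2.0 * design.half_width * unit[:, j])
    return pd.DataFrame(data)


def run_sensitivity(
    params: ModelParameters,
    scenario: ScenarioSpec,
    design: LHSDesign,
    covid: CovidConditions | None = None,
    config: IntegrationConfig | None = None,
    max_failure_fraction: float = 0.05,
) -> tuple[dict[str, IntervalEstimate], pd.DataFrame]:
    """Propagate multiplier uncertainty through scenario-vs-baseline runs.

    ``design`` must cover only the scenario's direct-effect multipliers
    (:data:`SAMPLEABLE_EFFECTS`).  Returns the per-metric interval estimates
    (central value from the nominal scenario) and the replicate-level tidy
    frame.  Failed replicates are excluded with a warning; more than
    ``max_failure_fraction`` failures aborts.
    """
    extra = set(design.nominals) - set(SAMPLEABLE_EFFECTS)
    if extra:
        raise ValueError(f"design covers non-effect parameters: {sorted(extra)}")
    for name, nominal in design.nominals.items():
        if getattr(scenario, name) != nominal:
            raise ValueError(f"design nominal for {name} differs from the scenario value")

    covid = covid or CovidConditions.pre()
    baseline = outcome_summary(
        run(apply_scenario(params, ScenarioSpec(name="business_as_usual",
                                                cap_gp_growth=params["cap_gp_growth"],
                                                cap_psy_growth=params["cap_psy_growth"],
                                                cap_cmhc_growth=params["cap_cmhc_growth"]),
                           covid), config)
    )
    central = compare(
        baseline, outcome_summary(run(apply_scenario(params, scenario, covid), config))
    ).as_dict()

    draws = lhs_sample(design)
    rows, failures = [], 0
    for i in range(len(draws)):
        spec_i = replace(scenario, **{k: float(draws.iloc[i][k]) for k in draws.columns})
        try:
            summary_i = outcome_summary(run(apply_scenario(params, spec_i, covid), config))
            rows.append({"replicate": i, **compare(baseline, summary_i).as_dict()})
        except (FloatingPointError, ValueError) as exc:
            failures += 1
            warnings.warn(f"replicate {i} failed and was excluded: {exc}")
    if failures > max_failure_fraction * len(draws):
        raise RuntimeError(f"{failures}/{len(draws)} sensitivity replicates failed")

    reps = pd.DataFrame(rows)
    intervals = {}
    for metric in central:
        values = reps[metric].to_numpy(dtype=float)
        lo, hi = np.percentile(values, [2.5, 97.5])  # linear (type-7) quantiles
        intervals[metric] = IntervalEstimate(
            central=float(central[metric]), lower=float(lo), upper=float(hi),
            n_replicates=len(reps),
        )
    return intervals, reps
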