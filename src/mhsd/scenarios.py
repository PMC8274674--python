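"""Intervention scenarios, uptake dynamics and pandemic condition sets.

Four scenarios are built in:

1. ``business_as_usual`` — no change; capacity keeps growing at current rates.
2. ``capacity_growth_20`` — yearly capacity growth of GP, psychiatrist/allied
   and community mental-health services increased by 20%.
3. ``standard_telehealth`` — existing care delivered remotely; modest effect
   multipliers, no change to referrals between services.
4. ``tech_enabled_coordination`` — technology-enabled care coordination:
   multidisciplinary team-based care supported by a shared digital platform,
   acting multiplicatively on recovery, referral, disengagement, relapse,
   employment/housing pathways and specialist capacity.

An intervention covers a fraction ``u(t)`` of services (the *maximum rate per
service*, ramping linearly from the start year); a multiplier ``m`` acting on
a covered service blends with the uncovered remainder as ``1 + u·(m − 1)``.

Pre- vs post-pandemic conditions follow the published comparison table:
post-pandemic runs apply a decaying unemployment shock, a youth job-loss
ratio, and a transient drop of the sense-of-community index from 9.61 to 8.24.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .engine import WEEKS_PER_YEAR
from .params import ModelParameters

__all__ = [
    "ScenarioSpec",
    "CovidConditions",
    "OutcomeComparison",
    "builtin_scenarios",
    "uptake",
    "effective_multiplier",
    "apply_scenario",
    "compare",
    "SCENARIO_NAMES",
]

SCENARIO_NAMES = (
    "business_as_usual",
    "capacity_growth_20",
    "standard_telehealth",
    "tech_enabled_coordination",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """One intervention scenario: effect multipliers plus capacity growth.

    ``u_max`` is the maximum fraction of services covered by the intervention;
    multipliers are per-covered-service effects (1.0 = no effect; values below
    1 are reductions, e.g. disengagement).  Capacity increments are in
    services/week added per year.
    """

    name: str
    u_max: float = 0.0
    m_rec: float = 1.0  # per-service recovery probability
    m_ref: float = 1.0  # GP referral to specialized care (high-distress only)
    m_dis: float = 1.0  # disengagement from services / waiting
    m_aod: float = 1.0  # referral to alcohol-and-other-drugs services
    m_rel: float = 1.0  # substance-use relapse
    m_emp: float = 1.0  # employment initiation
    m_home: float = 1.0  # exiting homelessness
    m_cap: float = 1.0  # specialized psychiatric service capacity
    m_onl: float = 1.0  # referral to online services (moderate distress)
    cap_gp_growth: float = 125.85
    cap_psy_growth: float = 216.31
    cap_cmhc_growth: float = 0.0
    start_year: float = 2021.0
    ramp_years: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.u_max <= 1.0:
            raise ValueError("u_max must lie in [0, 1]")
        for f in ("m_rec", "m_ref", "m_dis", "m_aod", "m_rel", "m_emp",
                  "m_home", "m_cap", "m_onl"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")

    @property
    def multipliers(self) -> dict[str, float]:
        return {
            f: getattr(self, f)
            for f in ("m_rec", "m_ref", "m_dis", "m_aod", "m_rel", "m_emp",
                      "m_home", "m_cap", "m_onl")
        }


@dataclass(frozen=True)
class CovidConditions:
    """Socioeconomic condition set (published pre/post pandemic comparison)."""

    youth_job_loss_rate_ratio: float = 1.0
    unemployment_shock_scale: float = 1.0
    unemployment_effect_decay_rate: float = 0.0  # per week
    sense_of_community_index: float = 9.61
    years_to_reach_index: float = 0.0
    duration_social_disconnection: float = 0.0  # years at the disturbed index
    shock_onset: float = 2020.25

    @classmethod
    def pre(cls) -> "CovidConditions":
        return cls()

    @classmethod
    def post(cls) -> "CovidConditions":
        return cls(
            youth_job_loss_rate_ratio=5.0,
            unemployment_shock_scale=15.0,
            unemployment_effect_decay_rate=0.05,
            sense_of_community_index=8.24,
            years_to_reach_index=1.0,
            duration_social_disconnection=2.0,
        )

    def is_baseline(self) -> bool:
        return (
            self.youth_job_loss_rate_ratio == 1.0
            and self.unemployment_shock_scale == 1.0
            and self.unemployment_effect_decay_rate == 0.0
            and self.years_to_reach_index == 0.0
            and self.duration_social_disconnection == 0.0
        )


@dataclass(frozen=True)
class OutcomeComparison:
    """Scenario-vs-baseline differences on the decade outcomes.

    Percent reductions are ``100·(baseline − scenario)/baseline``; the
    prevalence reduction is in percentage points; prevented counts are
    baseline − scenario rounded at reporting.  Negative values mean the
    scenario did worse than baseline.
    """

    pct_reduction_self_harm: float
    pct_reduction_suicide: float
    pct_reduction_ed: float
    pp_reduction_prevalence: float
    prevented_self_harm: int
    prevented_suicides: int
    prevented_ed: int

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def builtin_scenarios() -> dict[str, ScenarioSpec]:
    """The four published intervention scenarios.

    Technology-effect multipliers use the published parameter-box precision
    (1.177, 1.266, 0.520, 0.869).  The standard-telehealth referral
    multiplier defaults to 1.00 — remote delivery of existing care changes
    neither referrals between services nor who provides them — rather than
    the tabulated 10.00 outlier; pass an explicit ``ScenarioSpec`` to study
    that value.
    """
    return {
        "business_as_usual": ScenarioSpec(name="business_as_usual"),
        "capacity_growth_20": ScenarioSpec(
            name="capacity_growth_20",
            cap_gp_growth=151.02,
            cap_psy_growth=259.57,
            cap_cmhc_growth=75.14,
        ),
        "standard_telehealth": ScenarioSpec(
            name="standard_telehealth",
            u_max=0.70,
            m_rec=1.09,
            m_ref=1.00,
            m_dis=0.76,
            m_rel=0.93,
            m_cap=1.10,
        ),
        "tech_enabled_coordination": ScenarioSpec(
            name="tech_enabled_coordination",
            u_max=0.70,
            m_rec=1.177,
            m_ref=1.266,
            m_dis=0.520,
            m_aod=1.10,
            m_rel=0.869,
            m_emp=1.10,
            m_home=1.10,
            m_cap=1.10,
            m_onl=1.10,
        ),
    }


def uptake(t: float, spec: ScenarioSpec) -> float:
    """Covered-service fraction at decimal year ``t``: 0 before the start,
    linear ramp to ``u_max`` over ``ramp_years``, ``u_max`` thereafter."""
    if spec.u_max == 0.0 or t < spec.start_year:
        return 0.0
    if spec.ramp_years <= 0:
        return spec.u_max
    return spec.u_max * min(1.0, (t - spec.start_year) / spec.ramp_years)


def effective_multiplier(m: float, u: float) -> float:
    """Population-mix blend of covered (``m``) and uncovered (1) services."""
    if m <= 0:
        raise ValueError("multiplier must be positive")
    if not 0.0 <= u <= 1.0:
        raise ValueError("uptake must lie in [0, 1]")
    return 1.0 + u * (m - 1.0)


def _uptake_expr(spec: ScenarioSpec) -> str:
    u, t0, ramp = spec.u_max, spec.start_year, spec.ramp_years
    if ramp <= 0:
        return f"({u!r} if t >= {t0!r} else 0.0)"
    return f"({u!r} * min(1.0, max(0.0, (t - {t0!r}) / {ramp!r})))"


_HOOK_OF = {
    "m_rec": "m_rec_eff",
    "m_ref": "m_ref_eff",
    "m_dis": "m_dis_eff",
    "m_aod": "m_aod_eff",
    "m_rel": "m_rel_eff",
    "m_emp": "m_emp_eff",
    "m_home": "m_home_eff",
    "m_cap": "m_cap_eff",
    "m_onl": "m_onl_eff",
}


def apply_scenario(
    params: ModelParameters,
    spec: ScenarioSpec,
    covid: CovidConditions | None = None,
) -> ModelParameters:
    """Install scenario and condition overrides on a parameter set.

    Capacity increments are replaced by the scenario's; intervention effects
    become time-varying auxiliaries ``1 + u(t)·(m − 1)``; post-pandemic
    conditions add a decaying unemployment inflow shock, the youth job-loss
    ratio and the transient sense-of-community trajectory.  Business-as-usual
    under baseline conditions returns parameters that build a bit-identical
    model.
    """
    covid = covid or CovidConditions.pre()
    out = params

    overrides: dict[str, str] = {}
    # capacity-growth changes take effect at the intervention start year
    for pname, new in (
        ("cap_gp_growth", spec.cap_gp_growth),
        ("cap_psy_growth", spec.cap_psy_growth),
        ("cap_cmhc_growth", spec.cap_cmhc_growth),
    ):
        base = params[pname]
        if new != base:
            overrides[pname] = (
                f"({base!r} if t < {spec.start_year!r} else {new!r})"
            )
    conflicts = set(params.time_varying) & (set(_HOOK_OF.values()) | {"uptake_frac",
                   "unemp_shock", "youth_jl_ratio", "soc_index",
                   "cap_gp_growth", "cap_psy_growth", "cap_cmhc_growth"})
    if conflicts:
        raise ValueError(f"conflicting time-varying overrides: {sorted(conflicts)}")

    if spec.u_max > 0.0:
        overrides["uptake_frac"] = _uptake_expr(spec)
        for attr, hook in _HOOK_OF.items():
            m = getattr(spec, attr)
            if m != 1.0:
                overrides[hook] = f"(1.0 + uptake_frac * {m - 1.0!r})"

    if not covid.is_baseline():
        t0 = covid.shock_onset
        decay = covid.unemployment_effect_decay_rate
        scale = covid.unemployment_shock_scale
        ratio = covid.youth_job_loss_rate_ratio
        decay_wk = decay * WEEKS_PER_YEAR
        overrides["unemp_shock"] = (
            f"(1.0 if t < {t0!r} else 1.0 + {scale - 1.0!r}"
            f" * exp(-{decay_wk!r} * (t - {t0!r})))"
        )
        overrides["youth_jl_ratio"] = (
            f"(1.0 if t < {t0!r} else 1.0 + {ratio - 1.0!r}"
            f" * exp(-{decay_wk!r} * (t - {t0!r})))"
        )
        base, low = params["soc_index_baseline"], covid.sense_of_community_index
        ramp = covid.years_to_reach_index
        hold_end = t0 + ramp + covid.duration_social_disconnection
        if ramp > 0:
            drop = (
                f"(min(1.0, max(0.0, (t - {t0!r}) / {ramp!r}))"
                f" - min(1.0, max(0.0, (t - {hold_end!r}) / {ramp!r})))"
            )
        else:
            drop = f"(1.0 if {t0!r} <= t < {hold_end!r} else 0.0)"
        overrides["soc_index"] = f"({base!r} + {low - base!r} * {drop})"

    if overrides:
        out = out.with_time_varying(**overrides)
    return out


def compare(baseline, scenario) -> OutcomeComparison:
    """Scenario-vs-baseline outcome comparison (same reporting horizon)."""
    if (baseline.epoch, baseline.t_end) != (scenario.epoch, scenario.t_end):
        raise ValueError("summaries cover different horizons")

    def pct(b: float, s: float, what: str) -> float:
        if b == 0:
            raise ZeroDivisionError(f"baseline {what} is zero; percent reduction undefined")
        return 100.0 * (b - s) / b

    return OutcomeComparison(
        pct_reduction_self_harm=pct(
            baseline.self_harm_hospitalizations, scenario.self_harm_hospitalizations,
            "self-harm hospitalizations"),
        pct_reduction_suicide=pct(
            baseline.suicide_deaths, scenario.suicide_deaths, "suicide deaths"),
        pct_reduction_ed=pct(
            baseline.ed_presentations, scenario.ed_presentations, "ED presentations"),
        pp_reduction_prevalence=(
            baseline.prevalence_end_pct - scenario.prevalence_end_pct),
        prevented_self_harm=round(
            baseline.self_harm_hospitalizations - scenario.self_harm_hospitalizations),
        prevented_suicides=round(baseline.suicide_deaths - scenario.suicide_deaths),
        prevented_ed=round(baseline.ed_presentations - scenario.ed_presentations),
    )
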