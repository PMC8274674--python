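"""The regional mental-health system as a concrete stock-and-flow model.

Five interacting sectors:

* **population** — four age groups (0-14, 15-24, 25-64, 65+) with births,
  net migration, mortality and aging chains; adults (15+) carry distress.
* **psychological distress** — adults split into low (K10 10-15), moderate
  (K10 16-21) and high/very-high (K10 22-50) bands with first-order onset,
  escalation and remission transitions; onset is scaled by a social-
  determinant pressure multiplier.
* **social determinants** — unemployment, homelessness and substance-misuse
  levels plus domestic-violence, early-life-adversity and sense-of-community
  indices, combined into power-product pressure multipliers acting on
  distress onset, suicide attempts and service disengagement.
* **service system** — capacity-constrained channels (GP, psychiatrist +
  allied, community mental health, online, ED, inpatient, outpatient) with
  waiting lists, disengagement, referral pathways and per-service recovery
  probabilities; each delivered service can move a person one distress band
  down.  GP, psychiatrist/allied and CMHC capacities grow by fixed yearly
  increments (the capacity-scenario levers).
* **suicidal behaviour** — attempts arise predominantly from the high band,
  a hospitalized fraction becomes self-harm hospitalizations (the attempt
  proxy), a case-fatality fraction becomes suicide deaths, and mental-health
  ED presentations combine a crisis share of attempts with a rate from high
  distress.

People are continuous; waiting lists are shadow queues (members remain in
their distress band while queued) so band totals always sum to the adult
population.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import (
    Flow,
    IntegrationConfig,
    StockFlowModel,
    Trajectory,
    WEEKS_PER_YEAR,
    integrate,
)
from .params import ModelParameters

__all__ = [
    "OutcomeSummary",
    "build_model",
    "derived_parameters",
    "determinant_pressure",
    "service_throughput",
    "grow_capacity",
    "outcome_summary",
    "run",
    "HISTORIC_INDICATORS",
]

# Hooks overridden by scenario application (time-varying expressions).
SCENARIO_HOOKS = {
    "m_rec_eff": "1.0",
    "m_ref_eff": "1.0",
    "m_dis_eff": "1.0",
    "m_aod_eff": "1.0",
    "m_rel_eff": "1.0",
    "m_emp_eff": "1.0",
    "m_home_eff": "1.0",
    "m_cap_eff": "1.0",
    "m_onl_eff": "1.0",
    "unemp_shock": "1.0",
    "youth_jl_ratio": "1.0",
    "soc_index": "soc_index_baseline",
}

HISTORIC_INDICATORS = [
    "distress_prevalence_pct",
    "psychiatric_hospitalizations",
    "ed_presentations",
    "self_harm_hospitalizations",
    "suicide_deaths",
]


def determinant_pressure(
    levels: dict[str, float],
    references: dict[str, float],
    weights: dict[str, float],
    protective: tuple[str, ...] = ("sense_of_community",),
) -> float:
    """Power-product pressure multiplier over social determinants.

    ``prod_d (level_d / ref_d) ** w_d`` over adverse determinants, times
    ``(ref_s / level_s) ** w_s`` for protective ones (sense of community);
    equals 1 exactly when every determinant sits at its reference.
    """
    out = 1.0
    for name, w in weights.items():
        level, ref = levels[name], references[name]
        if level <= 0 or ref <= 0:
            raise ValueError(f"determinant {name!r}: level and reference must be positive")
        ratio = ref / level if name in protective else level / ref
        out *= ratio**w
    return out


def service_throughput(
    demand: float, waiting: float, capacity: float, tau: float = 1.0
) -> tuple[float, float]:
    """Weekly channel throughput under a capacity cap.

    The waiting list drains first (at most ``waiting / tau`` per week), then
    incident demand fills remaining capacity; unserved demand joins the queue.
    Returns ``(served, newly_waiting)`` in persons/week.
    """
    if min(demand, waiting, capacity) < 0:
        raise ValueError("demand, waiting and capacity must be non-negative")
    from_wait = min(waiting / tau, capacity)
    from_new = min(demand, max(capacity - from_wait, 0.0))
    return from_wait + from_new, demand - from_new


def grow_capacity(capacity: float, yearly_increment: float, dt: float) -> float:
    """Capacity after ``dt`` weeks of linear growth at ``yearly_increment``."""
    if yearly_increment < 0:
        raise ValueError("yearly increment must be non-negative")
    return capacity + yearly_increment * dt / WEEKS_PER_YEAR


def derived_parameters(params: ModelParameters) -> dict[str, float]:
    """Initial stocks, aging rates and determinant reference levels.

    References are the deterministic baseline equilibria of the determinant
    stocks, so every pressure multiplier is exactly 1 on the undisturbed
    baseline.
    """
    v = params.values
    total = v["pop_total"]
    pop_0_14 = total * v["frac_0_14"]
    pop_15_24 = total * v["frac_15_24"]
    pop_25_64 = total * v["frac_25_64"]
    pop_65p = total - pop_0_14 - pop_15_24 - pop_25_64
    adults = total - pop_0_14

    high0 = adults * v["init_high_frac"]
    mod0 = adults * v["init_mod_frac"]
    low0 = adults - high0 - mod0

    unemp_ref = v["job_loss_base"] / v["emp_init_rate"]
    home_ref = v["homeless_inflow"] / v["exit_home_rate"]
    subst_rec_ref = v["subst_onset"] / v["sustain_rate"]
    subst_ref = (v["subst_onset"] + v["relapse_rate"] * subst_rec_ref) / v["aod_referral_rate"]

    return {
        "pop_0_14_init": pop_0_14,
        "pop_15_24_init": pop_15_24,
        "pop_25_64_init": pop_25_64,
        "pop_65p_init": pop_65p,
        "distress_low_init": low0,
        "distress_mod_init": mod0,
        "distress_high_init": high0,
        "aging_rate_0": 1.0 / (15.0 * WEEKS_PER_YEAR),
        "aging_rate_1": 1.0 / (10.0 * WEEKS_PER_YEAR),
        "aging_rate_2": 1.0 / (40.0 * WEEKS_PER_YEAR),
        "entry_low_frac": 1.0 - v["entry_mod_frac"] - v["entry_high_frac"],
        "unemp_ref": unemp_ref,
        "home_ref": home_ref,
        "subst_ref": subst_ref,
        "subst_rec_init": subst_rec_ref,
        "dv_ref": v["dv_index"],
        "el_ref": v["early_life_frac"],
        "soc_ref": v["soc_index_baseline"],
    }


def _pressure_expr(kind: str) -> str:
    """Pressure auxiliary for 'onset' | 'att' | 'dis' weight sets."""
    terms = [
        f"(max(unemployed, 1.0) / unemp_ref) ** w_unemp_{kind}",
        f"(max(homeless, 1.0) / home_ref) ** w_home_{kind}",
        f"(max(substance_active, 1.0) / subst_ref) ** w_subst_{kind}",
        f"(soc_ref / soc_index) ** w_soc_{kind}",
    ]
    if kind in ("onset", "att"):
        terms.insert(3, f"(dv_index / dv_ref) ** w_dv_{kind}")
        terms.insert(4, f"(early_life_frac / el_ref) ** w_el_{kind}")
    return " * ".join(terms)


def build_model(params: ModelParameters) -> StockFlowModel:
    """Wire the five sectors into a validated :class:`StockFlowModel`.

    Raises ``ValueError`` naming the problem if the parameter set is
    incomplete or out of bounds.
    """
    diags = params.validate()
    if diags:
        raise ValueError("invalid parameters: " + "; ".join(diags))
    d = derived_parameters(params)

    stocks = {
        "pop_0_14": d["pop_0_14_init"],
        "pop_15_24": d["pop_15_24_init"],
        "pop_25_64": d["pop_25_64_init"],
        "pop_65p": d["pop_65p_init"],
        "distress_low": d["distress_low_init"],
        "distress_mod": d["distress_mod_init"],
        "distress_high": d["distress_high_init"],
        "unemployed": d["unemp_ref"],
        "homeless": d["home_ref"],
        "substance_active": d["subst_ref"],
        "substance_recovery": d["subst_rec_init"],
        "cap_gp": params["cap_gp_init"],
        "cap_psy": params["cap_psy_init"],
        "cap_cmhc": params["cap_cmhc_init"],
        "wait_gp": params["wait_gp_init"],
        "wait_psy": params["wait_psy_init"],
        "wait_cmhc": params["wait_cmhc_init"],
    }

    aux: dict[str, str] = {}
    aux.update(SCENARIO_HOOKS)
    aux.update(
        {
            "adults": "distress_low + distress_mod + distress_high",
            "pressure_onset": _pressure_expr("onset"),
            "pressure_att": _pressure_expr("att"),
            "pressure_dis": _pressure_expr("dis"),
            # general practice: first-contact channel
            "demand_gp": "hs_mod * distress_mod + hs_high * distress_high",
            "high_share_gp": "hs_high * distress_high / max(demand_gp, 1e-9)",
            "served_gp_wait": "min(wait_gp / wait_tau, cap_gp)",
            "served_gp_new": "min(demand_gp, max(cap_gp - served_gp_wait, 0.0))",
            "served_gp": "served_gp_wait + served_gp_new",
            "served_gp_high": "served_gp * high_share_gp",
            "served_gp_mod": "served_gp - served_gp_high",
            # referral pathways out of general practice
            "demand_psy": "p_ref_spec_high * m_ref_eff * served_gp_high",
            "demand_cmhc": "p_ref_cmhc_high * served_gp_high + p_ref_cmhc_mod * served_gp_mod",
            "high_share_cmhc": "p_ref_cmhc_high * served_gp_high / max(demand_cmhc, 1e-9)",
            "demand_online": "p_ref_online_mod * m_onl_eff * served_gp_mod",
            # specialized psychiatric care (capacity lever of care coordination)
            "cap_psy_eff": "cap_psy * m_cap_eff",
            "served_psy_wait": "min(wait_psy / wait_tau, cap_psy_eff)",
            "served_psy_new": "min(demand_psy, max(cap_psy_eff - served_psy_wait, 0.0))",
            "served_psy": "served_psy_wait + served_psy_new",
            # community mental health
            "served_cmhc_wait": "min(wait_cmhc / wait_tau, cap_cmhc)",
            "served_cmhc_new": "min(demand_cmhc, max(cap_cmhc - served_cmhc_wait, 0.0))",
            "served_cmhc": "served_cmhc_wait + served_cmhc_new",
            # online services (no queue)
            "served_online": "min(demand_online, cap_online)",
            # suicidal behaviour and crisis care
            "attempts": "pressure_att * (attempt_rate_high * distress_high"
                        " + attempt_rate_mod * distress_mod)",
            "ed_rate": "crisis_share_ed * attempts + ed_rate_high * distress_high",
            "served_ed": "min(ed_rate, cap_ed)",
            "demand_inpatient": "admit_frac * served_ed",
            "served_inpatient": "min(demand_inpatient, cap_inpatient)",
            "demand_outpatient": "outp_follow * served_inpatient",
            "served_outpatient": "min(demand_outpatient, cap_outpatient)",
            # adult demography shared by population and distress sectors
            "aging_in_adult": "pop_0_14 * aging_rate_0",
            "mig_adult": "mig_15_24 + mig_25_64 + mig_65p",
            "deaths_adult": "mort_15_24 * pop_15_24 + mort_25_64 * pop_25_64"
                            " + mort_65p * pop_65p",
            "entry_adult": "aging_in_adult + mig_adult",
        }
    )
    # honour scenario/pandemic overrides installed on the parameter set
    aux.update(params.time_varying)

    flows = [
        # population
        Flow("births", "birth_rate", sink="pop_0_14"),
        Flow("aging_0", "pop_0_14 * aging_rate_0", source="pop_0_14", sink="pop_15_24"),
        Flow("aging_1", "pop_15_24 * aging_rate_1", source="pop_15_24", sink="pop_25_64"),
        Flow("aging_2", "pop_25_64 * aging_rate_2", source="pop_25_64", sink="pop_65p"),
        Flow("mig_in_0_14", "mig_0_14", sink="pop_0_14"),
        Flow("mig_in_15_24", "mig_15_24", sink="pop_15_24"),
        Flow("mig_in_25_64", "mig_25_64", sink="pop_25_64"),
        Flow("mig_in_65p", "mig_65p", sink="pop_65p"),
        Flow("deaths_0_14", "mort_0_14 * pop_0_14", source="pop_0_14"),
        Flow("deaths_15_24", "mort_15_24 * pop_15_24", source="pop_15_24"),
        Flow("deaths_25_64", "mort_25_64 * pop_25_64", source="pop_25_64"),
        Flow("deaths_65p", "mort_65p * pop_65p", source="pop_65p"),
        Flow("suicide_pop", "case_fatality * attempts", source="pop_25_64"),
        # distress demographic coupling (mirrors the population flows exactly)
        Flow("entry_low", "entry_adult * entry_low_frac", sink="distress_low"),
        Flow("entry_mod", "entry_adult * entry_mod_frac", sink="distress_mod"),
        Flow("entry_high", "entry_adult * entry_high_frac", sink="distress_high"),
        Flow("ddeath_low", "deaths_adult * distress_low / max(adults, 1.0)",
             source="distress_low"),
        Flow("ddeath_mod", "deaths_adult * distress_mod / max(adults, 1.0)",
             source="distress_mod"),
        Flow("ddeath_high", "deaths_adult * distress_high / max(adults, 1.0)",
             source="distress_high"),
        Flow("suicide_death", "case_fatality * attempts", source="distress_high"),
        # distress transitions
        Flow("onset_lm", "onset_rate_lm * pressure_onset * distress_low",
             source="distress_low", sink="distress_mod"),
        Flow("esc_mh", "onset_rate_mh * pressure_onset * distress_mod",
             source="distress_mod", sink="distress_high"),
        Flow("rem_ml", "remission_ml * distress_mod", source="distress_mod",
             sink="distress_low"),
        Flow("rem_hm", "remission_hm * distress_high", source="distress_high",
             sink="distress_mod"),
        # service recoveries (one band down per successful service)
        Flow("rec_gp_mod", "served_gp_mod * p_rec_gp * m_rec_eff",
             source="distress_mod", sink="distress_low"),
        Flow("rec_gp_high", "served_gp_high * p_rec_gp * m_rec_eff",
             source="distress_high", sink="distress_mod"),
        Flow("rec_psy", "served_psy * p_rec_psy * m_rec_eff",
             source="distress_high", sink="distress_mod"),
        Flow("rec_cmhc_high", "served_cmhc * high_share_cmhc * p_rec_cmhc * m_rec_eff",
             source="distress_high", sink="distress_mod"),
        Flow("rec_cmhc_mod", "served_cmhc * (1.0 - high_share_cmhc) * p_rec_cmhc * m_rec_eff",
             source="distress_mod", sink="distress_low"),
        Flow("rec_online", "served_online * p_rec_online * m_rec_eff",
             source="distress_mod", sink="distress_low"),
        Flow("rec_inpatient", "served_inpatient * p_rec_inpatient * m_rec_eff",
             source="distress_high", sink="distress_mod"),
        Flow("rec_outpatient", "served_outpatient * p_rec_outpatient * m_rec_eff",
             source="distress_high", sink="distress_mod"),
        # waiting lists (shadow queues)
        Flow("queue_gp_in", "demand_gp - served_gp_new", sink="wait_gp"),
        Flow("queue_gp_out", "served_gp_wait", source="wait_gp"),
        Flow("diseng_gp", "disengage_rate * pressure_dis * m_dis_eff * wait_gp",
             source="wait_gp"),
        Flow("queue_psy_in", "demand_psy - served_psy_new", sink="wait_psy"),
        Flow("queue_psy_out", "served_psy_wait", source="wait_psy"),
        Flow("diseng_psy", "disengage_rate * pressure_dis * m_dis_eff * wait_psy",
             source="wait_psy"),
        Flow("queue_cmhc_in", "demand_cmhc - served_cmhc_new", sink="wait_cmhc"),
        Flow("queue_cmhc_out", "served_cmhc_wait", source="wait_cmhc"),
        Flow("diseng_cmhc", "disengage_rate * pressure_dis * m_dis_eff * wait_cmhc",
             source="wait_cmhc"),
        # service capacity growth
        Flow("grow_gp", "cap_gp_growth / 52.0", sink="cap_gp"),
        Flow("grow_psy", "cap_psy_growth / 52.0", sink="cap_psy"),
        Flow("grow_cmhc", "cap_cmhc_growth / 52.0", sink="cap_cmhc"),
        # social determinants
        Flow("job_loss",
             "job_loss_base * ((1.0 - youth_share_job_loss)"
             " + youth_share_job_loss * youth_jl_ratio) * unemp_shock",
             sink="unemployed"),
        Flow("employment", "emp_init_rate * m_emp_eff * unemployed", source="unemployed"),
        Flow("homeless_in", "homeless_inflow", sink="homeless"),
        Flow("homeless_out", "exit_home_rate * m_home_eff * homeless", source="homeless"),
        Flow("subst_onset_in", "subst_onset", sink="substance_active"),
        Flow("aod_treatment", "aod_referral_rate * m_aod_eff * substance_active",
             source="substance_active", sink="substance_recovery"),
        Flow("relapse", "relapse_rate * m_rel_eff * substance_recovery",
             source="substance_recovery", sink="substance_active"),
        Flow("sustained_exit", "sustain_rate * substance_recovery",
             source="substance_recovery"),
        # suicidal behaviour / reporting flows
        Flow("self_harm_hosp", "hosp_fraction * attempts"),
        Flow("ed_presentations", "ed_rate"),
        Flow("psych_admissions", "served_inpatient"),
    ]

    counters = {
        "self_harm_hospitalizations": "self_harm_hosp",
        "suicide_deaths": "suicide_death",
        "ed_presentations": "ed_presentations",
        "psych_admissions": "psych_admissions",
    }

    return StockFlowModel(stocks=stocks, flows=flows, aux=aux, counters=counters)


def compile_params(params: ModelParameters) -> dict[str, float]:
    """Flat numeric namespace (declared + derived) for engine compilation."""
    d = derived_parameters(params)
    out = dict(params.values)
    out.update(
        {
            k: v
            for k, v in d.items()
            if k in (
                "aging_rate_0", "aging_rate_1", "aging_rate_2", "entry_low_frac",
                "unemp_ref", "home_ref", "subst_ref", "dv_ref", "el_ref", "soc_ref",
            )
        }
    )
    return out


@dataclass(frozen=True)
class OutcomeSummary:
    """Cumulative 2021-2030 counts and high-distress prevalence endpoints."""

    self_harm_hospitalizations: float
    suicide_deaths: float
    ed_presentations: float
    prevalence_start_pct: float  # high-band prevalence at the reporting epoch
    prevalence_end_pct: float  # high-band prevalence at the horizon end
    epoch: float
    t_end: float


def high_distress_prevalence(traj: Trajectory, t: float) -> float:
    """High/very-high distress share of the modelled adult population, in %."""
    i = traj.at_time(t)
    low = traj.stock("distress_low")[i]
    mod = traj.stock("distress_mod")[i]
    high = traj.stock("distress_high")[i]
    return 100.0 * high / (low + mod + high)


def outcome_summary(traj: Trajectory) -> OutcomeSummary:
    """Read the three cumulative counters and prevalence endpoints."""
    epoch, t_end = traj.counter_epoch, float(traj.times[-1])
    if traj.times[0] > epoch or t_end < epoch + 1.0:
        raise ValueError(f"trajectory must cover the reporting window from {epoch}")
    return OutcomeSummary(
        self_harm_hospitalizations=traj.counter("self_harm_hospitalizations"),
        suicide_deaths=traj.counter("suicide_deaths"),
        ed_presentations=traj.counter("ed_presentations"),
        prevalence_start_pct=high_distress_prevalence(traj, epoch),
        prevalence_end_pct=high_distress_prevalence(traj, t_end),
        epoch=epoch,
        t_end=t_end,
    )


def run(
    params: ModelParameters | None = None,
    config: IntegrationConfig | None = None,
) -> Trajectory:
    """Build and integrate the model in one call."""
    params = params or ModelParameters()
    return integrate(build_model(params), compile_params(params), config)


def historic_series(traj: Trajectory, years: list[int] | None = None) -> dict[str, list[float]]:
    """Yearly validation indicators (the five historic-comparison series)."""
    years = years or list(range(2011, 2018))
    out: dict[str, list[float]] = {"year": [float(y) for y in years]}
    out["distress_prevalence_pct"] = [high_distress_prevalence(traj, y + 0.5) for y in years]
    for indicator, flow in [
        ("psychiatric_hospitalizations", "psych_admissions"),
        ("ed_presentations", "ed_presentations"),
        ("self_harm_hospitalizations", "self_harm_hosp"),
        ("suicide_deaths", "suicide_death"),
    ]:
        out[indicator] = list(traj.yearly_flow_totals(flow, years))
    return out
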