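"""Model parameter registry: every rate, fraction, multiplier and initial
condition of the regional mental-health model, with units, bounds and sector.

Parameters are flat and serialize to YAML/JSON as a documented mapping.  A
:class:`ModelParameters` instance carries numeric values plus optional
*time-varying overrides* — expression strings (see :mod:`mhsd.engine`) that
scenario application installs to replace constant auxiliaries such as the
intervention-effect multipliers or the sense-of-community index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import yaml

__all__ = ["ParamSpec", "ModelParameters", "PARAM_SPECS", "default_parameters"]


@dataclass(frozen=True)
class ParamSpec:
    name: str
    default: float
    units: str
    bounds: tuple[float, float]
    sector: str
    doc: str


def _p(name, default, units, lo, hi, sector, doc) -> ParamSpec:
    return ParamSpec(name, float(default), units, (float(lo), float(hi)), sector, doc)


# Defaults for the behavioural rates below are the product of calibrating the
# business-as-usual pre-pandemic run against the packaged decade forecast
# anchors (see mhsd.calibration / mhsd.reported); demographic and service
# structure values are plausible magnitudes for a ~500k regional catchment.
PARAM_SPECS: dict[str, ParamSpec] = {
    s.name: s
    for s in [
        # -- population ------------------------------------------------------
        _p("pop_total", 502_524, "persons", 4e5, 6e5, "population",
           "Total regional population at the simulation start (2011)."),
        _p("frac_0_14", 0.17, "fraction", 0.10, 0.30, "population",
           "Share of the population aged 0-14 at start."),
        _p("frac_15_24", 0.11, "fraction", 0.05, 0.20, "population",
           "Share aged 15-24 at start."),
        _p("frac_25_64", 0.50, "fraction", 0.35, 0.65, "population",
           "Share aged 25-64 at start."),
        _p("birth_rate", 96.0, "persons/week", 0.0, 400.0, "population",
           "Births entering the 0-14 group."),
        _p("mort_0_14", 3.8e-6, "fraction/week", 0.0, 1e-4, "population",
           "Weekly mortality, 0-14."),
        _p("mort_15_24", 7.7e-6, "fraction/week", 0.0, 1e-4, "population",
           "Weekly mortality, 15-24."),
        _p("mort_25_64", 4.8e-5, "fraction/week", 0.0, 1e-3, "population",
           "Weekly mortality, 25-64."),
        _p("mort_65p", 7.7e-4, "fraction/week", 0.0, 1e-2, "population",
           "Weekly mortality, 65+."),
        _p("mig_0_14", 4.0, "persons/week", -50.0, 100.0, "population",
           "Net migration into the 0-14 group."),
        _p("mig_15_24", 2.0, "persons/week", -50.0, 100.0, "population",
           "Net migration into the 15-24 group."),
        _p("mig_25_64", 22.0, "persons/week", -50.0, 200.0, "population",
           "Net migration into the 25-64 group."),
        _p("mig_65p", 18.0, "persons/week", -50.0, 200.0, "population",
           "Net migration into the 65+ group."),
        # -- psychological distress -----------------------------------------
        _p("init_mod_frac", 0.11496, "fraction", 0.05, 0.40, "distress",
           "Initial share of adults in moderate distress (K10 16-21)."),
        _p("init_high_frac", 0.23912, "fraction", 0.05, 0.40, "distress",
           "Initial share of adults in high/very-high distress (K10 22-50)."),
        _p("entry_mod_frac", 0.16, "fraction", 0.0, 0.5, "distress",
           "Share of adult entrants (aging-in, net migration) arriving moderately distressed."),
        _p("entry_high_frac", 0.08, "fraction", 0.0, 0.5, "distress",
           "Share of adult entrants arriving in high/very-high distress."),
        _p("onset_rate_lm", 0.0036316, "fraction/week", 0.0, 0.05, "distress",
           "Low -> moderate distress onset rate (scaled by determinant pressure)."),
        _p("onset_rate_mh", 0.0085104, "fraction/week", 0.0, 0.05, "distress",
           "Moderate -> high/very-high escalation rate (scaled by pressure)."),
        _p("remission_ml", 0.0100, "fraction/week", 0.0, 0.05, "distress",
           "Spontaneous moderate -> low remission."),
        _p("remission_hm", 0.0060, "fraction/week", 0.0, 0.05, "distress",
           "Spontaneous high -> moderate remission."),
        # -- social determinants --------------------------------------------
        _p("job_loss_base", 200.0, "persons/week", 10.0, 2000.0, "determinants",
           "Baseline flow into unemployment."),
        _p("youth_share_job_loss", 0.25, "fraction", 0.0, 1.0, "determinants",
           "Share of job losses falling on the 15-24 group (pandemic ratio applies here)."),
        _p("emp_init_rate", 0.010, "fraction/week", 1e-4, 0.2, "determinants",
           "Employment initiation (exit from unemployment); employment-service effects multiply it."),
        _p("homeless_inflow", 6.0, "persons/week", 0.1, 100.0, "determinants",
           "Flow into homelessness."),
        _p("exit_home_rate", 0.004, "fraction/week", 1e-4, 0.1, "determinants",
           "Exit rate from homelessness (inverse duration); housing-service effects multiply it."),
        _p("subst_onset", 25.0, "persons/week", 1.0, 500.0, "determinants",
           "Onset flow into active substance misuse."),
        _p("aod_referral_rate", 0.004, "fraction/week", 1e-4, 0.1, "determinants",
           "Referral of active substance misuse into treatment/recovery."),
        _p("relapse_rate", 0.006, "fraction/week", 1e-4, 0.1, "determinants",
           "Relapse from recovery back to active misuse."),
        _p("sustain_rate", 0.005, "fraction/week", 1e-4, 0.1, "determinants",
           "Sustained-recovery exit from the recovery pool."),
        _p("dv_index", 1.0, "index", 0.1, 10.0, "determinants",
           "Domestic-violence exposure index (baseline reference 1)."),
        _p("early_life_frac", 0.30, "fraction", 0.01, 0.9, "determinants",
           "Early-life adversity exposure fraction (baseline reference equals default)."),
        _p("soc_index_baseline", 9.61, "index", 5.0, 12.0, "determinants",
           "Sense-of-community (social connectedness) index, baseline value."),
        # pressure weights: exponents of the power-product multiplier
        _p("w_unemp_onset", 0.21, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of unemployment on distress onset."),
        _p("w_home_onset", 0.055, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of homelessness on distress onset."),
        _p("w_subst_onset", 0.085, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of substance misuse on distress onset."),
        _p("w_dv_onset", 0.035, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of domestic-violence exposure on distress onset."),
        _p("w_el_onset", 0.035, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of early-life adversity on distress onset."),
        _p("w_soc_onset", 0.55, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of (inverse) sense of community on distress onset."),
        _p("w_unemp_att", 0.02, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of unemployment on the suicide-attempt rate."),
        _p("w_home_att", 0.01, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of homelessness on the attempt rate."),
        _p("w_subst_att", 0.02, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of substance misuse on the attempt rate."),
        _p("w_dv_att", 0.01, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of domestic-violence exposure on the attempt rate."),
        _p("w_el_att", 0.00, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of early-life adversity on the attempt rate."),
        _p("w_soc_att", 0.10, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of (inverse) sense of community on the attempt rate."),
        _p("w_unemp_dis", 0.10, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of unemployment on service disengagement."),
        _p("w_home_dis", 0.00, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of homelessness on service disengagement."),
        _p("w_subst_dis", 0.00, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of substance misuse on service disengagement."),
        _p("w_soc_dis", 0.50, "dimensionless", 0.0, 2.0, "determinants",
           "Weight of (inverse) sense of community on service disengagement."),
        # -- service system --------------------------------------------------
        _p("hs_mod", 0.025, "fraction/week", 0.0, 0.2, "services",
           "Help-seeking (GP consultation) rate of moderately distressed adults."),
        _p("hs_high", 0.042, "fraction/week", 0.0, 0.2, "services",
           "Help-seeking rate of high/very-high-distress adults."),
        _p("cap_gp_init", 2400.0, "services/week", 0.0, 20000.0, "services",
           "Initial general-practice mental-health service capacity."),
        _p("cap_gp_growth", 125.85, "services/week/year", 0.0, 1000.0, "services",
           "Yearly increase in GP capacity (scenario lever)."),
        _p("cap_psy_init", 600.0, "services/week", 0.0, 10000.0, "services",
           "Initial psychiatrist + allied mental-health capacity."),
        _p("cap_psy_growth", 216.31, "services/week/year", 0.0, 1000.0, "services",
           "Yearly increase in psychiatrist/allied capacity (scenario lever)."),
        _p("cap_cmhc_init", 150.0, "services/week", 0.0, 5000.0, "services",
           "Initial community mental-health (CMHC) capacity."),
        _p("cap_cmhc_growth", 0.0, "services/week/year", 0.0, 1000.0, "services",
           "Yearly increase in CMHC capacity (scenario lever)."),
        _p("cap_online", 400.0, "services/week", 0.0, 5000.0, "services",
           "Online-services capacity (constant)."),
        _p("cap_ed", 400.0, "services/week", 0.0, 5000.0, "services",
           "Emergency-department mental-health capacity (constant)."),
        _p("cap_inpatient", 120.0, "services/week", 0.0, 2000.0, "services",
           "Psychiatric inpatient admission capacity (constant)."),
        _p("cap_outpatient", 300.0, "services/week", 0.0, 5000.0, "services",
           "Hospital outpatient follow-up capacity (constant)."),
        _p("wait_tau", 1.0, "weeks", 0.25, 8.0, "services",
           "Waiting-list drain time constant (weeks to clear a queue given capacity)."),
        _p("wait_gp_init", 6000.0, "persons", 0.0, 10000.0, "services",
           "Initial GP waiting list."),
        _p("wait_psy_init", 300.0, "persons", 0.0, 10000.0, "services",
           "Initial psychiatrist/allied waiting list."),
        _p("wait_cmhc_init", 500.0, "persons", 0.0, 10000.0, "services",
           "Initial CMHC waiting list."),
        _p("p_ref_spec_high", 0.50, "probability", 0.0, 1.0, "services",
           "GP referral probability to specialized psychiatric care, high-distress consultations "
           "(care-coordination referral effects multiply it)."),
        _p("p_ref_online_mod", 0.08, "probability", 0.0, 1.0, "services",
           "GP referral probability to online services, moderate-distress consultations."),
        _p("p_ref_cmhc_high", 0.06, "probability", 0.0, 1.0, "services",
           "GP referral probability to CMHC, high-distress consultations."),
        _p("p_ref_cmhc_mod", 0.03, "probability", 0.0, 1.0, "services",
           "GP referral probability to CMHC, moderate-distress consultations."),
        _p("p_rec_gp", 0.05, "probability", 0.0, 1.0, "services",
           "Per-service probability that a GP consultation drops distress one band."),
        _p("p_rec_psy", 0.16, "probability", 0.0, 1.0, "services",
           "Per-service recovery probability, psychiatrist/allied care."),
        _p("p_rec_cmhc", 0.12, "probability", 0.0, 1.0, "services",
           "Per-service recovery probability, CMHC."),
        _p("p_rec_online", 0.06, "probability", 0.0, 1.0, "services",
           "Per-service recovery probability, online services."),
        _p("p_rec_inpatient", 0.25, "probability", 0.0, 1.0, "services",
           "Per-admission recovery probability, psychiatric inpatient care."),
        _p("p_rec_outpatient", 0.12, "probability", 0.0, 1.0, "services",
           "Per-service recovery probability, outpatient follow-up."),
        _p("disengage_rate", 0.20, "fraction/week", 0.0, 1.0, "services",
           "Weekly disengagement from waiting lists (scaled by pressure and the "
           "care-coordination disengagement multiplier)."),
        _p("admit_frac", 0.12, "probability", 0.0, 1.0, "services",
           "Fraction of served mental-health ED presentations admitted to psychiatric inpatient care."),
        _p("outp_follow", 0.80, "probability", 0.0, 1.0, "services",
           "Outpatient follow-up demand per inpatient admission."),
        # -- suicidal behaviour ---------------------------------------------
        _p("attempt_rate_high", 3.373e-4, "attempts/person/week", 0.0, 5e-3, "suicidality",
           "Suicide-attempt rate of the high/very-high distress band (scaled by pressure)."),
        _p("attempt_rate_mod", 1.55e-5, "attempts/person/week", 0.0, 1e-3, "suicidality",
           "Attempt rate of the moderate band."),
        _p("hosp_fraction", 1.0, "probability", 0.0, 1.0, "suicidality",
           "Hospitalized fraction of attempts (self-harm hospitalizations are the attempt proxy)."),
        _p("case_fatality", 0.0776438, "probability", 0.0, 1.0, "suicidality",
           "Case-fatality fraction of attempts (suicide deaths per attempt)."),
        _p("crisis_share_ed", 1.0, "presentations/attempt", 0.0, 2.0, "suicidality",
           "Mental-health ED presentations generated per suicide attempt."),
        _p("ed_rate_high", 2.0032e-3, "presentations/person/week", 0.0, 2e-2, "suicidality",
           "ED presentation rate from (untreated) high/very-high distress."),
    ]
}


@dataclass
class ModelParameters:
    """Numeric parameter values plus time-varying auxiliary overrides."""

    values: dict[str, float] = field(default_factory=dict)
    time_varying: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {name: spec.default for name, spec in PARAM_SPECS.items()}
        unknown = set(self.values) - set(merged)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        merged.update({k: float(v) for k, v in self.values.items()})
        self.values = merged

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def with_updates(self, updates: dict[str, float] | None = None, **kw: float) -> "ModelParameters":
        new = dict(self.values)
        new.update(updates or {})
        new.update(kw)
        return ModelParameters(values=new, time_varying=dict(self.time_varying))

    def with_time_varying(self, **overrides: str) -> "ModelParameters":
        tv = dict(self.time_varying)
        tv.update(overrides)
        return ModelParameters(values=dict(self.values), time_varying=tv)

    def validate(self) -> list[str]:
        """Bound violations as diagnostics (empty list when all in bounds)."""
        diags = []
        for name, value in self.values.items():
            lo, hi = PARAM_SPECS[name].bounds
            if not math.isfinite(value) or not (lo <= value <= hi):
                diags.append(f"parameter {name!r}: value {value} outside bounds [{lo}, {hi}]")
        share_sum = self.values["frac_0_14"] + self.values["frac_15_24"] + self.values["frac_25_64"]
        if share_sum >= 1.0:
            diags.append("age-group shares (excluding 65+) must sum to < 1")
        if self.values["init_mod_frac"] + self.values["init_high_frac"] >= 1.0:
            diags.append("initial moderate + high distress shares must sum to < 1")
        if self.values["entry_mod_frac"] + self.values["entry_high_frac"] >= 1.0:
            diags.append("entrant moderate + high distress shares must sum to < 1")
        return diags

    # -- serialization -------------------------------------------------------
    def to_yaml(self, path=None) -> str:
        doc = {
            "parameters": {
                name: {
                    "value": self.values[name],
                    "units": PARAM_SPECS[name].units,
                    "bounds": list(PARAM_SPECS[name].bounds),
                    "sector": PARAM_SPECS[name].sector,
                    "doc": PARAM_SPECS[name].doc,
                }
                for name in PARAM_SPECS
            },
            "time_varying": dict(self.time_varying),
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "ModelParameters":
        """Load from a YAML string or file path.

        Accepts both the full documented schema written by :meth:`to_yaml`
        and a bare ``{name: value}`` mapping.
        """
        try:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        except (OSError, ValueError):
            doc = yaml.safe_load(source)
        if not isinstance(doc, dict):
            raise ValueError("parameter config must be a mapping")
        raw = doc.get("parameters", doc)
        values = {}
        for name, entry in raw.items():
            if name == "time_varying":
                continue
            values[name] = entry["value"] if isinstance(entry, dict) else float(entry)
        return cls(values=values, time_varying=dict(doc.get("time_varying", {})))


def default_parameters() -> ModelParameters:
    return ModelParameters()
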