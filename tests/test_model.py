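"""Concrete model wiring: sector operations, conservation, closed forms."""

import math

import numpy as np
import pytest

from mhsd.engine import IntegrationConfig, validate_model
from mhsd.model import (
    build_model,
    compile_params,
    determinant_pressure,
    grow_capacity,
    high_distress_prevalence,
    historic_series,
    outcome_summary,
    run,
    service_throughput,
)
from mhsd.params import ModelParameters


class TestDeterminantPressure:
    REFS = {"unemployment": 20000.0, "sense_of_community": 9.61}

    def test_unity_at_reference(self):
        levels = dict(self.REFS)
        w = {"unemployment": 0.3, "sense_of_community": 1.0}
        assert determinant_pressure(levels, self.REFS, w) == pytest.approx(1.0)

    def test_power_product_form(self):
        levels = {"unemployment": 40000.0, "sense_of_community": 9.61}
        w = {"unemployment": 0.5, "sense_of_community": 1.0}
        assert determinant_pressure(levels, self.REFS, w) == pytest.approx(math.sqrt(2.0))

    def test_sense_of_community_is_protective(self):
        levels = {"unemployment": 20000.0, "sense_of_community": 8.24}
        w = {"unemployment": 0.3, "sense_of_community": 1.0}
        assert determinant_pressure(levels, self.REFS, w) == pytest.approx(
            9.61 / 8.24
        )  # = 1.1663

    def test_nonpositive_level_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            determinant_pressure({"unemployment": 0.0, "sense_of_community": 9.61},
                                 self.REFS, {"unemployment": 0.3})


class TestServiceThroughput:
    def test_unconstrained(self):
        assert service_throughput(10.0, 0.0, 20.0) == (10.0, 0.0)

    def test_capacity_binding(self):
        assert service_throughput(30.0, 0.0, 20.0) == (20.0, 10.0)

    def test_waiting_drains_first(self):
        served, newly_waiting = service_throughput(10.0, 15.0, 20.0)
        assert served == 20.0
        # 15 leave the queue, 5 unserved new demand joins: net -10/week
        assert newly_waiting == 5.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            service_throughput(-1.0, 0.0, 10.0)


class TestGrowCapacity:
    def test_gp_increment_over_one_year(self):
        assert grow_capacity(1000.0, 125.85, 52.0) == pytest.approx(1125.85)

    def test_zero_increment(self):
        assert grow_capacity(321.0, 0.0, 52.0) == 321.0

    def test_psychiatrist_increment(self):
        assert grow_capacity(2000.0, 259.57, 52.0) == pytest.approx(2259.57)

    def test_negative_increment_rejected(self):
        with pytest.raises(ValueError):
            grow_capacity(100.0, -1.0, 1.0)


def test_default_model_validates_cleanly(default_params):
    model = build_model(default_params)
    assert validate_model(model, compile_params(default_params)) == []


def test_missing_or_invalid_parameter_is_named():
    with pytest.raises(KeyError, match="no_such_rate"):
        ModelParameters(values={"no_such_rate": 1.0})
    with pytest.raises(ValueError, match="case_fatality"):
        build_model(ModelParameters().with_updates(case_fatality=2.0))


def test_initial_population_matches_configured_total(default_params):
    model = build_model(default_params)
    pop = sum(model.stocks[s] for s in
              ("pop_0_14", "pop_15_24", "pop_25_64", "pop_65p"))
    assert pop == pytest.approx(502_524.0)


def test_frozen_demography_keeps_groups_constant(fast_config):
    """With zero births, migration, mortality and suppressed aging the age
    groups stay constant (aging is structural, so route entrants to reproduce
    stasis via zero-rate checks on the other flows)."""
    p = ModelParameters().with_updates(
        birth_rate=0, mig_0_14=0, mig_15_24=0, mig_25_64=0, mig_65p=0,
        mort_0_14=0, mort_15_24=0, mort_25_64=0, mort_65p=0,
        attempt_rate_high=0, attempt_rate_mod=0,
    )
    traj = run(p, fast_config)
    total = traj.stock_values[:, :4].sum(axis=1)
    assert np.allclose(total, total[0], rtol=1e-12)


def test_zero_rate_identity_leaves_counters_zero(fast_config):
    """No onset, attempts or service demand: all decade counters stay zero."""
    p = ModelParameters().with_updates(
        onset_rate_lm=0, onset_rate_mh=0, attempt_rate_high=0, attempt_rate_mod=0,
        hs_mod=0, hs_high=0, ed_rate_high=0, crisis_share_ed=0,
    )
    s = outcome_summary(run(p, fast_config))
    assert s.self_harm_hospitalizations == 0.0
    assert s.suicide_deaths == 0.0
    assert s.ed_presentations == 0.0


def test_closed_form_suicide_deaths_without_feedback(fast_config):
    """With every transition and service pathway disabled, the high-distress
    stock decays only through fatal attempts, so cumulative deaths follow
    H0·(1 − e^{−r·f·T}) exactly; the no-feedback approximation r·H0·f·T
    agrees to within its own depletion error."""
    r, f = 3.0e-4, 0.05
    p = ModelParameters().with_updates(
        onset_rate_lm=0, onset_rate_mh=0, remission_ml=0, remission_hm=0,
        hs_mod=0, hs_high=0, ed_rate_high=0, crisis_share_ed=0,
        attempt_rate_mod=0, attempt_rate_high=r, case_fatality=f,
        hosp_fraction=1.0,
        birth_rate=0, mig_0_14=0, mig_15_24=0, mig_25_64=0, mig_65p=0,
        mort_0_14=0, mort_15_24=0, mort_25_64=0, mort_65p=0,
        entry_mod_frac=0.0, entry_high_frac=0.0,
    )
    traj = run(p)
    H0 = build_model(p).stocks["distress_high"]
    # counting starts at the 2021 epoch, 10 years into the decay
    T_pre, T = 10 * 52.0, 9 * 52.0
    H_2021 = H0 * math.exp(-r * f * T_pre)
    exact = H_2021 * (1.0 - math.exp(-r * f * T))
    deaths = traj.counter("suicide_deaths")
    assert deaths == pytest.approx(exact, rel=2e-3)
    assert deaths == pytest.approx(r * H_2021 * f * T, rel=5e-3)


def test_people_conservation(baseline_traj):
    """Distress bands always sum to the adult population (15+)."""
    bands = (baseline_traj.stock("distress_low")
             + baseline_traj.stock("distress_mod")
             + baseline_traj.stock("distress_high"))
    adults = (baseline_traj.stock("pop_15_24")
              + baseline_traj.stock("pop_25_64")
              + baseline_traj.stock("pop_65p"))
    assert np.max(np.abs(bands - adults)) / adults[0] < 1e-6


def test_capacity_binding_zero_capacity(default_params, fast_config, baseline_traj):
    """With every channel capacity at zero there are no service recoveries
    and untreated prevalence dominates the default run at every time."""
    p = default_params.with_updates(
        cap_gp_init=0, cap_psy_init=0, cap_cmhc_init=0, cap_online=0,
        cap_ed=0, cap_inpatient=0, cap_outpatient=0,
        cap_gp_growth=0, cap_psy_growth=0, cap_cmhc_growth=0,
        wait_gp_init=0, wait_psy_init=0, wait_cmhc_init=0,
    )
    traj = run(p)
    for flow in ("rec_gp_mod", "rec_gp_high", "rec_psy", "rec_cmhc_high",
                 "rec_cmhc_mod", "rec_online", "rec_inpatient", "rec_outpatient"):
        assert np.all(traj.flow(flow) == 0.0)
    prev_zero = traj.stock("distress_high") / (
        traj.stock("distress_low") + traj.stock("distress_mod")
        + traj.stock("distress_high"))
    prev_default = baseline_traj.stock("distress_high") / (
        baseline_traj.stock("distress_low") + baseline_traj.stock("distress_mod")
        + baseline_traj.stock("distress_high"))
    assert np.all(prev_zero >= prev_default - 1e-12)


def test_monotone_harm_in_determinant_weight(fast_config):
    """Raising the unemployment weight on attempts cannot reduce cumulative
    self-harm when unemployment is elevated above its reference."""
    from mhsd.scenarios import CovidConditions, ScenarioSpec, apply_scenario

    spec = ScenarioSpec(name="business_as_usual")
    post = CovidConditions.post()
    counts = []
    for w in (0.02, 0.2, 0.5):
        p = ModelParameters().with_updates(w_unemp_att=w)
        traj = run(apply_scenario(p, spec, post), fast_config)
        counts.append(traj.counter("self_harm_hospitalizations"))
    assert counts[0] <= counts[1] <= counts[2]
    assert counts[2] > counts[0]


def test_outcome_summary_requires_reporting_window(default_params):
    cfg = IntegrationConfig(t_start=2011.0, t_end=2020.0)
    with pytest.raises(ValueError, match="reporting window"):
        outcome_summary(run(default_params, cfg))


def test_historic_series_shape_and_positivity(baseline_traj):
    h = historic_series(baseline_traj)
    assert len(h["year"]) == 7
    for key, values in h.items():
        assert len(values) == 7
        assert all(v > 0 for v in values)


def test_prevalence_accessor_matches_summary(baseline_traj):
    s = outcome_summary(baseline_traj)
    assert high_distress_prevalence(baseline_traj, 2021.0) == pytest.approx(
        s.prevalence_start_pct)
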