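"""Integrator correctness: oracles, invariants and diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhsd.engine import (
    Flow,
    IntegrationConfig,
    StockFlowModel,
    decaying_pulse_profile,
    integrate,
    ramp_profile,
    step_profile,
    validate_model,
)


def decay_model():
    return StockFlowModel(
        stocks={"S": 100.0},
        flows=[Flow("out", "k*S", source="S")],
        counters={"lost": "out"},
    )


def test_zero_flow_identity():
    """All-zero flows leave every stock constant and counters at zero."""
    m = StockFlowModel(
        stocks={"A": 10.0, "B": 5.0},
        flows=[Flow("f", "0.0", source="A", sink="B")],
        counters={"c": "f"},
    )
    traj = integrate(m, {}, IntegrationConfig(t_start=2011.0, t_end=2015.0))
    assert np.all(traj.stock("A") == 10.0)
    assert np.all(traj.stock("B") == 5.0)
    assert traj.counter("c") == 0.0


def test_steps_per_year():
    """One-sixteenth-of-a-week steps give exactly 832 steps per 52-week year."""
    cfg = IntegrationConfig(t_start=2011.0, t_end=2012.0, dt=1.0 / 16.0)
    assert cfg.n_steps == 832


class TestExponentialDecay:
    """0.1/week decay of a single stock over 52 weeks vs 100·e^{-5.2}."""

    EXACT = 100.0 * math.exp(-5.2)

    def run(self, dt, method="euler"):
        cfg = IntegrationConfig(t_start=2011.0, t_end=2012.0, dt=dt,
                                record_every=1, method=method)
        return integrate(decay_model(), {"k": 0.1}, cfg).stock("S")[-1]

    def test_euler_value_and_first_order_convergence(self):
        # frozen value of the explicit-Euler discretization (1 - k·dt)^832
        assert self.run(1 / 16) == pytest.approx(100.0 * (1 - 0.1 / 16) ** 832, rel=1e-12)
        # analytic first-order error: k²·T·dt/2 = 1.6% at dt = 1/16 week
        err16 = abs(self.run(1 / 16) - self.EXACT) / self.EXACT
        err32 = abs(self.run(1 / 32) - self.EXACT) / self.EXACT
        assert err16 == pytest.approx(0.0162, abs=0.002)
        assert err32 / err16 == pytest.approx(0.5, abs=0.05)

    def test_rk4_within_half_percent(self):
        assert abs(self.run(1 / 16, "rk4") - self.EXACT) / self.EXACT < 0.005


def test_mass_balance_closed_subsystem():
    """Flows confined to member stocks conserve their total to < 1e-6."""
    m = StockFlowModel(
        stocks={"A": 60.0, "B": 30.0, "C": 10.0},
        flows=[
            Flow("ab", "0.2*A", source="A", sink="B"),
            Flow("bc", "0.05*B", source="B", sink="C"),
            Flow("ca", "0.4*C", source="C", sink="A"),
        ],
    )
    traj = integrate(m, {}, IntegrationConfig(t_start=2011.0, t_end=2030.0))
    totals = traj.stock("A") + traj.stock("B") + traj.stock("C")
    assert np.max(np.abs(totals - 100.0)) / 100.0 < 1e-6


def test_outflow_rationing_keeps_stocks_nonnegative():
    """A demand far above the stock drains it exactly to zero, with both
    outflows scaled by the same factor."""
    m = StockFlowModel(
        stocks={"S": 1.0, "A": 0.0, "B": 0.0},
        flows=[
            Flow("fa", "30.0", source="S", sink="A"),
            Flow("fb", "10.0", source="S", sink="B"),
        ],
    )
    traj = integrate(m, {}, IntegrationConfig(t_start=2011.0, t_end=2011.5, dt=1.0,
                                              record_every=1))
    assert np.all(traj.stock_values >= 0.0)
    assert traj.stock("S")[-1] == pytest.approx(0.0, abs=1e-12)
    # proportional split 3:1 of the single unit available
    assert traj.stock("A")[-1] == pytest.approx(0.75)
    assert traj.stock("B")[-1] == pytest.approx(0.25)


def test_counter_accumulates_only_after_epoch():
    """A constant boundary flow of 0.2/week over the 9 reporting years sums
    to 93.6 regardless of the pre-epoch horizon."""
    m = StockFlowModel(stocks={"S": 1.0}, flows=[Flow("deaths", "0.2")],
                       counters={"cum": "deaths"})
    traj = integrate(m, {}, IntegrationConfig(t_start=2011.0, t_end=2030.0,
                                              counter_epoch=2021.0))
    assert traj.counter("cum") == pytest.approx(0.2 * 52 * 9, rel=1e-9)
    assert np.all(np.diff(traj.counter_values[:, 0]) >= -1e-12)


def test_validate_well_formed_model_is_clean():
    m = StockFlowModel(
        stocks={"A": 1.0, "B": 2.0},
        flows=[Flow("f", "r*A", source="A", sink="B")],
        aux={"x": "A + B"},
    )
    assert validate_model(m, {"r": 0.1}) == []


def test_validate_flags_unknown_stock_and_names():
    m = StockFlowModel(stocks={"A": 1.0}, flows=[Flow("f", "r*Z", source="Q")])
    diags = validate_model(m, {"r": 1.0})
    assert any("f" in d and "Q" in d for d in diags)
    assert any("f" in d and "Z" in d for d in diags)


def test_validate_flags_auxiliary_cycle():
    m = StockFlowModel(stocks={"S": 1.0}, flows=[],
                       aux={"a": "b + 1.0", "b": "a + 1.0"})
    diags = validate_model(m)
    assert any("cycle" in d and "a" in d and "b" in d for d in diags)


def test_validate_flags_bad_counter_and_negative_stock():
    m = StockFlowModel(stocks={"S": -1.0}, flows=[Flow("f", "1.0")],
                       counters={"c": "nope"})
    diags = validate_model(m)
    assert any("counter" in d for d in diags)
    assert any("initial value" in d for d in diags)


def test_nonfinite_flow_aborts_and_names_the_flow():
    # overflow to inf without raising inside the expression
    m = StockFlowModel(stocks={"S": 1.0},
                       flows=[Flow("bad", "S * (t - 2011.0) * 1e308 * 1e308")])
    with pytest.raises(FloatingPointError, match="bad"):
        integrate(m, {}, IntegrationConfig(t_start=2011.0, t_end=2012.0,
                                           dt=0.25, record_every=1))


def test_raising_expression_aborts_with_time():
    m = StockFlowModel(stocks={"S": 1.0}, flows=[Flow("div", "S / (t - 2011.5)")])
    with pytest.raises(FloatingPointError, match="2011.5"):
        integrate(m, {}, IntegrationConfig(t_start=2011.0, t_end=2012.0,
                                           dt=0.25, record_every=1))


@pytest.mark.parametrize(
    "kwargs", [dict(dt=0.0), dict(t_end=2010.0), dict(method="rk45")],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        IntegrationConfig(**kwargs)


def test_time_profiles_evaluate_correctly():
    """Step, ramp and decaying-pulse shock profiles drive an auxiliary."""
    m = StockFlowModel(
        stocks={"S": 0.0},
        flows=[Flow("in_", "stp + rmp + pls", sink="S")],
        shocks={
            "stp": step_profile(2012.0, 0.0, 1.0),
            "rmp": ramp_profile(2011.0, 2.0, 0.0, 10.0),
            "pls": decaying_pulse_profile(2012.0, 3.0, 0.1),
        },
    )
    traj = integrate(m, {}, IntegrationConfig(t_start=2011.0, t_end=2013.0,
                                              dt=0.25, record_every=1))
    i_2011_5 = traj.at_time(2011.5)
    # before the step/pulse: ramp contributes 2.5, others 1.0 + 0.0
    assert traj.flow("in_")[i_2011_5] == pytest.approx(1.0 + 2.5 + 0.0 + 0.0 + 1.0 - 1.0)
    i_2012_5 = traj.at_time(2012.5)
    expected = 1.0 + 7.5 + (1.0 + 2.0 * math.exp(-0.1 * 52 * 0.5))
    assert traj.flow("in_")[i_2012_5] == pytest.approx(expected, rel=1e-9)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    k1=st.floats(0.0, 2.0),
    k2=st.floats(0.0, 2.0),
    inflow=st.floats(0.0, 50.0),
)
def test_nonnegativity_property(k1, k2, inflow):
    """Recorded stocks never go negative for any admissible rate draw."""
    m = StockFlowModel(
        stocks={"A": 5.0, "B": 0.5},
        flows=[
            Flow("in_", "c", sink="A"),
            Flow("ab", "k1*A", source="A", sink="B"),
            Flow("out", "k2*B", source="B"),
        ],
    )
    traj = integrate(m, {"k1": k1, "k2": k2, "c": inflow},
                     IntegrationConfig(t_start=2011.0, t_end=2012.0, dt=0.5,
                                       record_every=1))
    assert np.all(traj.stock_values >= 0.0)


def test_dt_halving_changes_full_model_counters_under_one_percent(baseline_traj,
                                                                   default_params):
    """First-order step-size sensitivity of every cumulative counter."""
    from mhsd.model import run

    half = run(default_params, IntegrationConfig(dt=1.0 / 32.0, record_every=32))
    for name in baseline_traj.counter_names:
        c16, c32 = baseline_traj.counter(name), half.counter(name)
        assert abs(c32 - c16) / c16 < 0.01


def test_trajectory_tidy_export(baseline_traj):
    df = baseline_traj.to_frame()
    assert set(df.columns) == {"time", "variable", "value"}
    assert set(baseline_traj.stock_names) <= set(df["variable"].unique())
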