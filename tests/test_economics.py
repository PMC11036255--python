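"""Discounting, evaluation, ICER verdicts, sweeps, breakeven pricing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nafld_ce as nc
from nafld_ce.cohort import EventSummary
from nafld_ce.economics import (
    StrategyResult,
    breakeven_price,
    discount_factor,
    efficacy_sweep,
    frontier,
    icer,
    run_strategy,
)
from nafld_ce.parameters import set_param


def test_discount_factor_examples():
    assert discount_factor(0.03, 2) == pytest.approx(1 / 1.03**2)
    assert discount_factor(0.03, 2) == pytest.approx(0.942596, abs=1e-6)
    assert discount_factor(0.03, 0) == 1.0
    for t in range(10):
        assert discount_factor(0.0, t) == 1.0


@given(st.floats(min_value=0.001, max_value=0.2), st.integers(min_value=0, max_value=80))
def test_discount_factor_decreasing_in_cycle(rate, t):
    assert discount_factor(rate, t + 1) < discount_factor(rate, t) <= 1.0


def _stub(strategy, cost, qaly):
    ev = EventSummary(0, 0, 0, 0, 0, 0)
    return StrategyResult(strategy, 0, 0, qaly, qaly, cost, cost, 0, 0, ev, 0, 0)


def test_icer_quotient_of_printed_increments():
    pair = icer(_stub("a", 188_771.0, 1.58), _stub("b", 0.0, 0.0))
    assert pair.verdict == "icer"
    assert pair.icer == pytest.approx(188_771.0 / 1.58)
    assert pair.icer == pytest.approx(119_475.3, abs=0.5)


def test_icer_dominance_and_equality_verdicts():
    assert icer(_stub("a", -8_930.0, 0.199), _stub("b", 0, 0)).verdict == "dominant"
    assert icer(_stub("a", 8_930.0, -0.199), _stub("b", 0, 0)).verdict == "dominated"
    assert icer(_stub("a", 0.0, 0.0), _stub("b", 0, 0)).verdict == "equal"
    flagged = icer(_stub("a", 10.0, 0.0), _stub("b", 0, 0))
    assert flagged.verdict == "dominated" and flagged.equal_qaly


def test_evaluate_single_cycle_hand_arithmetic(two_state):
    """One cycle alive in a state with u=0.5, c=$100, r=0."""
    ps = two_state.copy()
    ps.demographics.max_age = ps.demographics.start_age + 1
    ps.econ.utility = dict(ps.econ.utility, early=0.5)
    ps.econ.cost = dict(ps.econ.cost, NAFL_F0=100.0)
    res = run_strategy(ps, "lifestyle")
    assert res.qaly_disc == pytest.approx(0.5)
    assert res.direct_medical_disc == pytest.approx(100.0)
    assert res.ly_disc == pytest.approx(1.0)


def test_unit_utilities_make_qaly_equal_ly(no_death):
    res = run_strategy(no_death, "lifestyle")
    assert res.qaly_disc == pytest.approx(res.ly_disc)
    assert res.qaly_undisc == pytest.approx(res.ly_undisc)


def test_total_cost_is_direct_plus_treatment(base_results):
    for res in base_results.values():
        assert res.total_cost_disc == pytest.approx(
            res.direct_medical_disc + res.treatment_disc, abs=0.01
        )
        assert res.ly_disc <= res.ly_undisc
        assert res.total_cost_disc <= res.total_cost_undisc


def test_zero_rates_equate_discounted_and_undiscounted(base_params):
    ps = base_params.copy()
    ps.econ.discount_rate_costs = 0.0
    ps.econ.discount_rate_outcomes = 0.0
    for strategy in nc.STRATEGIES:
        res = run_strategy(ps, strategy)
        assert res.ly_disc == pytest.approx(res.ly_undisc)
        assert res.qaly_disc == pytest.approx(res.qaly_undisc)
        assert res.total_cost_disc == pytest.approx(res.total_cost_undisc)


def test_delta_cost_affine_in_one_time_price(base_params):
    """Checked at three prices; slope = discounted administration count."""
    comp = run_strategy(base_params, "lifestyle")
    prices = (250_000.0, 500_000.0, 750_000.0)
    costs, admins = [], []
    for p in prices:
        ps = base_params.copy()
        set_param(ps, "econ.treatment.curative.one_time_price", p)
        res = run_strategy(ps, "curative")
        costs.append(res.total_cost_disc - comp.total_cost_disc)
        admins.append(res.admin_disc)
    assert admins[0] == pytest.approx(admins[1]) == pytest.approx(admins[2])
    slope1 = (costs[1] - costs[0]) / (prices[1] - prices[0])
    slope2 = (costs[2] - costs[1]) / (prices[2] - prices[1])
    assert slope1 == pytest.approx(slope2, rel=1e-9)
    assert slope1 == pytest.approx(admins[0], rel=1e-9)


def test_icer_strictly_increasing_in_price(base_params):
    values = []
    for p in (300_000.0, 500_000.0, 700_000.0):
        ps = base_params.copy()
        set_param(ps, "econ.treatment.curative.one_time_price", p)
        pair = icer(run_strategy(ps, "curative"), run_strategy(ps, "lifestyle"))
        values.append(pair.icer)
    assert values[0] < values[1] < values[2]


def _bisect_breakeven(params, strategy, comparator, wtp, tol=0.5):
    """Independent oracle: bisection on the fully re-evaluated ICER."""
    comp = run_strategy(params, comparator)
    lo, hi = 0.0, 5e6

    def f(price):
        ps = params.copy()
        set_param(ps, f"econ.treatment.{strategy}.one_time_price", price)
        res = run_strategy(ps, strategy)
        return (res.total_cost_disc - comp.total_cost_disc) / (
            res.qaly_disc - comp.qaly_disc
        ) - wtp

    assert f(lo) < 0 < f(hi)
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def test_breakeven_agrees_with_bisection_oracle(base_params):
    p_lin = breakeven_price(base_params, "curative", "lifestyle", 150_000.0)
    p_bis = _bisect_breakeven(base_params, "curative", "lifestyle", 150_000.0)
    assert p_lin == pytest.approx(p_bis, abs=1.0)


def test_breakeven_fixed_point_at_current_icer(base_params):
    pair = icer(
        run_strategy(base_params, "curative"), run_strategy(base_params, "lifestyle")
    )
    p = breakeven_price(base_params, "curative", "lifestyle", pair.icer)
    assert p == pytest.approx(500_000.0, abs=1.0)


def test_breakeven_requires_positive_qaly_gain(base_params):
    with pytest.raises(ValueError, match="breakeven"):
        breakeven_price(base_params, "lifestyle", "curative", 150_000.0)


def test_efficacy_sweep_monotone_and_null_effect(base_params):
    df = efficacy_sweep(base_params, "biologic", (0.0, 0.5, 0.7, 0.9), ("lifestyle",))
    dq = df.sort_values("efficacy")["delta_qaly"].to_numpy()
    assert (np.diff(dq) > 0).all()
    # zero efficacy: identical dynamics, cost differs only by the price ledger
    null = df[df["efficacy"] == 0.0].iloc[0]
    assert null["delta_qaly"] == pytest.approx(0.0, abs=1e-12)
    assert null["delta_cost"] > 0


def test_frontier_reports_increasing_icers(base_results):
    df = frontier(list(base_results.values()))
    assert df["cost_disc"].is_monotonic_increasing
    seq = df["icer_vs_previous"].dropna().to_numpy()
    assert (np.diff(seq) >= 0).all()
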