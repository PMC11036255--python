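"""DSA tornado, distribution calibration, PSA, CEAC and CE plane."""

import numpy as np
import pytest

import nafld_ce as nc
from nafld_ce.parameters import DsaParam
from nafld_ce.sensitivity import (
    PsaDraws,
    calibrate_distribution,
    ce_plane,
    ceac,
    one_way_dsa,
    run_psa,
    sample_parameter_set,
)

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------


def test_normal_calibration_moments():
    cal = calibrate_distribution(DsaParam("econ.discount_rate_costs", 0.015, 0.05, "normal"), 0.03)
    assert cal.dist.mean() == pytest.approx(0.03)
    assert cal.dist.std() == pytest.approx((0.05 - 0.015) / 3.92)
    assert cal.dist.std() == pytest.approx(0.008929, abs=1e-6)


def test_beta_calibration_method_of_moments():
    cal = calibrate_distribution(DsaParam("econ.utility.early", 0.68, 0.84, "beta"), 0.76)
    m, sd = 0.76, (0.84 - 0.68) / 3.92
    k = m * (1 - m) / sd**2 - 1  # moments oracle
    a, b = m * k, (1 - m) * k
    assert cal.dist.mean() == pytest.approx(m)
    assert cal.dist.std() == pytest.approx(sd, abs=1e-4)
    assert cal.dist.kwds["a"] == pytest.approx(a)
    assert cal.dist.kwds["b"] == pytest.approx(b)
    assert sd == pytest.approx(0.0408, abs=1e-4)


def test_gamma_and_lognormal_calibration_recover_mean():
    g = calibrate_distribution(DsaParam("econ.cost.DC", 74_459.37, 138_281.69, "gamma"), 106_370.53)
    assert g.dist.mean() == pytest.approx(106_370.53, rel=1e-9)
    ln = calibrate_distribution(
        DsaParam("econ.treatment.curative.one_time_price", 350_000.0, 650_000.0, "lognormal"),
        500_000.0,
    )
    assert ln.dist.mean() == pytest.approx(500_000.0, rel=1e-9)


def test_degenerate_bounds_give_point_mass():
    cal = calibrate_distribution(DsaParam("econ.utility.DC", 0.57, 0.57, "beta"), 0.57)
    rng = np.random.default_rng(0)
    assert cal.sample(rng) == 0.57


def test_infeasible_beta_falls_back_to_uniform():
    spec = DsaParam("efficacy.lifestyle_progression_mult_by_class.0", 0.8, 1.2, "beta")
    with pytest.warns(UserWarning, match="falling back to uniform"):
        cal = calibrate_distribution(spec, 1.0)
    assert cal.family == "uniform"
    rng = np.random.default_rng(1)
    draws = [cal.sample(rng) for _ in range(200)]
    assert all(0.8 <= x <= 1.2 for x in draws)


# --------------------------------------------------------------------------
# one-way DSA
# --------------------------------------------------------------------------


def test_zero_width_entry_for_degenerate_bounds(base_params):
    ps = base_params.copy()
    ps.dsa = [DsaParam("econ.utility.DC", 0.57, 0.57, "beta")]
    (entry,) = one_way_dsa(ps, "curative", "lifestyle")
    assert entry.width("delta_qaly") == pytest.approx(0.0, abs=1e-12)
    assert entry.width("delta_cost") == pytest.approx(0.0, abs=1e-9)


def test_outcome_discounting_monotone_in_rate(base_params):
    lo, hi = base_params.copy(), base_params.copy()
    lo.econ.discount_rate_outcomes = 0.015
    hi.econ.discount_rate_outcomes = 0.05
    assert (
        nc.run_strategy(lo, "lifestyle").qaly_disc
        > nc.run_strategy(hi, "lifestyle").qaly_disc
    )


def test_irrelevant_parameter_has_zero_width(base_params):
    """The curative price cannot move a lifestyle-vs-small-molecule comparison."""
    ps = base_params.copy()
    ps.dsa = [
        DsaParam("econ.treatment.curative.one_time_price", 350_000.0, 650_000.0, "lognormal")
    ]
    (entry,) = one_way_dsa(ps, "small_molecule", "lifestyle")
    assert entry.width("delta_qaly") == pytest.approx(0.0, abs=1e-12)
    assert entry.width("delta_cost") == pytest.approx(0.0, abs=1e-9)


def test_dominant_comparison_suppresses_icer(base_params):
    ps = base_params.copy()
    ps.dsa = ps.dsa[:3]
    entries = one_way_dsa(ps, "small_molecule", "lifestyle")
    assert all(e.icer_suppressed for e in entries)
    assert all(np.isnan(e.at_low["icer"]) for e in entries)


def test_biologic_effectiveness_among_widest_icer_bars(base_params):
    entries = one_way_dsa(base_params, "biologic", "lifestyle")
    ranked = [e.path for e in entries if not e.icer_suppressed]
    assert "efficacy.biologic_avoid_prob" in ranked[:6]


# --------------------------------------------------------------------------
# PSA
# --------------------------------------------------------------------------


def _point_mass_params(base_params):
    ps = base_params.copy()
    ps.dsa = [DsaParam(d.path, d.low, d.high, "point", d.cap) for d in ps.dsa]
    ps.psa.transition_kappa = None
    return ps


def test_point_mass_psa_equals_deterministic(base_params):
    ps = _point_mass_params(base_params)
    draws = run_psa(ps, n_iter=2, seed=3, strategies=("lifestyle", "curative"))
    det = {s: nc.run_strategy(ps, s) for s in ("lifestyle", "curative")}
    for k, s in enumerate(("lifestyle", "curative")):
        assert (draws.costs[:, k] == det[s].total_cost_disc).all()
        assert (draws.qalys[:, k] == det[s].qaly_disc).all()


def test_same_seed_reproduces_draws(base_params):
    a = run_psa(base_params, n_iter=8, seed=11, strategies=("lifestyle", "small_molecule"))
    b = run_psa(base_params, n_iter=8, seed=11, strategies=("lifestyle", "small_molecule"))
    np.testing.assert_array_equal(a.costs, b.costs)
    np.testing.assert_array_equal(a.qalys, b.qalys)
    c = run_psa(base_params, n_iter=8, seed=12, strategies=("lifestyle", "small_molecule"))
    assert not np.array_equal(a.costs, c.costs)


def test_sampled_sets_respect_supports(base_params):
    rng = np.random.default_rng(5)
    for _ in range(10):
        ps = sample_parameter_set(base_params, rng)
        for g, u in ps.econ.utility.items():
            assert 0.0 <= u <= 1.0, g
        for g, c in ps.econ.cost.items():
            assert c > 0.0, g
        assert 0.0 <= ps.efficacy.curative_cure_prob <= 1.0
        # shares rescale back to the configured total (0.9998 as printed)
        assert ps.efficacy.weightloss_shares.sum() == pytest.approx(
            base_params.efficacy.weightloss_shares.sum()
        )
        out = ps.transitions.groupby(
            [ps.transitions["subpop"].fillna(""), "from_state"]
        )["annual_probability"].sum()
        assert (out <= 1.0 + 1e-9).all()


# --------------------------------------------------------------------------
# CEAC / CE plane
# --------------------------------------------------------------------------


def _manual_draws(costs, qalys, strategies):
    return PsaDraws(
        seed=0,
        strategies=tuple(strategies),
        costs=np.asarray(costs, float),
        qalys=np.asarray(qalys, float),
    )


def test_ceac_partitions_to_one_and_cheapest_wins_at_zero_wtp(base_params):
    draws = run_psa(base_params, n_iter=12, seed=2)
    grid = (0.0, 50_000.0, 100_000.0, 150_000.0)
    df = ceac(draws, grid)
    sums = df.groupby("wtp")["probability"].sum()
    np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)
    at0 = df[df["wtp"] == 0.0].set_index("strategy")["probability"]
    cheapest = [
        draws.strategies[i] for i in np.argmin(draws.costs, axis=1)
    ]  # per-iteration cheapest
    for s in draws.strategies:
        assert at0[s] == pytest.approx(np.mean([c == s for c in cheapest]))


def test_ceac_tie_split_equal():
    draws = _manual_draws([[10.0, 10.0]], [[1.0, 1.0]], ["a", "b"])
    df = ceac(draws, (0.0, 1.0))
    assert (df["probability"] == 0.5).all()


def test_two_strategy_ceac_equals_icer_threshold_count():
    """All draws in the NE quadrant: acceptance = fraction with ICER < WTP."""
    rng = np.random.default_rng(4)
    n = 400
    dq = rng.uniform(0.5, 2.0, n)
    dc = rng.uniform(10_000.0, 300_000.0, n)
    costs = np.column_stack([np.zeros(n), dc])
    qalys = np.column_stack([np.zeros(n), dq])
    draws = _manual_draws(costs, qalys, ["comparator", "intervention"])
    for wtp in (50_000.0, 100_000.0, 150_000.0):
        df = ceac(draws, (wtp,)).set_index("strategy")["probability"]
        brute = np.mean(dc / dq < wtp)  # brute-force count oracle
        assert df["intervention"] == pytest.approx(brute)


def test_ce_plane_quadrants_and_threshold_flag():
    costs = np.array([[0.0, -5.0], [0.0, 5.0], [0.0, 5.0]])
    qalys = np.array([[0.0, 1.0], [0.0, -1.0], [0.0, 1.0]])
    draws = _manual_draws(costs, qalys, ["c", "i"])
    df = ce_plane(draws, "i", "c", wtp=2.0)
    assert list(df["quadrant"]) == ["SE/dominant", "NW/dominated", "NE"]
    assert list(df["below_wtp"]) == [True, False, False]


def test_empty_draws_give_empty_plane():
    draws = _manual_draws(np.empty((0, 2)), np.empty((0, 2)), ["c", "i"])
    assert len(ce_plane(draws, "i", "c")) == 0
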