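"""Disease matrix construction, strategy effects and mortality splits."""

import numpy as np
import pandas as pd
import pytest

import nafld_ce as nc
from nafld_ce.natural_history import (
    apply_strategy_effects,
    build_disease_matrix,
    cycle_matrix,
    death_split,
    lifestyle_mixture_effects,
    parse_transition_table,
)
from nafld_ce.parameters import MortalityModel
from nafld_ce.states import IDX, STRATEGIES


def test_lifestyle_mixture_matches_hand_computed_weighted_average(base_params):
    res, mult = lifestyle_mixture_effects(base_params.efficacy)
    # plain-arithmetic oracle on the printed class shares/effects
    expected_res = 0.8019 * 0.1024 + 0.1287 * 0.4237 + 0.0692 * 0.8965
    expected_mult = 0.8019 * 1.0 + 0.1287 * 0.9893 + 0.0692 * 0.4081
    assert res == pytest.approx(expected_res, abs=1e-9)
    assert mult == pytest.approx(expected_mult, abs=1e-9)
    assert res == pytest.approx(0.19868, abs=5e-6)
    assert mult == pytest.approx(0.95746, abs=5e-6)


def test_degenerate_mixture_picks_single_class(base_params):
    ps = base_params.copy()
    ps.efficacy.weightloss_shares = np.array([1.0, 0.0, 0.0])
    res, mult = lifestyle_mixture_effects(ps.efficacy)
    assert res == pytest.approx(0.1024)
    assert mult == pytest.approx(1.0)


def test_mixture_caps_resolution_classes_above_one(base_params):
    ps = base_params.copy()
    ps.efficacy.lifestyle_resolution_by_class = np.array([0.1, 0.5, 1.0759])
    res, _ = lifestyle_mixture_effects(ps.efficacy)
    shares = ps.efficacy.weightloss_shares
    assert res == pytest.approx(shares @ np.array([0.1, 0.5, 1.0]))


def test_small_molecule_scales_nash_progression(base_params):
    base = parse_transition_table(base_params.transitions)
    table = apply_strategy_effects(base, base_params, "small_molecule")
    for stage, row in base.nash_prog.items():
        for dest, p in row.items():
            assert table.nash_prog[stage][dest] == pytest.approx(0.4081 * p)
    assert table.f3_to["F4"] == pytest.approx(0.4081 * base.f3_to["F4"])
    assert all(v == pytest.approx(0.527) for v in table.switch_nash_to_nafl.values())


def test_biologic_with_zero_effect_equals_lifestyle(base_params):
    ps = base_params.copy()
    ps.efficacy.biologic_avoid_prob = 0.0
    D_bio = build_disease_matrix(ps, "biologic")
    D_life = build_disease_matrix(ps, "lifestyle")
    np.testing.assert_allclose(D_bio, D_life, atol=1e-15)


def test_biologic_scales_advanced_progression(base_params):
    base = parse_transition_table(base_params.transitions)
    life = apply_strategy_effects(base, base_params, "lifestyle")
    bio = apply_strategy_effects(base, base_params, "biologic")
    keep = 1.0 - base_params.efficacy.biologic_avoid_prob
    for dest in ("F4", "DC", "HCC"):
        assert bio.f3_to[dest] == pytest.approx(keep * life.f3_to[dest])
    for dest in ("DC", "HCC"):
        assert bio.f4_to[dest] == pytest.approx(keep * life.f4_to[dest])


def test_full_cure_moves_all_f4_entrants_absent_death(base_params):
    ps = base_params.copy()
    ps.efficacy.curative_cure_prob = 1.0
    D = build_disease_matrix(ps, "curative")
    assert D[IDX["F4_Y1"], IDX["NAFL_F0"]] == pytest.approx(1.0)
    assert D[IDX["F4_Y1"], IDX["F4_LATER"]] == 0.0


def test_switch_composes_with_destination_fibrosis_row(base_params):
    """NAFL_F0 -> NASH_F1 = switch(F0) * within-NASH prog(F0->F1)."""
    ps = base_params.copy()
    ps.transitions = pd.DataFrame(
        [
            ("F0", "NASH", 0.2, "NAFL"),
            ("F0", "F1", 0.5, "NASH"),
        ],
        columns=["from_state", "to_state", "annual_probability", "subpop"],
    )
    # null the lifestyle mixture so the base table passes through unchanged
    ps.efficacy.weightloss_shares = np.array([1.0, 0.0, 0.0])
    ps.efficacy.lifestyle_resolution_by_class = np.array([0.0, 0.0, 0.0])
    ps.efficacy.lifestyle_progression_mult_by_class = np.array([1.0, 1.0, 1.0])
    D = build_disease_matrix(ps, "lifestyle")
    assert D[IDX["NAFL_F0"], IDX["NASH_F1"]] == pytest.approx(0.2 * 0.5)
    assert D[IDX["NAFL_F0"], IDX["NASH_F0"]] == pytest.approx(0.2 * 0.5)
    assert D[IDX["NAFL_F0"], IDX["NAFL_F0"]] == pytest.approx(0.8)


def test_f4_y1_is_a_tunnel(base_params):
    for strategy in STRATEGIES:
        D = build_disease_matrix(base_params, strategy)
        assert D[IDX["F4_Y1"], IDX["F4_Y1"]] == 0.0
        assert D[IDX["LT_DC"], IDX["PLT"]] == 1.0
        assert D[IDX["LT_HCC"], IDX["PLT"]] == 1.0


@pytest.mark.parametrize("strategy", STRATEGIES)
@pytest.mark.parametrize("sex", ["female", "male"])
def test_cycle_matrix_row_stochastic_base_case(base_params, strategy, sex):
    for age in (47.7, 60.0, 85.0, 105.0):
        M = cycle_matrix(base_params, strategy, age, sex)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert (M >= 0).all()
        assert M[IDX["DEATH"], IDX["DEATH"]] == 1.0


def _toy_mortality(base_params, q=0.01, cv=0.4, liver=0.1, rr_dc=3.0):
    ps = base_params.copy()
    ages = np.arange(0, 111)
    ps.mortality = MortalityModel(
        life_table=pd.concat(
            [
                pd.DataFrame(
                    {"age": ages, "sex": s, "q": q, "cv_frac": cv, "liver_frac": liver}
                )
                for s in ("female", "male")
            ],
            ignore_index=True,
        ),
        liver_rr={"F3": 1.0, "F4": 1.0, "DC": rr_dc, "HCC": 1.0, "LT": 1.0, "PLT": 1.0},
        cv_hr={"F0_F2": 1.0, "F3": 1.0, "F4": 1.0},
    )
    return ps


def test_death_split_toy_relative_risk(base_params):
    ps = _toy_mortality(base_params)
    cv, liver, other = death_split(ps, "DC", 50.0, "female")
    assert liver == pytest.approx(0.1 * 0.01 * 3.0)  # liver_frac * q * RR
    assert cv == pytest.approx(0.4 * 0.01)
    assert other == pytest.approx(0.5 * 0.01)


def test_death_split_null_adjustment_equals_life_table_fractions(base_params):
    ps = _toy_mortality(base_params, rr_dc=1.0)
    for state in ("NAFL_F0", "F3", "DC"):
        cv, liver, other = death_split(ps, state, 60.0, "male")
        total = cv + liver + other
        assert total == pytest.approx(0.01)
        assert cv / total == pytest.approx(0.4)
        assert liver / total == pytest.approx(0.1)


def test_doubling_cv_hazard_doubles_cv_component(base_params):
    ps = _toy_mortality(base_params)
    cv1, _, _ = death_split(ps, "F4_LATER", 60.0, "female")
    ps.mortality.cv_hr["F4"] = 2.0
    cv2, _, _ = death_split(ps, "F4_LATER", 60.0, "female")
    assert cv2 == pytest.approx(2.0 * cv1)


@pytest.mark.parametrize(
    "strategy, path, target",
    [
        ("biologic", "biologic_avoid_prob", ("F3", "DC")),
        ("biologic", "biologic_avoid_prob", ("F4_LATER", "HCC")),
    ],
)
def test_increasing_biologic_efficacy_never_increases_progression(
    base_params, strategy, path, target
):
    probs = []
    for e in (0.0, 0.3, 0.6, 0.9):
        ps = base_params.copy()
        setattr(ps.efficacy, path, e)
        D = build_disease_matrix(ps, strategy)
        probs.append(D[IDX[target[0]], IDX[target[1]]])
    assert all(b <= a + 1e-15 for a, b in zip(probs, probs[1:]))


def test_increasing_cure_probability_never_increases_f4_persistence(base_params):
    stay = []
    for e in (0.0, 0.3, 0.6, 0.9):
        ps = base_params.copy()
        ps.efficacy.curative_cure_prob = e
        D = build_disease_matrix(ps, "curative")
        stay.append(D[IDX["F4_Y1"], IDX["F4_LATER"]])
    assert all(b <= a + 1e-15 for a, b in zip(stay, stay[1:]))


def test_nulled_effects_collapse_to_shared_natural_history(base_params):
    """With all treatment effects removed the four strategies share one matrix."""
    ps = base_params.copy()
    base_switch = 0.06  # the base NASH->NAFL switching probability
    ps.efficacy.weightloss_shares = np.array([1.0, 0.0, 0.0])
    ps.efficacy.lifestyle_resolution_by_class = np.full(3, base_switch)
    ps.efficacy.lifestyle_progression_mult_by_class = np.ones(3)
    ps.efficacy.smallmol_resolution = base_switch
    ps.efficacy.smallmol_progression_mult = 1.0
    ps.efficacy.biologic_avoid_prob = 0.0
    ps.efficacy.curative_cure_prob = 0.0
    mats = [build_disease_matrix(ps, s) for s in STRATEGIES]
    for M in mats[1:]:
        np.testing.assert_allclose(M, mats[0], atol=1e-12)


def test_row_stochastic_on_random_synthetic_sets():
    for seed in range(50):
        ps = nc.generate(seed)
        strategy = STRATEGIES[seed % 4]
        M = cycle_matrix(ps, strategy, ps.demographics.start_age + (seed % 40), "male")
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert (M >= 0).all()
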