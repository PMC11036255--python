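"""Synthetic parameter sets and degenerate fixtures.

:func:`generate` builds a complete, validated :class:`ParameterSet` with
the statistical structure of the real inputs — net-progressive disease
dynamics, a Gompertz-like background mortality curve, costs increasing and
utilities decreasing with severity, probability-scale parameters in [0,1] —
without reproducing any published table.  It exists so that every stage of
the pipeline is testable on randomised inputs, and as the documented
stand-in for the unpublished per-transition appendix data.

:func:`degenerate_fixture` returns minimal closed-form-checkable sets
(no mortality, a single geometric transition, a single F3->DC path) used by
the cohort-engine and economics oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    Demographics,
    DsaParam,
    EconParams,
    EfficacyParams,
    MortalityModel,
    ParameterSet,
    PsaSettings,
    TreatmentCost,
    cap_probability,
    validate,
)
from .states import COST_GROUP, CV_HR_GROUP, LIVER_RR_GROUP, UTILITY_GROUP

__all__ = ["SyntheticSpec", "generate", "degenerate_fixture"]

_PRE_CIRRHOSIS = ("NAFL_F0", "NAFL_F1", "NAFL_F2", "NASH_F0", "NASH_F1", "NASH_F2", "F3")


@dataclass
class SyntheticSpec:
    """Ranges for the random generator (annual scales).

    Defaults emulate the magnitudes of the real inputs: fibrosis
    progression 0.005-0.25/yr with NASH faster than NAFL, a Gompertz
    mortality curve q(age) = min(1, a*exp(b*age)) with a in [1e-5, 1e-3]
    and b in [0.07, 0.11], costs rising and utilities falling with
    severity.
    """

    seed: int = 0
    progression_range: tuple[float, float] = (0.005, 0.25)
    gompertz_a_range: tuple[float, float] = (1e-5, 1e-3)
    gompertz_b_range: tuple[float, float] = (0.07, 0.11)
    max_age: float = 110.0


def _life_table(rng: np.random.Generator, spec: SyntheticSpec) -> pd.DataFrame:
    a_f = rng.uniform(*spec.gompertz_a_range)
    a_m = a_f * rng.uniform(1.0, 2.0)  # male excess
    b = rng.uniform(*spec.gompertz_b_range)
    cv0 = rng.uniform(0.2, 0.35)
    liver0 = rng.uniform(0.01, 0.03)
    ages = np.arange(0, int(spec.max_age) + 1)
    rows = []
    for sex, a in (("female", a_f), ("male", a_m)):
        q = np.minimum(1.0, a * np.exp(b * ages))
        cv = np.minimum(0.45, cv0 + 0.002 * ages)
        liver = np.full_like(q, liver0)
        rows.append(
            pd.DataFrame(
                {"age": ages, "sex": sex, "q": q, "cv_frac": cv, "liver_frac": liver}
            )
        )
    return pd.concat(rows, ignore_index=True)


def _transitions(rng: np.random.Generator, spec: SyntheticSpec) -> pd.DataFrame:
    lo, hi = spec.progression_range
    u = lambda a, b: float(rng.uniform(a, b))
    nafl = [u(lo, min(hi, 0.08)) for _ in range(3)]
    nash = [min(hi, p * rng.uniform(1.5, 2.5)) for p in nafl]  # NASH progresses faster
    direct_f4 = u(0.001, 0.006)
    sw_fn = u(0.05, 0.15)
    sw_nf = u(0.02, min(0.1, sw_fn))  # net-progressive: regression below progression
    rows = [
        ("F0", "F1", nafl[0], "NAFL"),
        ("F1", "F2", nafl[1], "NAFL"),
        ("F2", "F3", nafl[2], "NAFL"),
        ("F0", "F4", direct_f4, "NAFL"),
        ("F1", "F4", direct_f4, "NAFL"),
        ("F0", "F1", nash[0], "NASH"),
        ("F1", "F2", nash[1], "NASH"),
        ("F2", "F3", nash[2], "NASH"),
        ("F2", "F4", u(0.005, 0.03), "NASH"),
        ("F0", "NASH", sw_fn, "NAFL"),
        ("F1", "NASH", sw_fn, "NAFL"),
        ("F2", "NASH", sw_fn, "NAFL"),
        ("F0", "NAFL", sw_nf, "NASH"),
        ("F1", "NAFL", sw_nf, "NASH"),
        ("F2", "NAFL", sw_nf, "NASH"),
        ("F3", "F4", u(0.06, min(hi, 0.2)), ""),
        ("F3", "DC", u(0.01, 0.04), ""),
        ("F3", "HCC", u(0.004, 0.02), ""),
        ("F4", "DC", u(0.03, 0.1), ""),
        ("F4", "HCC", u(0.01, 0.03), ""),
        ("DC", "HCC", u(0.01, 0.05), ""),
        ("DC", "LT", u(0.002, 0.02), ""),
        ("HCC", "LT", u(0.002, 0.02), ""),
    ]
    return pd.DataFrame(rows, columns=["from_state", "to_state", "annual_probability", "subpop"])


def generate(spec: SyntheticSpec | int = 0) -> ParameterSet:
    """Generate a complete validated ParameterSet from a seed or spec."""
    if isinstance(spec, (int, np.integer)):
        spec = SyntheticSpec(seed=int(spec))
    rng = np.random.default_rng(spec.seed)

    transitions = _transitions(rng, spec)
    life_table = _life_table(rng, spec)

    u_early = rng.uniform(0.70, 0.82)
    utility = {"early": u_early}
    utility["F3"] = u_early - rng.uniform(0.02, 0.06)
    utility["F4"] = utility["F3"] - rng.uniform(0.03, 0.08)
    utility["DC"] = utility["F4"] - rng.uniform(0.05, 0.10)
    utility["HCC"] = utility["DC"] - rng.uniform(0.03, 0.08)
    utility["LT"] = float(np.clip(rng.uniform(utility["F4"], utility["F3"]), 0, 1))

    c0 = rng.uniform(2000, 4000)
    cost = {
        "NAFL_F0": c0,
        "NAFL_F1": c0 * 2,
        "NAFL_F2": c0 * 3,
        "NASH_F0": c0 * rng.uniform(1.3, 1.6),
        "NASH_F1": c0 * rng.uniform(2.6, 3.2),
        "NASH_F2": c0 * rng.uniform(3.9, 4.8),
        "F3": rng.uniform(12_000, 24_000),
        "F4": rng.uniform(20_000, 40_000),
        "DC": rng.uniform(70_000, 140_000),
        "HCC": rng.uniform(150_000, 280_000),
        "LT_Y1": rng.uniform(150_000, 280_000),
        "PLT": rng.uniform(35_000, 70_000),
    }

    price = float(np.exp(rng.normal(np.log(5e5), 0.2)))  # lognormal-like price
    treatment = {
        "lifestyle": TreatmentCost(rng.uniform(1500, 2500), 0.0, _PRE_CIRRHOSIS),
        "small_molecule": TreatmentCost(rng.uniform(1800, 3000), 0.0, _PRE_CIRRHOSIS),
        "biologic": TreatmentCost(rng.uniform(1500, 2500), price, _PRE_CIRRHOSIS),
        "curative": TreatmentCost(rng.uniform(1500, 2500), price, _PRE_CIRRHOSIS),
    }

    shares = rng.dirichlet([8.0, 1.5, 1.0])
    res_cls = np.sort(rng.uniform(0.05, 0.95, size=3))  # resolution rises with weight loss
    mult_cls = np.sort(rng.uniform(0.3, 1.1, size=3))[::-1].copy()

    efficacy = EfficacyParams(
        weightloss_shares=shares,
        lifestyle_resolution_by_class=res_cls,
        lifestyle_progression_mult_by_class=mult_cls,
        smallmol_resolution=rng.uniform(0.4, 0.65),
        smallmol_progression_mult=rng.uniform(0.3, 0.5),
        biologic_avoid_prob=rng.uniform(0.5, 0.9),
        curative_cure_prob=rng.uniform(0.5, 0.9),
    )

    rr_f3 = rng.uniform(2, 30)
    rr_f4 = rng.uniform(30, 100)
    mortality = MortalityModel(
        life_table=life_table,
        liver_rr={
            "F3": rr_f3,
            "F4": rr_f4,
            "DC": rng.uniform(300, 1200),
            "HCC": rng.uniform(1500, 3500),
            "LT": rng.uniform(600, 1500),
            "PLT": rng.uniform(50, 250),
        },
        cv_hr={
            "F0_F2": rng.uniform(1.0, 1.5),
            "F3": rng.uniform(1.2, 2.0),
            "F4": rng.uniform(1.5, 3.0),
        },
    )

    ps = ParameterSet(
        demographics=Demographics(
            start_age=rng.uniform(40, 55),
            female_fraction=rng.uniform(0.45, 0.62),
            max_age=spec.max_age,
        ),
        econ=EconParams(
            discount_rate_costs=0.03,
            discount_rate_outcomes=0.03,
            utility=utility,
            cost=cost,
            age_utility=None,
            treatment=treatment,
        ),
        efficacy=efficacy,
        transitions=transitions,
        mortality=mortality,
        psa=PsaSettings(n_iter=1000, transition_kappa=100.0),
    )
    ps.dsa = _dsa_entries(ps)
    validate(ps)
    return ps


def _dsa_entries(ps: ParameterSet) -> list[DsaParam]:
    """±25% bounds (capped on the probability scale) per parameter class,
    with distribution families matching the real inputs' assignments."""
    entries: list[DsaParam] = []

    def add(path, base, family, cap=False):
        low, high = base * 0.75, base * 1.25
        if cap:
            high = cap_probability(high)
            low = min(low, high)
        entries.append(DsaParam(path=path, low=low, high=high, family=family, cap=cap))

    add("econ.discount_rate_costs", ps.econ.discount_rate_costs, "normal")
    add("econ.discount_rate_outcomes", ps.econ.discount_rate_outcomes, "normal")
    add("demographics.female_fraction", ps.demographics.female_fraction, "beta", cap=True)
    for g in sorted(set(UTILITY_GROUP.values())):
        add(f"econ.utility.{g}", ps.econ.utility[g], "beta", cap=True)
    for g in sorted(set(COST_GROUP.values())):
        add(f"econ.cost.{g}", ps.econ.cost[g], "gamma")
    for name in ("lifestyle", "small_molecule"):
        add(f"econ.treatment.{name}.annual", ps.econ.treatment[name].annual, "lognormal")
    for name in ("biologic", "curative"):
        add(
            f"econ.treatment.{name}.one_time_price",
            ps.econ.treatment[name].one_time_price,
            "lognormal",
        )
    for i in range(3):
        add(
            f"efficacy.lifestyle_resolution_by_class.{i}",
            float(ps.efficacy.lifestyle_resolution_by_class[i]),
            "beta",
            cap=True,
        )
    add("efficacy.smallmol_resolution", ps.efficacy.smallmol_resolution, "beta", cap=True)
    add("efficacy.biologic_avoid_prob", ps.efficacy.biologic_avoid_prob, "beta", cap=True)
    add("efficacy.curative_cure_prob", ps.efficacy.curative_cure_prob, "beta", cap=True)
    return entries


# --------------------------------------------------------------------------
# degenerate fixtures
# --------------------------------------------------------------------------

_FIXTURE_KINDS = ("no_death", "two_state", "single_path")


def degenerate_fixture(kind: str) -> ParameterSet:
    """Minimal closed-form fixtures.

    * ``no_death``   — base-like disease dynamics, zero mortality.
    * ``two_state``  — only NAFL F0 -> F1 at 0.1/yr, no death: geometric
      occupancy 0.9^t of the start state.
    * ``single_path``— only F3 -> DC at 0.1/yr, no death: cumulative DC
      incidence after n cycles is 1 - 0.9^n.
    """
    if kind not in _FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {_FIXTURE_KINDS}")

    ages = np.arange(0, 111)
    life = pd.concat(
        [
            pd.DataFrame(
                {"age": ages, "sex": sex, "q": 0.0, "cv_frac": 0.4, "liver_frac": 0.1}
            )
            for sex in ("female", "male")
        ],
        ignore_index=True,
    )

    cols = ["from_state", "to_state", "annual_probability", "subpop"]
    if kind == "two_state":
        rows = [("F0", "F1", 0.1, "NAFL")]
    elif kind == "single_path":
        rows = [("F3", "DC", 0.1, "")]
    else:
        rows = [
            ("F0", "F1", 0.05, "NAFL"),
            ("F0", "F1", 0.1, "NASH"),
            ("F0", "NASH", 0.1, "NAFL"),
            ("F0", "NAFL", 0.05, "NASH"),
            ("F3", "F4", 0.1, ""),
            ("F4", "DC", 0.05, ""),
        ]
    transitions = pd.DataFrame(rows, columns=cols)

    utility = {"early": 1.0, "F3": 1.0, "F4": 1.0, "DC": 1.0, "HCC": 1.0, "LT": 1.0}
    cost = {g: 0.0 for g in set(COST_GROUP.values())}
    treatment = {
        name: TreatmentCost(0.0, 0.0, _PRE_CIRRHOSIS)
        for name in ("lifestyle", "small_molecule", "biologic", "curative")
    }
    # null treatment effects: every strategy reduces to the shared dynamics
    efficacy = EfficacyParams(
        weightloss_shares=np.array([1.0, 0.0, 0.0]),
        lifestyle_resolution_by_class=np.array([0.05 if kind == "no_death" else 0.0] * 3),
        lifestyle_progression_mult_by_class=np.array([1.0, 1.0, 1.0]),
        smallmol_resolution=0.05 if kind == "no_death" else 0.0,
        smallmol_progression_mult=1.0,
        biologic_avoid_prob=0.0,
        curative_cure_prob=0.0,
    )
    mortality = MortalityModel(
        life_table=life,
        liver_rr={g: 1.0 for g in set(LIVER_RR_GROUP.values())},
        cv_hr={g: 1.0 for g in set(CV_HR_GROUP.values())},
    )
    ps = ParameterSet(
        demographics=Demographics(start_age=50.0, female_fraction=0.5, max_age=110.0),
        econ=EconParams(0.0, 0.0, utility, cost, None, treatment),
        efficacy=efficacy,
        transitions=transitions,
        mortality=mortality,
        psa=PsaSettings(n_iter=10, transition_kappa=None),
    )
    validate(ps)
    return ps
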