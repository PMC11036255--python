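"""Per-cycle transition dynamics: disease progression, treatment effects,
and three-cause mortality.

The annual cycle is resolved as two competing steps: death first (a
state/age/sex-specific probability combining background mortality with a
cardiovascular hazard ratio and a liver-related relative risk), then disease
transitions among survivors.  The disease part is age-independent, so each
strategy has a single 15x15 disease matrix ``D``; the full cycle matrix at a
given age/sex is ``diag(1-d) @ D`` with the death mass sent to the absorbing
state.

NAFL<->NASH switching is composed multiplicatively with the within-group
fibrosis dynamics: a patient switching groups at stage Fx lands in the
destination group distributed according to that group's own stage-transition
row from Fx (e.g. NAFL_F0 -> NASH_F1 = switch(F0) * prog_NASH(F0->F1)).

Treatment effects:

* lifestyle — NASH->NAFL resolution and a fibrosis-progression multiplier,
  each a weight-loss-class mixture; applied to NASH stage progression and
  F3->F4.  All strategies sit on top of this standard-of-care background.
* small molecule — replaces the lifestyle mixture with its own resolution
  probability and progression multiplier.
* biologic — scales progression out of F3 (to F4/DC/HCC) and out of F4
  (to DC/HCC) by ``1 - e_B``.
* curative — on entry into first-year cirrhosis, cures with probability
  ``e_C`` (returns to NAFL F0); the remainder follows F4 natural history.
  Re-entry into first-year cirrhosis triggers retreatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import EfficacyParams, ParameterSet, cap_probability
from .states import (
    CV_HR_GROUP,
    IDX,
    LIVER_RR_GROUP,
    N_STATES,
    STATES,
    STRATEGIES,
)

__all__ = [
    "Strategy",
    "lifestyle_mixture_effects",
    "parse_transition_table",
    "build_disease_matrix",
    "mortality_components",
    "death_split",
    "cycle_matrix",
]

_EARLY = ("F0", "F1", "F2")


@dataclass(frozen=True)
class Strategy:
    """A named treatment behaviour with its resolved cost schedule."""

    name: str
    annual_cost: float
    one_time_price: float
    eligible_states: tuple[str, ...]

    @classmethod
    def from_params(cls, params: ParameterSet, name: str) -> "Strategy":
        if name not in STRATEGIES:
            raise ValueError(f"unknown strategy {name!r}; expected one of {STRATEGIES}")
        tc = params.econ.treatment[name]
        return cls(
            name=name,
            annual_cost=tc.annual,
            one_time_price=tc.one_time_price,
            eligible_states=tuple(tc.eligible_states),
        )


def lifestyle_mixture_effects(eff: EfficacyParams) -> tuple[float, float]:
    """Share-weighted lifestyle effect: (resolution prob, progression mult).

    Resolution probabilities are capped at 1 per class before averaging
    (upper uncertainty bounds can exceed the probability scale).
    """
    shares = np.asarray(eff.weightloss_shares, float)
    if abs(shares.sum() - 1.0) > 1e-3:
        raise ValueError("weight-loss shares must sum to 1")
    res = np.array([cap_probability(r) for r in eff.lifestyle_resolution_by_class])
    mult = np.asarray(eff.lifestyle_progression_mult_by_class, float)
    return float(shares @ res), float(shares @ mult)


# --------------------------------------------------------------------------
# transition-table parsing and strategy application
# --------------------------------------------------------------------------


@dataclass
class DiseaseTransitionTable:
    """Parsed annual disease probabilities (no mortality).

    Stage keys are 'F0'..'F2'; within-group rows map stage -> destination
    stage among {'F1','F2','F3','F4'}; ``switch`` maps stage -> probability
    of crossing between NAFL and NASH that year.
    """

    nafl_prog: dict[str, dict[str, float]]
    nash_prog: dict[str, dict[str, float]]
    switch_nafl_to_nash: dict[str, float]
    switch_nash_to_nafl: dict[str, float]
    f3_to: dict[str, float]  # F4, DC, HCC
    f4_to: dict[str, float]  # DC, HCC
    dc_to: dict[str, float]  # HCC, LT
    hcc_to_lt: float


def parse_transition_table(df: pd.DataFrame) -> DiseaseTransitionTable:
    nafl_prog: dict[str, dict[str, float]] = {s: {} for s in _EARLY}
    nash_prog: dict[str, dict[str, float]] = {s: {} for s in _EARLY}
    sw_fn: dict[str, float] = {s: 0.0 for s in _EARLY}
    sw_nf: dict[str, float] = {s: 0.0 for s in _EARLY}
    f3_to = {"F4": 0.0, "DC": 0.0, "HCC": 0.0}
    f4_to = {"DC": 0.0, "HCC": 0.0}
    dc_to = {"HCC": 0.0, "LT": 0.0}
    hcc_to_lt = 0.0
    for row in df.itertuples(index=False):
        sub = "" if pd.isna(row.subpop) else str(row.subpop)
        frm, to, p = str(row.from_state), str(row.to_state), float(row.annual_probability)
        if sub == "NAFL":
            if to == "NASH":
                sw_fn[frm] = p
            else:
                nafl_prog[frm][to] = p
        elif sub == "NASH":
            if to == "NAFL":
                sw_nf[frm] = p
            else:
                nash_prog[frm][to] = p
        elif frm == "F3":
            f3_to[to] = p
        elif frm == "F4":
            f4_to[to] = p
        elif frm == "DC":
            dc_to[to] = p
        elif frm == "HCC" and to == "LT":
            hcc_to_lt = p
        else:
            raise ValueError(f"unrecognized transition row {sub}:{frm}->{to}")
    return DiseaseTransitionTable(
        nafl_prog, nash_prog, sw_fn, sw_nf, f3_to, f4_to, dc_to, hcc_to_lt
    )


_PROGRESSION_DESTS = ("F1", "F2", "F3", "F4")


def _scaled(prog: dict[str, dict[str, float]], mult: float) -> dict[str, dict[str, float]]:
    return {
        stage: {dest: p * mult for dest, p in row.items()} for stage, row in prog.items()
    }


def apply_strategy_effects(
    table: DiseaseTransitionTable, params: ParameterSet, strategy: str
) -> DiseaseTransitionTable:
    """Return the strategy-specific disease table.

    With all treatment effects nulled (unit multipliers, zero efficacy and
    resolution equal to the base switch probabilities) every strategy
    reduces to the shared natural history.
    """
    eff = params.efficacy
    if strategy == "small_molecule":
        resolution = cap_probability(eff.smallmol_resolution)
        mult = eff.smallmol_progression_mult
    else:
        resolution, mult = lifestyle_mixture_effects(eff)

    nash_prog = _scaled(table.nash_prog, mult)
    f3_to = dict(table.f3_to)
    f3_to["F4"] = f3_to["F4"] * mult
    f4_to = dict(table.f4_to)

    if strategy == "biologic":
        keep = 1.0 - cap_probability(eff.biologic_avoid_prob)
        f3_to = {dest: p * keep for dest, p in f3_to.items()}
        f4_to = {dest: p * keep for dest, p in f4_to.items()}

    out = DiseaseTransitionTable(
        nafl_prog={s: dict(r) for s, r in table.nafl_prog.items()},
        nash_prog=nash_prog,
        switch_nafl_to_nash=dict(table.switch_nafl_to_nash),
        switch_nash_to_nafl={s: resolution for s in _EARLY},
        f3_to=f3_to,
        f4_to=f4_to,
        dc_to=dict(table.dc_to),
        hcc_to_lt=table.hcc_to_lt,
    )
    _check_rows(out)
    return out


def _check_rows(t: DiseaseTransitionTable) -> None:
    for stage in _EARLY:
        for prog, sw, label in (
            (t.nafl_prog, t.switch_nafl_to_nash, "NAFL"),
            (t.nash_prog, t.switch_nash_to_nafl, "NASH"),
        ):
            internal = sum(prog[stage].values())
            if internal > 1.0 + 1e-9 or sw[stage] > 1.0 + 1e-9:
                raise ValueError(f"{label} {stage} outflow exceeds 1 after effects")
    for row, label in ((t.f3_to, "F3"), (t.f4_to, "F4"), (t.dc_to, "DC")):
        if sum(row.values()) > 1.0 + 1e-9:
            raise ValueError(f"{label} outflow exceeds 1 after effects")


def _dest_index(dest: str, group: str) -> int:
    """Map a within-group destination stage to a model state index."""
    if dest in ("F0", "F1", "F2"):
        return IDX[f"{group}_{dest}"]
    if dest == "F3":
        return IDX["F3"]
    if dest == "F4":
        return IDX["F4_Y1"]
    raise ValueError(dest)


def build_disease_matrix(params: ParameterSet, strategy: str) -> np.ndarray:
    """15x15 row-stochastic disease matrix (mortality excluded)."""
    table = apply_strategy_effects(parse_transition_table(params.transitions), params, strategy)
    D = np.zeros((N_STATES, N_STATES))

    for group, other, prog_self, prog_other, switch in (
        ("NAFL", "NASH", table.nafl_prog, table.nash_prog, table.switch_nafl_to_nash),
        ("NASH", "NAFL", table.nash_prog, table.nafl_prog, table.switch_nash_to_nafl),
    ):
        for stage in _EARLY:
            i = IDX[f"{group}_{stage}"]
            s = switch[stage]
            # switching mass: distributed per the destination group's own
            # stage-transition row from this stage
            row_other = prog_other[stage]
            moved = 0.0
            for dest, p in row_other.items():
                D[i, _dest_index(dest, other)] += s * p
                moved += s * p
            D[i, IDX[f"{other}_{stage}"]] += s - moved
            # non-switching mass follows the own-group row
            row_self = prog_self[stage]
            stayed = 1.0 - s
            for dest, p in row_self.items():
                D[i, _dest_index(dest, group)] += (1.0 - s) * p
                stayed -= (1.0 - s) * p
            D[i, i] += stayed

    i = IDX["F3"]
    D[i, IDX["F4_Y1"]] = table.f3_to["F4"]
    D[i, IDX["DC"]] = table.f3_to["DC"]
    D[i, IDX["HCC"]] = table.f3_to["HCC"]
    D[i, i] = 1.0 - sum(table.f3_to.values())

    # first-year cirrhosis: one-cycle tunnel; survivors who neither cure nor
    # decompensate move on to the established-cirrhosis state
    i = IDX["F4_Y1"]
    cure = cap_probability(params.efficacy.curative_cure_prob) if strategy == "curative" else 0.0
    D[i, IDX["NAFL_F0"]] = cure
    D[i, IDX["DC"]] = (1.0 - cure) * table.f4_to["DC"]
    D[i, IDX["HCC"]] = (1.0 - cure) * table.f4_to["HCC"]
    D[i, IDX["F4_LATER"]] = (1.0 - cure) * (1.0 - table.f4_to["DC"] - table.f4_to["HCC"])

    i = IDX["F4_LATER"]
    D[i, IDX["DC"]] = table.f4_to["DC"]
    D[i, IDX["HCC"]] = table.f4_to["HCC"]
    D[i, i] = 1.0 - table.f4_to["DC"] - table.f4_to["HCC"]

    i = IDX["DC"]
    D[i, IDX["HCC"]] = table.dc_to["HCC"]
    D[i, IDX["LT_DC"]] = table.dc_to["LT"]
    D[i, i] = 1.0 - table.dc_to["HCC"] - table.dc_to["LT"]

    i = IDX["HCC"]
    D[i, IDX["LT_HCC"]] = table.hcc_to_lt
    D[i, i] = 1.0 - table.hcc_to_lt

    D[IDX["LT_DC"], IDX["PLT"]] = 1.0
    D[IDX["LT_HCC"], IDX["PLT"]] = 1.0
    D[IDX["PLT"], IDX["PLT"]] = 1.0
    D[IDX["DEATH"], IDX["DEATH"]] = 1.0

    if (D < -1e-15).any():
        raise ValueError("negative entry in disease matrix (invalid inputs)")
    np.clip(D, 0.0, None, out=D)
    sums = D.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-12):
        raise ValueError(f"disease matrix rows do not sum to 1: {sums}")
    return D


# --------------------------------------------------------------------------
# mortality
# --------------------------------------------------------------------------


def _life_table_arrays(params: ParameterSet, sex: str):
    lt = params.mortality.life_table
    sub = lt[lt["sex"] == sex].sort_values("age")
    if sub.empty:
        raise ValueError(f"life table has no rows for sex {sex!r}")
    return (
        sub["age"].to_numpy(float),
        sub["q"].to_numpy(float),
        sub["cv_frac"].to_numpy(float),
        sub["liver_frac"].to_numpy(float),
    )


def mortality_components(
    params: ParameterSet, ages: np.ndarray, sex: str
) -> np.ndarray:
    """State-specific death probabilities by cause.

    Returns an array of shape ``(len(ages), 15, 3)`` with the CV, liver and
    other-cause annual death probability per state: the background all-cause
    probability split by the cause-of-death fractions, with the CV component
    scaled by the stage-group hazard ratio and the liver component by the
    state relative risk.  Totals are capped at 1 (components rescaled
    proportionally); the absorbing state has zero mortality.
    """
    tab_age, tab_q, tab_cv, tab_liver = _life_table_arrays(params, sex)
    idx = np.clip(np.searchsorted(tab_age, np.floor(ages), side="right") - 1, 0, len(tab_age) - 1)
    q = tab_q[idx]
    cvf = tab_cv[idx]
    lvf = tab_liver[idx]

    hr = np.array(
        [params.mortality.cv_hr[CV_HR_GROUP[s]] if s in CV_HR_GROUP else 0.0 for s in STATES]
    )
    rr = np.array(
        [
            params.mortality.liver_rr.get(LIVER_RR_GROUP.get(s, ""), 1.0)
            if s != "DEATH"
            else 0.0
            for s in STATES
        ]
    )
    alive = np.array([1.0 if s != "DEATH" else 0.0 for s in STATES])

    cv = q[:, None] * cvf[:, None] * hr[None, :]
    liver = q[:, None] * lvf[:, None] * rr[None, :] * alive[None, :]
    other = q[:, None] * (1.0 - cvf - lvf)[:, None] * alive[None, :]
    comp = np.stack([cv, liver, other], axis=-1)
    total = comp.sum(-1)
    over = total > 1.0
    if over.any():
        scale = np.where(over, 1.0 / np.maximum(total, 1e-300), 1.0)
        comp = comp * scale[..., None]
    return comp


def death_split(
    params: ParameterSet, state: str, age: float, sex: str
) -> tuple[float, float, float]:
    """(cv, liver, other) death-probability components for one state."""
    comp = mortality_components(params, np.array([age]), sex)[0, IDX[state]]
    return float(comp[0]), float(comp[1]), float(comp[2])


def cycle_matrix(
    params: ParameterSet,
    strategy: str,
    age: float,
    sex: str,
    D: np.ndarray | None = None,
) -> np.ndarray:
    """Full 15x15 row-stochastic cycle matrix at a given age and sex."""
    if D is None:
        D = build_disease_matrix(params, strategy)
    comp = mortality_components(params, np.array([age]), sex)[0]
    d = np.clip(comp.sum(-1), 0.0, 1.0)
    M = np.clip(1.0 - d, 0.0, 1.0)[:, None] * D
    M[:, IDX["DEATH"]] += d
    M[IDX["DEATH"], :] = 0.0
    M[IDX["DEATH"], IDX["DEATH"]] = 1.0
    if (M < -1e-15).any():
        raise ValueError("negative entry in cycle matrix")
    np.clip(M, 0.0, None, out=M)
    if not np.allclose(M.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("cycle matrix rows do not sum to 1")
    return M
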