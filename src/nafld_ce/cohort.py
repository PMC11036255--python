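"""Annual-cycle lifetime cohort trace and event accounting.

The cohort (mass 1) is split into a female and a male stratum at entry and
each stratum is iterated independently with its own sex-specific mortality;
the combined trace is their sum.  Each cycle the engine records state
occupancy, first entries into decompensated cirrhosis, HCC and transplant,
one-time treatment administrations, and deaths by cause.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .natural_history import build_disease_matrix, mortality_components
from .parameters import ParameterSet
from .states import IDX, N_STATES, STATES

__all__ = ["CohortTrace", "EventSummary", "run_cohort", "summarize_events", "initial_state_sweep"]

_DC = IDX["DC"]
_HCC = IDX["HCC"]
_LT = (IDX["LT_DC"], IDX["LT_HCC"])
_F4Y1 = IDX["F4_Y1"]
_F3 = IDX["F3"]
_DEATH = IDX["DEATH"]
_EARLY_IDX = tuple(range(6))


@dataclass
class CohortTrace:
    """Cycle-by-cycle ledger of one strategy run.

    ``occupancy[t]`` is the state distribution at the start of cycle ``t``
    (summing, with cumulative deaths included in the DEATH column, to 1).
    ``flows`` holds per-cycle first entries into DC/HCC/LT;
    ``administrations[t]`` counts one-time treatment charges at the start of
    cycle ``t``; ``deaths[t]`` are deaths during cycle ``t`` by cause
    (cv, liver, other).
    """

    strategy: str
    initial_state: str
    ages: np.ndarray  # (T+1,)
    occupancy: np.ndarray  # (T+1, 15) combined over sexes
    flows: dict[str, np.ndarray]  # 'DC' | 'HCC' | 'LT' -> (T+1,)
    administrations: np.ndarray  # (T+1,)
    deaths: np.ndarray  # (T, 3) cv, liver, other
    occupancy_by_sex: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return len(self.ages) - 1

    def live_mass(self) -> np.ndarray:
        return self.occupancy[:, :_DEATH].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (cycle, age, state, occupancy)."""
        t = np.repeat(np.arange(len(self.ages)), N_STATES)
        return pd.DataFrame(
            {
                "cycle": t,
                "age": np.repeat(self.ages, N_STATES),
                "state": np.tile(STATES, len(self.ages)),
                "occupancy": self.occupancy.ravel(),
            }
        )


@dataclass
class EventSummary:
    """Lifetime cumulative first-entry probabilities and death-cause shares."""

    pct_dc: float
    pct_hcc: float
    pct_lt: float
    death_share_liver: float
    death_share_cv: float
    death_share_other: float

    def to_dict(self) -> dict[str, float]:
        return {
            "pct_dc": self.pct_dc,
            "pct_hcc": self.pct_hcc,
            "pct_lt": self.pct_lt,
            "death_share_liver": self.death_share_liver,
            "death_share_cv": self.death_share_cv,
            "death_share_other": self.death_share_other,
        }


def _admin_inflow(strategy: str, surv: np.ndarray, D: np.ndarray) -> float:
    """One-time-treatment administrations occurring at the next cycle start."""
    if strategy == "curative":
        # every entry into first-year cirrhosis is an administration
        return float(surv @ D[:, _F4Y1])
    if strategy == "biologic":
        # first entry into advanced fibrosis / cirrhosis from an early state
        early = np.zeros_like(surv)
        early[list(_EARLY_IDX)] = surv[list(_EARLY_IDX)]
        return float(early @ D[:, _F3] + early @ D[:, _F4Y1])
    return 0.0


def _admin_initial(strategy: str, occ0: np.ndarray) -> float:
    if strategy == "curative":
        return float(occ0[_F4Y1])
    if strategy == "biologic":
        return float(occ0[_F3] + occ0[_F4Y1] + occ0[IDX["F4_LATER"]])
    return 0.0


def run_cohort(
    params: ParameterSet,
    strategy: str,
    initial_state: str = "NAFL_F0",
    live_mass_threshold: float = 1e-9,
) -> CohortTrace:
    """Run the deterministic cohort trace for one strategy.

    Iterates to ``max_age`` (or until live mass is exhausted), advancing age
    one year per cycle.  Deterministic given inputs.
    """
    if initial_state not in STATES or initial_state == "DEATH":
        raise ValueError(f"initial_state must be a live state, got {initial_state!r}")
    demo = params.demographics
    T = int(np.ceil(demo.max_age - demo.start_age))
    ages = demo.start_age + np.arange(T + 1, dtype=float)
    D = build_disease_matrix(params, strategy)

    occ = np.zeros((T + 1, N_STATES))
    flows = {k: np.zeros(T + 1) for k in ("DC", "HCC", "LT")}
    admin = np.zeros(T + 1)
    deaths = np.zeros((T, 3))
    occ_by_sex: dict[str, np.ndarray] = {}

    weights = {"female": demo.female_fraction, "male": 1.0 - demo.female_fraction}
    i0 = IDX[initial_state]
    for sex, w in weights.items():
        if w == 0.0:
            continue
        comp = mortality_components(params, ages[:T], sex)  # (T, 15, 3)
        d = np.clip(comp.sum(-1), 0.0, 1.0)
        o = np.zeros((T + 1, N_STATES))
        o[0, i0] = w
        flows_0 = {"DC": _DC, "HCC": _HCC}
        for key, j in flows_0.items():
            flows[key][0] += o[0, j]
        flows["LT"][0] += o[0, _LT[0]] + o[0, _LT[1]]
        admin[0] += _admin_initial(strategy, o[0])
        for t in range(T):
            cur = o[t]
            death_t = cur[:, None] * comp[t]  # (15, 3)
            surv = cur * np.clip(1.0 - d[t], 0.0, 1.0)
            nxt = surv @ D
            deaths[t] += death_t.sum(axis=0)
            nxt[_DEATH] = cur[_DEATH] + death_t.sum()
            o[t + 1] = nxt
            flows["DC"][t + 1] += float(surv @ D[:, _DC]) - surv[_DC] * D[_DC, _DC]
            flows["HCC"][t + 1] += float(surv @ D[:, _HCC]) - surv[_HCC] * D[_HCC, _HCC]
            flows["LT"][t + 1] += float(surv @ D[:, _LT[0]] + surv @ D[:, _LT[1]])
            admin[t + 1] += _admin_inflow(strategy, surv, D)
            if o[t + 1, :_DEATH].sum() < live_mass_threshold * w:
                o[t + 2 :] = o[t + 1]
                break
        occ += o
        occ_by_sex[sex] = o

    live_end = occ[-1, :_DEATH].sum()
    if live_end > 1e-3:
        warnings.warn(
            f"horizon reached with live mass {live_end:.2e} remaining", stacklevel=2
        )
    return CohortTrace(
        strategy=strategy,
        initial_state=initial_state,
        ages=ages,
        occupancy=occ,
        flows=flows,
        administrations=admin,
        deaths=deaths,
        occupancy_by_sex=occ_by_sex,
    )


def summarize_events(trace: CohortTrace) -> EventSummary:
    """Lifetime first-entry probabilities and death-cause shares.

    Shares are computed over all deaths through the horizon; first-entry
    probabilities are cumulative inflows (none of DC, HCC or the transplant
    tunnel can be re-entered, so inflow equals first entry).
    """
    total = trace.occupancy[0, :].sum()
    pct = {k: float(v.sum()) / total for k, v in trace.flows.items()}
    dead = trace.deaths.sum(axis=0)
    all_deaths = dead.sum()
    if all_deaths > 0:
        shares = dead / all_deaths
    else:
        shares = np.zeros(3)
    return EventSummary(
        pct_dc=pct["DC"],
        pct_hcc=pct["HCC"],
        pct_lt=pct["LT"],
        death_share_cv=float(shares[0]),
        death_share_liver=float(shares[1]),
        death_share_other=float(shares[2]),
    )


def initial_state_sweep(
    params: ParameterSet,
    strategies: tuple[str, ...],
    states: tuple[str, ...],
) -> pd.DataFrame:
    """Discounted lifetime QALYs by (strategy, initial state).

    Rows follow the given state order (callers pass states ordered by
    disease severity).
    """
    from .economics import evaluate  # local import to avoid a cycle

    records = []
    for state in states:
        for strategy in strategies:
            trace = run_cohort(params, strategy, initial_state=state)
            res = evaluate(trace, params, strategy)
            records.append(
                {
                    "initial_state": state,
                    "strategy": strategy,
                    "qaly_disc": res.qaly_disc,
                    "qaly_undisc": res.qaly_undisc,
                    "ly_disc": res.ly_disc,
                    "total_cost_disc": res.total_cost_disc,
                }
            )
    return pd.DataFrame.from_records(records)
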