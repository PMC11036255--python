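"""Discounted outcomes, ICERs, efficacy sweeps and breakeven pricing.

Costs and utilities accrue at cycle start; discounting uses integer cycle
exponents, ``(1+r)^-t``, with cycle 0 undiscounted.  Utilities are the
health-state value times an age-band population-norm multiplier normalised
to 1 at the cohort's entry age band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTrace, EventSummary, run_cohort, summarize_events
from .natural_history import Strategy
from .parameters import ParameterSet, set_param
from .states import COST_GROUP, IDX, STATES, UTILITY_GROUP

__all__ = [
    "StrategyResult",
    "IcerResult",
    "discount_factor",
    "evaluate",
    "icer",
    "run_strategy",
    "efficacy_sweep",
    "breakeven_price",
    "frontier",
]

_EFFICACY_PATH = {
    "biologic": "efficacy.biologic_avoid_prob",
    "curative": "efficacy.curative_cure_prob",
}


def discount_factor(rate: float, cycle: int) -> float:
    """(1+rate)^-cycle; cycle 0 is undiscounted."""
    if rate <= -1:
        raise ValueError("discount rate must exceed -1")
    if cycle < 0:
        raise ValueError("cycle must be non-negative")
    return float((1.0 + rate) ** (-cycle))


@dataclass
class StrategyResult:
    """Lifetime outcomes of one strategy run (per patient)."""

    strategy: str
    ly_disc: float
    ly_undisc: float
    qaly_disc: float
    qaly_undisc: float
    direct_medical_disc: float
    direct_medical_undisc: float
    treatment_disc: float
    treatment_undisc: float
    events: EventSummary
    admin_disc: float  # discounted one-time administrations per patient
    admin_undisc: float

    @property
    def total_cost_disc(self) -> float:
        return self.direct_medical_disc + self.treatment_disc

    @property
    def total_cost_undisc(self) -> float:
        return self.direct_medical_undisc + self.treatment_undisc

    def summary(self) -> pd.Series:
        ev = self.events
        return pd.Series(
            {
                "LY (disc)": self.ly_disc,
                "LY (undisc)": self.ly_undisc,
                "QALY (disc)": self.qaly_disc,
                "QALY (undisc)": self.qaly_undisc,
                "Direct medical cost (disc)": self.direct_medical_disc,
                "Treatment cost (disc)": self.treatment_disc,
                "Total cost (disc)": self.total_cost_disc,
                "Total cost (undisc)": self.total_cost_undisc,
                "% experiencing DC": 100 * ev.pct_dc,
                "% experiencing HCC": 100 * ev.pct_hcc,
                "% experiencing LT": 100 * ev.pct_lt,
                "Death share liver (%)": 100 * ev.death_share_liver,
                "Death share CV (%)": 100 * ev.death_share_cv,
                "Death share other (%)": 100 * ev.death_share_other,
            },
            name=self.strategy,
        )


def _age_multiplier(params: ParameterSet, ages: np.ndarray) -> np.ndarray:
    au = params.econ.age_utility
    if au is None:
        return np.ones_like(ages)
    lo = au["age_lo"].to_numpy(float)
    val = au["utility"].to_numpy(float)
    idx = np.clip(np.searchsorted(lo, ages, side="right") - 1, 0, len(lo) - 1)
    start_idx = np.clip(
        np.searchsorted(lo, params.demographics.start_age, side="right") - 1, 0, len(lo) - 1
    )
    return val[idx] / val[start_idx]


def evaluate(trace: CohortTrace, params: ParameterSet, strategy: str | Strategy) -> StrategyResult:
    """Convert a cohort trace into discounted/undiscounted LY, QALY, costs."""
    strat = (
        strategy
        if isinstance(strategy, Strategy)
        else Strategy.from_params(params, strategy)
    )
    econ = params.econ
    T = trace.n_cycles
    occ = trace.occupancy[:T]  # accrual at cycle start; final row is horizon end
    t = np.arange(T)
    ages = trace.ages[:T]

    u = np.zeros(len(STATES))
    c = np.zeros(len(STATES))
    for s in STATES[:-1]:
        u[IDX[s]] = econ.utility[UTILITY_GROUP[s]]
        c[IDX[s]] = econ.cost[COST_GROUP[s]]

    disc_o = (1.0 + econ.discount_rate_outcomes) ** (-t)
    disc_c = (1.0 + econ.discount_rate_costs) ** (-t)
    ones = np.ones(T)

    live = occ[:, : IDX["DEATH"]].sum(axis=1)
    qaly_t = (occ @ u) * _age_multiplier(params, ages)
    direct_t = occ @ c

    eligible = np.zeros(len(STATES))
    for s in strat.eligible_states:
        eligible[IDX[s]] = 1.0
    annual_t = strat.annual_cost * (occ @ eligible)
    admin = trace.administrations[:T]
    onetime_t = strat.one_time_price * admin

    def agg(series, disc):
        return float(series @ disc)

    return StrategyResult(
        strategy=strat.name,
        ly_disc=agg(live, disc_o),
        ly_undisc=agg(live, ones),
        qaly_disc=agg(qaly_t, disc_o),
        qaly_undisc=agg(qaly_t, ones),
        direct_medical_disc=agg(direct_t, disc_c),
        direct_medical_undisc=agg(direct_t, ones),
        treatment_disc=agg(annual_t, disc_c) + agg(onetime_t, disc_c),
        treatment_undisc=agg(annual_t, ones) + agg(onetime_t, ones),
        events=summarize_events(trace),
        admin_disc=agg(admin, disc_c),
        admin_undisc=float(admin.sum()),
    )


def run_strategy(
    params: ParameterSet, strategy: str, initial_state: str = "NAFL_F0"
) -> StrategyResult:
    """Convenience: run the cohort and evaluate in one call."""
    trace = run_cohort(params, strategy, initial_state=initial_state)
    return evaluate(trace, params, strategy)


# --------------------------------------------------------------------------
# ICER
# --------------------------------------------------------------------------


@dataclass
class IcerResult:
    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    verdict: str  # 'icer' | 'dominant' | 'dominated' | 'equal'
    icer: float | None = None
    equal_qaly: bool = False

    def __str__(self) -> str:
        if self.verdict == "icer":
            return (
                f"{self.intervention} vs {self.comparator}: "
                f"ICER ${self.icer:,.0f}/QALY (dC ${self.delta_cost:,.0f}, dQ {self.delta_qaly:.3f})"
            )
        return f"{self.intervention} vs {self.comparator}: {self.verdict}"


def icer(
    intervention: StrategyResult, comparator: StrategyResult, qaly_tol: float = 1e-12
) -> IcerResult:
    """Pairwise incremental comparison on discounted totals."""
    dc = intervention.total_cost_disc - comparator.total_cost_disc
    dq = intervention.qaly_disc - comparator.qaly_disc
    kw = dict(
        intervention=intervention.strategy,
        comparator=comparator.strategy,
        delta_cost=dc,
        delta_qaly=dq,
    )
    if abs(dq) < qaly_tol:
        if abs(dc) < 1e-6:
            return IcerResult(**kw, verdict="equal")
        verdict = "dominant" if dc < 0 else "dominated"
        return IcerResult(**kw, verdict=verdict, equal_qaly=True)
    if dq > 0 and dc < 0:
        return IcerResult(**kw, verdict="dominant")
    if dq < 0 and dc > 0:
        return IcerResult(**kw, verdict="dominated")
    return IcerResult(**kw, verdict="icer", icer=dc / dq)


def frontier(results: list[StrategyResult]) -> pd.DataFrame:
    """Efficiency-frontier report across strategies (extra output).

    Sorts by discounted cost, drops strongly and extendedly dominated
    strategies, and reports sequential ICERs along the frontier.
    """
    rows = sorted(results, key=lambda r: r.total_cost_disc)
    keep = [r for r in rows]
    # strong dominance
    keep = [
        r
        for r in keep
        if not any(
            o.total_cost_disc <= r.total_cost_disc and o.qaly_disc > r.qaly_disc
            for o in rows
            if o is not r
        )
    ]
    # extended dominance: sequential ICERs must increase
    changed = True
    while changed and len(keep) > 2:
        changed = False
        for i in range(1, len(keep) - 1):
            lo, mid, hi = keep[i - 1], keep[i], keep[i + 1]
            icer_lo = (mid.total_cost_disc - lo.total_cost_disc) / max(
                mid.qaly_disc - lo.qaly_disc, 1e-12
            )
            icer_hi = (hi.total_cost_disc - mid.total_cost_disc) / max(
                hi.qaly_disc - mid.qaly_disc, 1e-12
            )
            if icer_lo > icer_hi:
                keep.pop(i)
                changed = True
                break
    records = []
    prev = None
    for r in keep:
        rec = {
            "strategy": r.strategy,
            "cost_disc": r.total_cost_disc,
            "qaly_disc": r.qaly_disc,
            "icer_vs_previous": np.nan,
        }
        if prev is not None:
            rec["icer_vs_previous"] = (r.total_cost_disc - prev.total_cost_disc) / (
                r.qaly_disc - prev.qaly_disc
            )
        records.append(rec)
        prev = r
    return pd.DataFrame.from_records(records)


# --------------------------------------------------------------------------
# efficacy sweep and breakeven pricing
# --------------------------------------------------------------------------


def efficacy_sweep(
    params: ParameterSet,
    strategy: str,
    levels: tuple[float, ...] = (0.5, 0.7, 0.9),
    comparators: tuple[str, ...] = ("lifestyle", "small_molecule"),
    initial_state: str = "NAFL_F0",
) -> pd.DataFrame:
    """Incremental discounted QALYs/costs at different efficacy levels."""
    if strategy not in _EFFICACY_PATH:
        raise ValueError("efficacy sweep applies to the biologic or curative strategy")
    comp_results = {c: run_strategy(params, c, initial_state) for c in comparators}
    records = []
    for level in levels:
        ps = params.copy()
        set_param(ps, _EFFICACY_PATH[strategy], float(level))
        res = run_strategy(ps, strategy, initial_state)
        for c, comp in comp_results.items():
            pair = icer(res, comp)
            records.append(
                {
                    "strategy": strategy,
                    "efficacy": level,
                    "comparator": c,
                    "delta_qaly": pair.delta_qaly,
                    "delta_cost": pair.delta_cost,
                    "verdict": pair.verdict,
                    "icer": pair.icer,
                }
            )
    return pd.DataFrame.from_records(records)


def _cost_at_price(
    params: ParameterSet, res: StrategyResult, price: float
) -> float:
    """Discounted total cost of a one-time-priced strategy at another price.

    The administration ledger does not depend on the price, so total cost is
    affine in the price with slope equal to the discounted administration
    count.
    """
    base_price = params.econ.treatment[res.strategy].one_time_price
    return res.total_cost_disc + (price - base_price) * res.admin_disc


def breakeven_price(
    params: ParameterSet,
    strategy: str,
    comparator: str,
    wtp: float,
    efficacy: float | None = None,
    tol: float = 1.0,
) -> float:
    """Price at which the strategy's ICER vs the comparator equals ``wtp``.

    Exploits the affinity of discounted cost in the one-time price; the
    linear solution is verified by re-evaluation and refined by bisection in
    the (numerically unlikely) case the verification misses ``tol`` dollars.
    """
    ps = params
    if efficacy is not None:
        ps = params.copy()
        set_param(ps, _EFFICACY_PATH[strategy], float(efficacy))
    res = run_strategy(ps, strategy)
    comp = run_strategy(ps, comparator)
    dq = res.qaly_disc - comp.qaly_disc
    if dq <= 0:
        raise ValueError(
            f"no finite breakeven price: {strategy} does not gain QALYs vs {comparator}"
        )
    if res.admin_disc <= 0:
        raise ValueError(f"{strategy} has no one-time administrations to price")

    def delta_cost(price: float) -> float:
        return _cost_at_price(ps, res, price) - comp.total_cost_disc

    slope = res.admin_disc
    price = (wtp * dq - delta_cost(0.0)) / slope
    # verify by re-evaluation through the full evaluate() path; the price can
    # legitimately be negative when even a free treatment exceeds the
    # threshold against this comparator
    ps2 = ps.copy()
    set_param(ps2, f"econ.treatment.{strategy}.one_time_price", float(price))
    res2 = run_strategy(ps2, strategy)
    achieved = (res2.total_cost_disc - comp.total_cost_disc) / dq
    if abs(achieved - wtp) * dq > tol:  # dollars of incremental cost
        from scipy.optimize import brentq

        def f(p):
            ps3 = ps.copy()
            set_param(ps3, f"econ.treatment.{strategy}.one_time_price", float(p))
            r = run_strategy(ps3, strategy)
            return (r.total_cost_disc - comp.total_cost_disc) / dq - wtp

        half = max(abs(price) * 4, 1e7)
        price = brentq(f, -half, half, xtol=tol / 10)
    return float(price)
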