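"""Typed parameter model, validation, and config I/O.

A :class:`ParameterSet` bundles everything the cohort engine needs:
demographics, economics (utilities, costs, discounting, treatment cost
schedules), treatment-efficacy parameters, the annual disease transition
table, the three-cause mortality model, and the one-way/probabilistic
sensitivity specification.

Configuration lives in one YAML file for scalars plus sibling CSV files for
the naturally tabular blocks (disease transitions, life table, age-utility
norms).  Every scalar the sensitivity analyses vary is addressable by a
dotted path (e.g. ``econ.utility.DC`` or ``efficacy.weightloss_shares.1``)
via :func:`get_param` / :func:`set_param`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .states import (
    COST_GROUP,
    CV_HR_GROUP,
    LIVER_RR_GROUP,
    STATES,
    STRATEGIES,
    UTILITY_GROUP,
)

__all__ = [
    "ParameterError",
    "Demographics",
    "TreatmentCost",
    "EconParams",
    "EfficacyParams",
    "MortalityModel",
    "DsaParam",
    "PsaSettings",
    "ParameterSet",
    "cap_probability",
    "get_param",
    "set_param",
    "load_parameters",
    "save_parameters",
    "base_case_parameters",
    "validate",
]


class ParameterError(ValueError):
    """Raised when a parameter file or ParameterSet violates an invariant."""


def cap_probability(p: float) -> float:
    """Cap a probability at 1.

    Sensitivity bounds can exceed 1 on the probability scale (e.g. an upper
    confidence bound of 107.59% on a resolution probability); wherever such a
    value is used as a probability it is capped at 1.  Negative inputs are
    rejected.
    """
    p = float(p)
    if p < 0:
        raise ParameterError(f"probability must be non-negative, got {p}")
    return min(p, 1.0)


# --------------------------------------------------------------------------
# component dataclasses
# --------------------------------------------------------------------------


@dataclass
class Demographics:
    start_age: float = 47.7
    female_fraction: float = 0.558
    max_age: float = 110.0


@dataclass
class TreatmentCost:
    """Cost schedule of one strategy.

    ``annual`` accrues every cycle spent alive in ``eligible_states``;
    ``one_time_price`` is charged per administration, triggered by the
    strategy's entry rule (entry into first-year cirrhosis for the curative
    therapy, first entry into F3/F4 for the biologic).
    """

    annual: float = 0.0
    one_time_price: float = 0.0
    eligible_states: tuple[str, ...] = ()


@dataclass
class EconParams:
    discount_rate_costs: float = 0.03
    discount_rate_outcomes: float = 0.03
    utility: dict[str, float] = field(default_factory=dict)  # group -> u in [0,1]
    cost: dict[str, float] = field(default_factory=dict)  # group -> USD/yr
    age_utility: pd.DataFrame | None = None  # columns: age_lo, utility
    treatment: dict[str, TreatmentCost] = field(default_factory=dict)


@dataclass
class EfficacyParams:
    """Treatment-effect parameters.

    The lifestyle intervention is a mixture over three weight-loss classes
    (<5%, 5-10%, >10%), each with its own NASH-resolution probability and
    fibrosis-progression multiplier; the realized effect is the
    share-weighted average.  ``smallmol_*`` describe pioglitazone added to
    lifestyle; ``biologic_avoid_prob`` is the probability of avoiding
    progression out of F3/F4; ``curative_cure_prob`` is the probability that
    a patient entering cirrhosis is returned to NAFL F0.
    """

    weightloss_shares: np.ndarray = field(
        default_factory=lambda: np.array([0.8019, 0.1287, 0.0692])
    )
    lifestyle_resolution_by_class: np.ndarray = field(
        default_factory=lambda: np.array([0.1024, 0.4237, 0.8965])
    )
    lifestyle_progression_mult_by_class: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.9893, 0.4081])
    )
    smallmol_resolution: float = 0.527
    smallmol_progression_mult: float = 0.4081
    biologic_avoid_prob: float = 0.70
    curative_cure_prob: float = 0.70


@dataclass
class MortalityModel:
    """Background mortality plus disease-specific adjustment.

    ``life_table`` has columns ``age, sex, q, cv_frac, liver_frac``: the
    all-cause annual death probability and the fractions of deaths at that
    age/sex attributable to cardiovascular and liver causes (the remainder
    is "other").  The cardiovascular component is scaled by a stage-group
    hazard ratio, the liver component by a state relative risk.
    """

    life_table: pd.DataFrame | None = None
    liver_rr: dict[str, float] = field(default_factory=dict)  # group -> RR >= 1
    cv_hr: dict[str, float] = field(default_factory=dict)  # group -> HR > 0


@dataclass
class DsaParam:
    """One-way sensitivity entry: dotted path, bounds, PSA family."""

    path: str
    low: float
    high: float
    family: str = "normal"  # beta | gamma | lognormal | normal | point | uniform
    cap: bool = False  # cap sampled/bound values at 1 (probability-typed)


@dataclass
class PsaSettings:
    n_iter: int = 10_000
    transition_kappa: float | None = 100.0  # Dirichlet concentration; None = fixed rows


@dataclass
class ParameterSet:
    demographics: Demographics = field(default_factory=Demographics)
    econ: EconParams = field(default_factory=EconParams)
    efficacy: EfficacyParams = field(default_factory=EfficacyParams)
    transitions: pd.DataFrame | None = None  # from_state,to_state,annual_probability,subpop
    mortality: MortalityModel = field(default_factory=MortalityModel)
    dsa: list[DsaParam] = field(default_factory=list)
    wtp_grid: tuple[float, ...] = (50_000.0, 100_000.0, 150_000.0)
    psa: PsaSettings = field(default_factory=PsaSettings)

    # -- convenience -------------------------------------------------------
    def copy(self) -> "ParameterSet":
        """Cheap structural copy safe to mutate (shares the life table)."""
        return ParameterSet(
            demographics=replace(self.demographics),
            econ=EconParams(
                discount_rate_costs=self.econ.discount_rate_costs,
                discount_rate_outcomes=self.econ.discount_rate_outcomes,
                utility=dict(self.econ.utility),
                cost=dict(self.econ.cost),
                age_utility=self.econ.age_utility,
                treatment={k: replace(v) for k, v in self.econ.treatment.items()},
            ),
            efficacy=EfficacyParams(
                weightloss_shares=self.efficacy.weightloss_shares.copy(),
                lifestyle_resolution_by_class=self.efficacy.lifestyle_resolution_by_class.copy(),
                lifestyle_progression_mult_by_class=self.efficacy.lifestyle_progression_mult_by_class.copy(),
                smallmol_resolution=self.efficacy.smallmol_resolution,
                smallmol_progression_mult=self.efficacy.smallmol_progression_mult,
                biologic_avoid_prob=self.efficacy.biologic_avoid_prob,
                curative_cure_prob=self.efficacy.curative_cure_prob,
            ),
            transitions=None if self.transitions is None else self.transitions.copy(),
            mortality=MortalityModel(
                life_table=self.mortality.life_table,
                liver_rr=dict(self.mortality.liver_rr),
                cv_hr=dict(self.mortality.cv_hr),
            ),
            dsa=[replace(d) for d in self.dsa],
            wtp_grid=tuple(self.wtp_grid),
            psa=replace(self.psa),
        )

    def equals(self, other: "ParameterSet", tol: float = 1e-12) -> bool:
        """Structural equality up to floating-point round-trip noise."""

        def close(a, b):
            return abs(float(a) - float(b)) <= tol * max(1.0, abs(float(a)))

        if not all(
            close(getattr(self.demographics, f), getattr(other.demographics, f))
            for f in ("start_age", "female_fraction", "max_age")
        ):
            return False
        e1, e2 = self.econ, other.econ
        if not (
            close(e1.discount_rate_costs, e2.discount_rate_costs)
            and close(e1.discount_rate_outcomes, e2.discount_rate_outcomes)
            and e1.utility.keys() == e2.utility.keys()
            and all(close(e1.utility[k], e2.utility[k]) for k in e1.utility)
            and e1.cost.keys() == e2.cost.keys()
            and all(close(e1.cost[k], e2.cost[k]) for k in e1.cost)
        ):
            return False
        if e1.treatment.keys() != e2.treatment.keys():
            return False
        for k in e1.treatment:
            t1, t2 = e1.treatment[k], e2.treatment[k]
            if not (
                close(t1.annual, t2.annual)
                and close(t1.one_time_price, t2.one_time_price)
                and tuple(t1.eligible_states) == tuple(t2.eligible_states)
            ):
                return False
        f1, f2 = self.efficacy, other.efficacy
        for name in (
            "weightloss_shares",
            "lifestyle_resolution_by_class",
            "lifestyle_progression_mult_by_class",
        ):
            if not np.allclose(getattr(f1, name), getattr(f2, name), rtol=tol, atol=tol):
                return False
        for name in (
            "smallmol_resolution",
            "smallmol_progression_mult",
            "biologic_avoid_prob",
            "curative_cure_prob",
        ):
            if not close(getattr(f1, name), getattr(f2, name)):
                return False
        for df1, df2 in (
            (self.transitions, other.transitions),
            (self.mortality.life_table, other.mortality.life_table),
            (self.econ.age_utility, other.econ.age_utility),
        ):
            if (df1 is None) != (df2 is None):
                return False
            if df1 is not None:
                a = df1.reset_index(drop=True)
                b = df2.reset_index(drop=True)
                if list(a.columns) != list(b.columns) or len(a) != len(b):
                    return False
                for c in a.columns:
                    if a[c].dtype.kind in "fi":
                        if not np.allclose(a[c], b[c], rtol=1e-9, atol=1e-12):
                            return False
                    elif not (a[c].fillna("") == b[c].fillna("")).all():
                        return False
        if self.mortality.liver_rr != other.mortality.liver_rr:
            if self.mortality.liver_rr.keys() != other.mortality.liver_rr.keys() or not all(
                close(self.mortality.liver_rr[k], other.mortality.liver_rr[k])
                for k in self.mortality.liver_rr
            ):
                return False
        if self.mortality.cv_hr.keys() != other.mortality.cv_hr.keys() or not all(
            close(self.mortality.cv_hr[k], other.mortality.cv_hr[k])
            for k in self.mortality.cv_hr
        ):
            return False
        if len(self.dsa) != len(other.dsa):
            return False
        for d1, d2 in zip(self.dsa, other.dsa):
            if d1.path != d2.path or d1.family != d2.family or d1.cap != d2.cap:
                return False
            if not (close(d1.low, d2.low) and close(d1.high, d2.high)):
                return False
        return tuple(self.wtp_grid) == tuple(other.wtp_grid)


# --------------------------------------------------------------------------
# dotted-path access
# --------------------------------------------------------------------------


def _step(obj, token: str):
    if isinstance(obj, dict):
        if token not in obj:
            raise ParameterError(f"unknown key {token!r} in parameter path")
        return obj[token]
    if isinstance(obj, (list, np.ndarray)):
        return obj[int(token)]
    if not hasattr(obj, token):
        raise ParameterError(f"unresolvable parameter path segment {token!r}")
    return getattr(obj, token)


def get_param(ps: ParameterSet, path: str) -> float:
    obj = ps
    for token in path.split("."):
        obj = _step(obj, token)
    return obj


def set_param(ps: ParameterSet, path: str, value: float) -> None:
    tokens = path.split(".")
    obj = ps
    for token in tokens[:-1]:
        obj = _step(obj, token)
    last = tokens[-1]
    if isinstance(obj, dict):
        if last not in obj:
            raise ParameterError(f"unknown key {last!r} in parameter path")
        obj[last] = value
    elif isinstance(obj, (list, np.ndarray)):
        obj[int(last)] = value
    else:
        if not hasattr(obj, last):
            raise ParameterError(f"unresolvable parameter path segment {last!r}")
        setattr(obj, last, value)


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

_TRANSITION_COLUMNS = ["from_state", "to_state", "annual_probability", "subpop"]
_EARLY_STAGES = ("F0", "F1", "F2")


def _transition_rows(ps: ParameterSet):
    """Yield (subpop, from, to, p) with subpop normalized to '' for shared rows."""
    df = ps.transitions
    for row in df.itertuples(index=False):
        sub = "" if pd.isna(row.subpop) or row.subpop == "" else str(row.subpop)
        yield sub, str(row.from_state), str(row.to_state), float(row.annual_probability)


def validate(ps: ParameterSet, check_dsa_brackets: bool = True) -> None:
    """Check every ParameterSet invariant; raise ParameterError on violation.

    ``check_dsa_brackets=False`` skips the low <= base <= high check, which
    by design does not hold for PSA-sampled sets (draws may fall outside
    the one-way bounds).
    """
    d = ps.demographics
    if not 0.0 <= d.female_fraction <= 1.0:
        raise ParameterError(f"demographics.female_fraction out of [0,1]: {d.female_fraction}")
    if not d.start_age < d.max_age:
        raise ParameterError("demographics.start_age must be below max_age")

    e = ps.econ
    for r_name in ("discount_rate_costs", "discount_rate_outcomes"):
        if getattr(e, r_name) <= -1:
            raise ParameterError(f"econ.{r_name} must exceed -1")
    needed_u = set(UTILITY_GROUP.values())
    missing = needed_u - e.utility.keys()
    if missing:
        raise ParameterError(f"missing utility groups: {sorted(missing)}")
    for k, u in e.utility.items():
        if not 0.0 <= u <= 1.0:
            raise ParameterError(f"econ.utility.{k} out of [0,1]: {u}")
    needed_c = set(COST_GROUP.values())
    missing = needed_c - e.cost.keys()
    if missing:
        raise ParameterError(f"missing cost groups: {sorted(missing)}")
    for k, c in e.cost.items():
        if c < 0:
            raise ParameterError(f"econ.cost.{k} negative: {c}")
    for name, tc in e.treatment.items():
        if name not in STRATEGIES:
            raise ParameterError(f"unknown strategy {name!r} in treatment costs")
        if tc.annual < 0 or tc.one_time_price < 0:
            raise ParameterError(f"negative treatment cost for {name}")
        for s in tc.eligible_states:
            if s not in STATES:
                raise ParameterError(f"unknown eligible state {s!r} for {name}")
    for name in STRATEGIES:
        if name not in e.treatment:
            raise ParameterError(f"missing treatment cost schedule for {name}")
    if e.age_utility is not None:
        au = e.age_utility
        if not ((au["utility"] > 0) & (au["utility"] <= 1)).all():
            raise ParameterError("age-utility multipliers must lie in (0,1]")

    f = ps.efficacy
    if abs(float(np.sum(f.weightloss_shares)) - 1.0) > 1e-3:
        raise ParameterError("efficacy.weightloss_shares must sum to 1 (tol 1e-3)")
    for name in (
        "weightloss_shares",
        "lifestyle_resolution_by_class",
        "lifestyle_progression_mult_by_class",
    ):
        arr = np.asarray(getattr(f, name), float)
        if arr.shape != (3,):
            raise ParameterError(f"efficacy.{name} must have 3 entries")
        if (arr < 0).any():
            raise ParameterError(f"efficacy.{name} has negative entries")
    for name in ("smallmol_resolution", "biologic_avoid_prob", "curative_cure_prob"):
        v = getattr(f, name)
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"efficacy.{name} out of [0,1]: {v}")
    if f.smallmol_progression_mult < 0:
        raise ParameterError("efficacy.smallmol_progression_mult negative")

    # transitions
    if ps.transitions is None:
        raise ParameterError("missing disease transition table")
    if list(ps.transitions.columns) != _TRANSITION_COLUMNS:
        raise ParameterError(f"transition table must have columns {_TRANSITION_COLUMNS}")
    outflow: dict[tuple[str, str], float] = {}
    nafl_to_f4 = {}
    for sub, frm, to, p in _transition_rows(ps):
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"transition {sub}:{frm}->{to} probability out of [0,1]: {p}")
        key = (sub, frm)
        outflow[key] = outflow.get(key, 0.0) + p
        if sub == "NAFL" and to == "F4":
            nafl_to_f4[frm] = p
    for key, total in outflow.items():
        if total > 1.0 + 1e-9:
            raise ParameterError(f"disease outflow from {key} exceeds 1: {total}")
    if {"F0", "F1"} <= nafl_to_f4.keys():
        if abs(nafl_to_f4["F0"] - nafl_to_f4["F1"]) > 1e-12:
            warnings.warn(
                "NAFL F1->F4 differs from F0->F4 (direct-to-cirrhosis probabilities "
                "are expected to be equal for F0 and F1)",
                stacklevel=2,
            )

    # mortality
    m = ps.mortality
    if m.life_table is None:
        raise ParameterError("missing life table")
    lt = m.life_table
    for col in ("age", "sex", "q", "cv_frac", "liver_frac"):
        if col not in lt.columns:
            raise ParameterError(f"life table missing column {col!r}")
    if not ((lt["q"] >= 0) & (lt["q"] <= 1)).all():
        raise ParameterError("life-table q out of [0,1]")
    if ((lt["cv_frac"] + lt["liver_frac"]) > 1 + 1e-12).any():
        raise ParameterError("life-table cause fractions exceed 1")
    for sex, grp in lt.sort_values("age").groupby("sex"):
        if (np.diff(grp["q"].to_numpy()) < -1e-12).any():
            raise ParameterError(f"life-table q not non-decreasing in age for sex {sex!r}")
    needed = set(LIVER_RR_GROUP.values())
    missing = needed - m.liver_rr.keys()
    if missing:
        raise ParameterError(f"missing liver RR groups: {sorted(missing)}")
    for k, rr in m.liver_rr.items():
        if rr < 1.0:
            raise ParameterError(f"mortality.liver_rr.{k} must be >= 1, got {rr}")
    needed = set(CV_HR_GROUP.values())
    missing = needed - m.cv_hr.keys()
    if missing:
        raise ParameterError(f"missing CV HR groups: {sorted(missing)}")
    for k, hr in m.cv_hr.items():
        if hr <= 0:
            raise ParameterError(f"mortality.cv_hr.{k} must be positive, got {hr}")

    # DSA entries must resolve and bracket the base value
    for spec in ps.dsa:
        base = float(get_param(ps, spec.path))
        low, high = spec.low, spec.high
        if not check_dsa_brackets:
            if spec.family not in ("beta", "gamma", "lognormal", "normal", "point", "uniform"):
                raise ParameterError(f"unknown distribution family {spec.family!r}")
            continue
        if spec.cap:
            low, high, base_chk = (
                cap_probability(low),
                cap_probability(high),
                cap_probability(base),
            )
        else:
            base_chk = base
        if not low <= base_chk + 1e-9 or not base_chk <= high + 1e-9:
            raise ParameterError(
                f"DSA bounds for {spec.path} do not bracket base: "
                f"low={low}, base={base}, high={high}"
            )
        if spec.family not in ("beta", "gamma", "lognormal", "normal", "point", "uniform"):
            raise ParameterError(f"unknown distribution family {spec.family!r}")

    for w in ps.wtp_grid:
        if w < 0:
            raise ParameterError("WTP thresholds must be non-negative")


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

_KNOWN_TOP_KEYS = {
    "demographics",
    "economics",
    "efficacy",
    "mortality",
    "files",
    "dsa",
    "wtp_grid",
    "psa",
}


def _require(mapping: dict, key: str, ctx: str):
    if key not in mapping:
        raise ParameterError(f"missing required key {ctx}.{key}" if ctx else f"missing required key {key}")
    return mapping[key]


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a ParameterSet from a YAML config.

    CSV blocks (transitions, life table, age-utility norms) are referenced
    by relative path under the config's ``files:`` section.  Unknown top
    level keys are ignored with a warning; missing required keys and
    out-of-range values raise :class:`ParameterError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ParameterError(f"config {path} is not a mapping")
    unknown = set(raw) - _KNOWN_TOP_KEYS
    for key in sorted(unknown):
        warnings.warn(f"ignoring unknown config key {key!r}", stacklevel=2)

    dm = _require(raw, "demographics", "")
    demographics = Demographics(
        start_age=float(_require(dm, "start_age", "demographics")),
        female_fraction=float(_require(dm, "female_fraction", "demographics")),
        max_age=float(dm.get("max_age", 110.0)),
    )

    ec = _require(raw, "economics", "")
    treatment = {}
    for name, block in _require(ec, "treatment", "economics").items():
        treatment[name] = TreatmentCost(
            annual=float(block.get("annual", 0.0)),
            one_time_price=float(block.get("one_time_price", 0.0)),
            eligible_states=tuple(block.get("eligible_states", ())),
        )
    files = raw.get("files", {})
    base_dir = path.parent

    def _read_csv(key):
        if key not in files:
            return None
        return pd.read_csv(base_dir / files[key], keep_default_na=True)

    age_utility = _read_csv("age_utility")
    econ = EconParams(
        discount_rate_costs=float(_require(ec, "discount_rate_costs", "economics")),
        discount_rate_outcomes=float(_require(ec, "discount_rate_outcomes", "economics")),
        utility={k: float(v) for k, v in _require(ec, "utility", "economics").items()},
        cost={k: float(v) for k, v in _require(ec, "cost", "economics").items()},
        age_utility=age_utility,
        treatment=treatment,
    )

    ef = _require(raw, "efficacy", "")
    efficacy = EfficacyParams(
        weightloss_shares=np.asarray(_require(ef, "weightloss_shares", "efficacy"), float),
        lifestyle_resolution_by_class=np.asarray(
            _require(ef, "lifestyle_resolution_by_class", "efficacy"), float
        ),
        lifestyle_progression_mult_by_class=np.asarray(
            _require(ef, "lifestyle_progression_mult_by_class", "efficacy"), float
        ),
        smallmol_resolution=float(_require(ef, "smallmol_resolution", "efficacy")),
        smallmol_progression_mult=float(_require(ef, "smallmol_progression_mult", "efficacy")),
        biologic_avoid_prob=float(_require(ef, "biologic_avoid_prob", "efficacy")),
        curative_cure_prob=float(_require(ef, "curative_cure_prob", "efficacy")),
    )

    mo = _require(raw, "mortality", "")
    transitions = _read_csv("transitions")
    if transitions is not None:
        transitions["subpop"] = transitions["subpop"].fillna("")
    life_table = _read_csv("life_table")
    mortality = MortalityModel(
        life_table=life_table,
        liver_rr={k: float(v) for k, v in _require(mo, "liver_rr", "mortality").items()},
        cv_hr={k: float(v) for k, v in _require(mo, "cv_hr", "mortality").items()},
    )

    dsa = [
        DsaParam(
            path=str(_require(entry, "path", "dsa[]")),
            low=float(_require(entry, "low", "dsa[]")),
            high=float(_require(entry, "high", "dsa[]")),
            family=str(entry.get("family", "normal")),
            cap=bool(entry.get("cap", False)),
        )
        for entry in raw.get("dsa", [])
    ]

    psa_block = raw.get("psa", {})
    kappa = psa_block.get("transition_kappa", 100.0)
    psa = PsaSettings(
        n_iter=int(psa_block.get("n_iter", 10_000)),
        transition_kappa=None if kappa in (None, "none") else float(kappa),
    )

    ps = ParameterSet(
        demographics=demographics,
        econ=econ,
        efficacy=efficacy,
        transitions=transitions,
        mortality=mortality,
        dsa=dsa,
        wtp_grid=tuple(float(w) for w in raw.get("wtp_grid", (50_000, 100_000, 150_000))),
        psa=psa,
    )
    validate(ps)
    return ps


def save_parameters(ps: ParameterSet, path: str | Path) -> Path:
    """Write a ParameterSet as YAML + sibling CSVs; returns the YAML path.

    ``load_parameters(save_parameters(ps, p))`` round-trips.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stem = path.stem
    files = {}
    if ps.transitions is not None:
        fn = f"{stem}_transitions.csv"
        ps.transitions.to_csv(path.parent / fn, index=False)
        files["transitions"] = fn
    if ps.mortality.life_table is not None:
        fn = f"{stem}_life_table.csv"
        ps.mortality.life_table.to_csv(path.parent / fn, index=False)
        files["life_table"] = fn
    if ps.econ.age_utility is not None:
        fn = f"{stem}_age_utility.csv"
        ps.econ.age_utility.to_csv(path.parent / fn, index=False)
        files["age_utility"] = fn

    doc = {
        "demographics": {
            "start_age": ps.demographics.start_age,
            "female_fraction": ps.demographics.female_fraction,
            "max_age": ps.demographics.max_age,
        },
        "economics": {
            "discount_rate_costs": ps.econ.discount_rate_costs,
            "discount_rate_outcomes": ps.econ.discount_rate_outcomes,
            "utility": {k: float(v) for k, v in ps.econ.utility.items()},
            "cost": {k: float(v) for k, v in ps.econ.cost.items()},
            "treatment": {
                name: {
                    "annual": tc.annual,
                    "one_time_price": tc.one_time_price,
                    "eligible_states": list(tc.eligible_states),
                }
                for name, tc in ps.econ.treatment.items()
            },
        },
        "efficacy": {
            "weightloss_shares": [float(x) for x in ps.efficacy.weightloss_shares],
            "lifestyle_resolution_by_class": [
                float(x) for x in ps.efficacy.lifestyle_resolution_by_class
            ],
            "lifestyle_progression_mult_by_class": [
                float(x) for x in ps.efficacy.lifestyle_progression_mult_by_class
            ],
            "smallmol_resolution": ps.efficacy.smallmol_resolution,
            "smallmol_progression_mult": ps.efficacy.smallmol_progression_mult,
            "biologic_avoid_prob": ps.efficacy.biologic_avoid_prob,
            "curative_cure_prob": ps.efficacy.curative_cure_prob,
        },
        "mortality": {
            "liver_rr": {k: float(v) for k, v in ps.mortality.liver_rr.items()},
            "cv_hr": {k: float(v) for k, v in ps.mortality.cv_hr.items()},
        },
        "files": files,
        "dsa": [
            {"path": d.path, "low": d.low, "high": d.high, "family": d.family, "cap": d.cap}
            for d in ps.dsa
        ],
        "wtp_grid": [float(w) for w in ps.wtp_grid],
        "psa": {
            "n_iter": ps.psa.n_iter,
            "transition_kappa": ps.psa.transition_kappa,
        },
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def base_case_parameters() -> ParameterSet:
    """The packaged base case.

    Scalars (discounting, demographics, utilities, state costs, treatment
    costs/prices, efficacy, DSA bounds and distribution families) are the
    published base-case inputs.  The disease transition table, life table,
    cause-of-death fractions and mortality adjustments are a synthetic
    stand-in calibrated to the magnitudes typical of the NASH
    natural-history literature — the original per-transition appendix values
    are not published in the main text — so absolute model outputs are
    indicative, not a reproduction.
    """
    with resources.as_file(resources.files("nafld_ce.data") / "base_case.yaml") as p:
        return load_parameters(p)
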