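"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the pairwise comparison with one parameter at its lower
or upper bound, all others at base, producing tornado entries sorted by
range width.  PSA draws every uncertain parameter from a distribution
calibrated to the DSA bounds (interpreted as a 95% interval:
sd = (high - low)/3.92, mean = base, method of moments per family) and
re-runs all strategies on common draws within an iteration (paired
sampling), which is forced anyway by the shared natural-history parameters
and reduces the variance of incremental outcomes.  Disease transition rows
are jittered with a Dirichlet on the full outgoing row (stay probability
included), so sampled rows renormalise by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .economics import StrategyResult, icer, run_strategy
from .parameters import DsaParam, ParameterSet, cap_probability, get_param, set_param
from .states import STRATEGIES

__all__ = [
    "TornadoEntry",
    "PsaDraws",
    "one_way_dsa",
    "calibrate_distribution",
    "sample_parameter_set",
    "run_psa",
    "ceac",
    "ce_plane",
]


# --------------------------------------------------------------------------
# one-way DSA
# --------------------------------------------------------------------------


@dataclass
class TornadoEntry:
    path: str
    base: dict[str, float]  # metric -> base outcome
    at_low: dict[str, float]
    at_high: dict[str, float]
    icer_suppressed: bool = False  # dominance at base or either bound
    non_monotone: bool = False

    def width(self, metric: str) -> float:
        lo, hi = self.at_low.get(metric), self.at_high.get(metric)
        if lo is None or hi is None or np.isnan(lo) or np.isnan(hi):
            return np.nan
        return abs(hi - lo)


def _set_model_param(ps: ParameterSet, path: str, value: float) -> None:
    """Set one parameter, re-establishing coupled invariants.

    The weight-loss shares form a composition: perturbing one class
    rescales the vector back to its configured total.
    """
    total = float(np.sum(ps.efficacy.weightloss_shares))
    set_param(ps, path, value)
    if path.startswith("efficacy.weightloss_shares"):
        shares = np.asarray(ps.efficacy.weightloss_shares, float)
        ps.efficacy.weightloss_shares = shares * (total / shares.sum())


def _pair_metrics(a: StrategyResult, b: StrategyResult) -> dict[str, float]:
    pair = icer(a, b)
    return {
        "delta_qaly": pair.delta_qaly,
        "delta_cost": pair.delta_cost,
        "icer": pair.icer if pair.verdict == "icer" else np.nan,
        "_dominance": float(pair.verdict in ("dominant", "dominated")),
    }


def one_way_dsa(
    params: ParameterSet,
    intervention: str,
    comparator: str,
    sort_metric: str = "icer",
) -> list[TornadoEntry]:
    """One-way sensitivity of the pairwise comparison to every DSA entry.

    ICER entries are suppressed (NaN, flagged) when base or either bound
    yields dominance — an ICER range is meaningless across a dominance
    change; the QALY/cost tornados remain available.
    """
    base_m = _pair_metrics(
        run_strategy(params, intervention), run_strategy(params, comparator)
    )
    entries = []
    for spec in params.dsa:
        outcomes = {}
        for label, bound in (("low", spec.low), ("high", spec.high)):
            ps = params.copy()
            value = cap_probability(bound) if spec.cap else bound
            _set_model_param(ps, spec.path, value)
            outcomes[label] = _pair_metrics(
                run_strategy(ps, intervention), run_strategy(ps, comparator)
            )
        suppressed = bool(
            base_m["_dominance"]
            or outcomes["low"]["_dominance"]
            or outcomes["high"]["_dominance"]
        )
        non_mono = False
        for metric in ("delta_qaly", "delta_cost"):
            lo, hi, b = outcomes["low"][metric], outcomes["high"][metric], base_m[metric]
            if not (min(lo, hi) - 1e-9 <= b <= max(lo, hi) + 1e-9):
                non_mono = True
        entry = TornadoEntry(
            path=spec.path,
            base={k: v for k, v in base_m.items() if not k.startswith("_")},
            at_low={k: v for k, v in outcomes["low"].items() if not k.startswith("_")},
            at_high={k: v for k, v in outcomes["high"].items() if not k.startswith("_")},
            icer_suppressed=suppressed,
            non_monotone=non_mono,
        )
        if suppressed:
            entry.at_low["icer"] = np.nan
            entry.at_high["icer"] = np.nan
        entries.append(entry)

    def key(e: TornadoEntry) -> float:
        w = e.width(sort_metric)
        if np.isnan(w):
            w = e.width("delta_qaly")
        return -(w if not np.isnan(w) else 0.0)

    return sorted(entries, key=key)


def tornado_frame(entries: list[TornadoEntry], metric: str = "icer") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "path": e.path,
                "base": e.base.get(metric, np.nan),
                "at_low": e.at_low.get(metric, np.nan),
                "at_high": e.at_high.get(metric, np.nan),
                "width": e.width(metric),
                "icer_suppressed": e.icer_suppressed,
                "non_monotone": e.non_monotone,
            }
            for e in entries
        ]
    )


# --------------------------------------------------------------------------
# distribution calibration
# --------------------------------------------------------------------------


@dataclass
class CalibratedDistribution:
    family: str
    dist: object | None  # frozen scipy distribution, or None for point mass
    value: float = 0.0  # point-mass value
    cap: bool = False

    def sample(self, rng: np.random.Generator) -> float:
        if self.dist is None:
            x = self.value
        else:
            x = float(self.dist.rvs(random_state=rng))
        if self.cap:
            x = cap_probability(max(x, 0.0))
        if self.family == "beta":
            x = float(np.clip(x, 0.0, 1.0))
        return x


def calibrate_distribution(spec: DsaParam, base: float) -> CalibratedDistribution:
    """Method-of-moments fit with mean=base, sd=(high-low)/3.92.

    Infeasible moments (e.g. a beta variance at or above m(1-m)) fall back
    to uniform(low, high) with a warning.  Degenerate bounds give a point
    mass.
    """
    low, high = spec.low, spec.high
    if spec.cap:
        low, high = cap_probability(low), cap_probability(high)
        base = cap_probability(base)
    sd = (high - low) / 3.92
    if spec.family == "point" or sd <= 0:
        return CalibratedDistribution("point", None, value=base, cap=spec.cap)

    def uniform_fallback(reason: str) -> CalibratedDistribution:
        warnings.warn(
            f"cannot calibrate {spec.family} for {spec.path} ({reason}); "
            "falling back to uniform(low, high)",
            stacklevel=2,
        )
        return CalibratedDistribution(
            "uniform", stats.uniform(loc=low, scale=high - low), cap=spec.cap
        )

    if spec.family == "normal":
        return CalibratedDistribution("normal", stats.norm(loc=base, scale=sd), cap=spec.cap)
    if spec.family == "uniform":
        return CalibratedDistribution(
            "uniform", stats.uniform(loc=low, scale=high - low), cap=spec.cap
        )
    if spec.family == "beta":
        m, v = base, sd**2
        if not 0.0 < m < 1.0 or v >= m * (1.0 - m):
            return uniform_fallback("moments infeasible for beta")
        k = m * (1.0 - m) / v - 1.0
        return CalibratedDistribution(
            "beta", stats.beta(a=m * k, b=(1.0 - m) * k), cap=spec.cap
        )
    if spec.family == "gamma":
        if base <= 0:
            return uniform_fallback("non-positive mean for gamma")
        shape = (base / sd) ** 2
        return CalibratedDistribution(
            "gamma", stats.gamma(a=shape, scale=sd**2 / base), cap=spec.cap
        )
    if spec.family == "lognormal":
        if base <= 0 or low <= 0:
            return uniform_fallback("non-positive support for lognormal")
        sigma = (np.log(high) - np.log(low)) / 3.92
        mu = np.log(base) - sigma**2 / 2.0  # mean on the natural scale = base
        return CalibratedDistribution(
            "lognormal", stats.lognorm(s=sigma, scale=np.exp(mu)), cap=spec.cap
        )
    raise ValueError(f"unknown distribution family {spec.family!r}")


# --------------------------------------------------------------------------
# PSA
# --------------------------------------------------------------------------


def _calibrate_all(params: ParameterSet) -> list[tuple[DsaParam, CalibratedDistribution]]:
    return [(spec, calibrate_distribution(spec, float(get_param(params, spec.path)))) for spec in params.dsa]


def _sample_transitions(df: pd.DataFrame, kappa: float, rng: np.random.Generator) -> pd.DataFrame:
    """Dirichlet jitter per outgoing row, stay probability included."""
    out = df.copy()
    probs = out["annual_probability"].to_numpy(float).copy()
    sub = out["subpop"].fillna("")
    groups: dict[tuple[str, str], list[int]] = {}
    for i, (s, f) in enumerate(zip(sub, out["from_state"])):
        groups.setdefault((str(s), str(f)), []).append(i)
    for rows in groups.values():
        p = probs[rows]
        stay = 1.0 - p.sum()
        alpha = np.concatenate([p, [max(stay, 1e-9)]]) * kappa
        mask = alpha > 0
        draw = np.zeros_like(alpha)
        draw[mask] = rng.dirichlet(alpha[mask])
        # rescale so the sampled outgoing mass replaces the base outgoing mass
        probs[rows] = draw[:-1]
    out["annual_probability"] = probs
    return out


def sample_parameter_set(
    params: ParameterSet,
    rng: np.random.Generator,
    calibrations: list[tuple[DsaParam, CalibratedDistribution]] | None = None,
) -> ParameterSet:
    """Draw one PSA parameter set (scalar draws + transition-row Dirichlet)."""
    if calibrations is None:
        calibrations = _calibrate_all(params)
    ps = params.copy()
    base_share_total = float(np.sum(params.efficacy.weightloss_shares))
    share_sampled = False
    for spec, cal in calibrations:
        value = cal.sample(rng)
        set_param(ps, spec.path, value)
        if spec.path.startswith("efficacy.weightloss_shares"):
            share_sampled = True
    if share_sampled:
        # each share is drawn from its own marginal; rescale the composition
        # back to its configured total (identity for point-mass draws)
        shares = np.asarray(ps.efficacy.weightloss_shares, float)
        ps.efficacy.weightloss_shares = shares * (base_share_total / shares.sum())
    if ps.psa.transition_kappa is not None:
        ps.transitions = _sample_transitions(ps.transitions, ps.psa.transition_kappa, rng)
    return ps


@dataclass
class PsaDraws:
    """Per-iteration PSA outcomes on common parameter draws."""

    seed: int
    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_iter, n_strategies) discounted
    qalys: np.ndarray  # (n_iter, n_strategies) discounted
    n_failures: int = 0
    param_digest: pd.DataFrame | None = None  # per-iteration sampled scalars

    @property
    def n_iter(self) -> int:
        return self.costs.shape[0]

    def deltas(self, intervention: str, comparator: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.strategies.index(intervention)
        j = self.strategies.index(comparator)
        return self.costs[:, i] - self.costs[:, j], self.qalys[:, i] - self.qalys[:, j]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, s in enumerate(self.strategies):
            rows.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(self.n_iter),
                        "strategy": s,
                        "cost": self.costs[:, k],
                        "qaly": self.qalys[:, k],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def run_psa(
    params: ParameterSet,
    n_iter: int | None = None,
    seed: int = 0,
    strategies: tuple[str, ...] = STRATEGIES,
    initial_state: str = "NAFL_F0",
    keep_digest: bool = False,
) -> PsaDraws:
    """Monte-Carlo PSA with one RNG stream per iteration.

    Streams are derived from ``(seed, iteration)`` so results do not depend
    on execution order.  An iteration whose sampled set fails validation is
    redrawn once from a perturbed stream; more than 1% failing aborts.
    """
    from .parameters import validate

    if n_iter is None:
        n_iter = params.psa.n_iter
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    calibrations = _calibrate_all(params)
    costs = np.empty((n_iter, len(strategies)))
    qalys = np.empty((n_iter, len(strategies)))
    digest_rows = []
    failures = 0
    for i in range(n_iter):
        ps = None
        for attempt in range(2):
            rng = np.random.default_rng([seed, i, attempt])
            candidate = sample_parameter_set(params, rng, calibrations)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    validate(candidate, check_dsa_brackets=False)
                ps = candidate
                break
            except Exception:
                failures += 1
        if ps is None:
            raise RuntimeError(f"PSA iteration {i} failed validation twice")
        if failures > max(1, n_iter // 100):
            raise RuntimeError(
                f"more than 1% of PSA iterations failed validation ({failures} failures)"
            )
        for k, s in enumerate(strategies):
            res = run_strategy(ps, s, initial_state)
            costs[i, k] = res.total_cost_disc
            qalys[i, k] = res.qaly_disc
        if keep_digest:
            digest_rows.append(
                {spec.path: float(get_param(ps, spec.path)) for spec, _ in calibrations}
            )
    return PsaDraws(
        seed=seed,
        strategies=tuple(strategies),
        costs=costs,
        qalys=qalys,
        n_failures=failures,
        param_digest=pd.DataFrame(digest_rows) if keep_digest else None,
    )


# --------------------------------------------------------------------------
# CEAC and CE plane
# --------------------------------------------------------------------------


def ceac(draws: PsaDraws, wtp_grid: tuple[float, ...]) -> pd.DataFrame:
    """Acceptance probability per strategy across WTP thresholds.

    A strategy is accepted in an iteration when it maximises net monetary
    benefit ``wtp*Q - C``; ties split equally.  Columns sum to 1 at every
    threshold.
    """
    records = []
    for wtp in wtp_grid:
        nmb = wtp * draws.qalys - draws.costs  # (n, k)
        best = nmb.max(axis=1, keepdims=True)
        winners = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        share = winners / winners.sum(axis=1, keepdims=True)
        probs = share.mean(axis=0)
        for s, p in zip(draws.strategies, probs):
            records.append({"wtp": wtp, "strategy": s, "probability": float(p)})
    return pd.DataFrame.from_records(records)


def ce_plane(
    draws: PsaDraws,
    intervention: str,
    comparator: str,
    wtp: float = 150_000.0,
) -> pd.DataFrame:
    """Per-iteration incremental scatter with quadrant and threshold flags."""
    dc, dq = draws.deltas(intervention, comparator)
    quadrant = np.where(
        dq >= 0,
        np.where(dc >= 0, "NE", "SE/dominant"),
        np.where(dc >= 0, "NW/dominated", "SW"),
    )
    return pd.DataFrame(
        {
            "iteration": np.arange(draws.n_iter),
            "delta_qaly": dq,
            "delta_cost": dc,
            "quadrant": quadrant,
            "below_wtp": wtp * dq - dc > 0,
        }
    )
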