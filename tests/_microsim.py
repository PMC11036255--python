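"""Individual-level microsimulation oracle.

Simulates patients one at a time through the same per-cycle matrices as the
cohort engine but by Monte-Carlo sampling, providing an independent check
of the deterministic occupancy trace (the cohort result is the N -> inf
limit of this simulation).
"""

import numpy as np

from nafld_ce.natural_history import build_disease_matrix, mortality_components
from nafld_ce.states import IDX, N_STATES

_DEATH = IDX["DEATH"]


def microsimulate(params, strategy, n, seed, initial_state="NAFL_F0"):
    """Return state-occupancy fractions, shape (T+1, 15)."""
    demo = params.demographics
    T = int(np.ceil(demo.max_age - demo.start_age))
    ages = demo.start_age + np.arange(T, dtype=float)
    D = build_disease_matrix(params, strategy)
    rng = np.random.default_rng(seed)
    n_female = int(round(n * demo.female_fraction))
    counts = np.zeros((T + 1, N_STATES))
    for sex, n_sex in (("female", n_female), ("male", n - n_female)):
        if n_sex == 0:
            continue
        comp = mortality_components(params, ages, sex)
        d = comp.sum(-1)
        state = np.full(n_sex, IDX[initial_state])
        counts[0] += np.bincount(state, minlength=N_STATES)
        for t in range(T):
            M = (1.0 - d[t])[:, None] * D
            M[:, _DEATH] += d[t]
            M[_DEATH, :] = 0.0
            M[_DEATH, _DEATH] = 1.0
            cum = np.cumsum(M, axis=1)
            u = rng.random(n_sex)
            state = (cum[state] < u[:, None]).sum(axis=1)
            counts[t + 1] += np.bincount(state, minlength=N_STATES)
    return counts / n
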