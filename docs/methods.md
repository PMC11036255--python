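# Methods

## Model structure and conventions

The model is an annual-cycle, lifetime-horizon Markov cohort over 15
states (see `nafld_ce.states`). Conventions, chosen where the problem
statement leaves them open and held fixed throughout:

* **Competing risks within a cycle**: death first, disease transitions
  among survivors. This is the standard cohort-model ordering; the
  per-cycle matrix is `diag(1-d) · D` with death mass absorbed.
* **Sex strata**: two independent traces (female/male) with sex-specific
  mortality, combined at entry weights 0.558/0.442. Averaging mortality
  rates instead would bias late-life outcomes as the cohort's sex
  composition drifts.
* **Horizon**: cycles run to age 110 (a conventional closing age for
  "lifetime" with period life tables) or until live mass falls below
  1e-9. Remaining live mass at the horizon triggers a warning, not an
  error.
* **No half-cycle correction**: state membership is valued at cycle
  start for utilities and costs alike; discounting uses integer
  exponents `(1+r)^-t` with cycle 0 undiscounted. A half-cycle option was
  considered and deliberately not defaulted, to match the family of
  models this one extends.
* **First-entry accounting**: DC/HCC/transplant incidence is the
  per-cycle *inflow* into those states (none is re-enterable, so inflow
  equals first entry), matching "percentage of patients experiencing" an
  event rather than prevalence. Death-cause shares are taken over all
  deaths through the horizon.

## NAFL–NASH switching composition

A patient who switches between NAFL and NASH in a cycle is distributed
across the destination group's fibrosis stages according to that group's
own internal stage row: `P(NAFL_Fx → NASH_Fy) = s_x · p_NASH(Fx→Fy)`, with
the non-transitioning remainder of the switch mass staying at stage x in
the destination group. The non-switching mass follows the origin group's
internal row. Rows conserve mass by construction.

Within NAFL, the direct-to-cirrhosis probability for F1 is set equal to
F0's: the source natural-history data contain a F0→F4 observation but no
F1→F4 observation, which would otherwise make the model incoherent
(validation warns if the two differ).

## Treatment strategies

All strategies sit on a lifestyle standard-of-care background. The
lifestyle effect is a mixture over weight-loss classes (<5%, 5–10%, >10%
with shares 0.8019/0.1287/0.0692 *as printed*; they sum to 0.9998 and are
used unnormalised, with validation tolerance 1e-3): NASH→NAFL resolution
is the share-weighted resolution (≈0.1987) and fibrosis progression in
NASH and F3→F4 is scaled by the share-weighted multiplier (≈0.9575).
Per-class resolution probabilities are capped at 1 before averaging, since
upper uncertainty bounds can exceed the probability scale.

* **Small molecule** replaces the mixture with resolution 0.527 and
  multiplier 0.4081 (NASH stages and F3→F4; decompensation and HCC risks
  from F3 are interpreted as cirrhosis-driven and left unscaled).
* **Biologic** scales *all* progression out of F3 (to F4, DC and HCC) and
  out of F4 (to DC and HCC) by `1-e_B`. Whether avoiding "further
  progression" should include F3→F4 is ambiguous; it is included here
  (the therapy targets late-stage progression generally), and the choice
  is isolated in `apply_strategy_effects`.
* **Curative** acts on entry into first-year cirrhosis: with probability
  `e_C` the patient returns to NAFL F0; otherwise F4 natural history
  applies. Each entry into `F4_Y1` is an administration and is charged
  the one-time price — a cured patient who re-progresses is retreated.
  No extra relapse hazard is added beyond natural re-progression.
* **One-time biologic price** is charged on *first* entry into F3/F4
  (tracked as inflow from early states, so at most once per patient);
  annual routine-care costs continue alongside.
* Annual treatment costs accrue while alive in NAFL/NASH F0–F2 and F3 by
  default; the eligible-state set is configurable per strategy because
  accrual windows are the natural lever reconciling treatment-cost totals
  with life expectancy.

## Mortality

Background mortality comes from a life table (age × sex: all-cause `q`,
cardiovascular and liver cause-of-death fractions). Per state the three
components are `q·cv_frac·HR_g` (hazard ratio by stage group F0–F2 / F3 /
F4, with states at or beyond cirrhosis using the F4 group), `q·liver_frac·
RR_s` (relative risk for F3, F4, DC, HCC, transplant-year and
post-transplant states), and `q·(1-cv_frac-liver_frac)`. Totals are
capped at 1 with proportional component rescaling.

## Economics

QALYs weight occupancy by grouped state utilities (NAFL/NASH F0–F2 share
0.76) times an age-band population-norm multiplier normalised to 1 at the
entry age band — utilities decline with age multiplicatively, which is the
standard normalisation when only population norms are available. Breakeven
prices exploit that discounted incremental cost is affine in a one-time
price with slope equal to the discounted administration count; the linear
solution is verified by full re-evaluation and falls back to bisection.
Dominance is reported pairwise; an efficiency-frontier report
(`economics.frontier`) is provided separately.

## Sensitivity analysis

One-way DSA sets each uncertain parameter to its bound, all others at
base; ICER tornado entries are suppressed (flagged) whenever base or
either bound yields dominance. Perturbing one weight-loss share rescales
the composition back to its configured total.

PSA interprets the DSA bounds as a 95% interval — `sd = (high-low)/3.92`,
mean = base — and fits by method of moments: beta (clipped to [0,1]),
gamma, lognormal (fitted on the log scale with the mean preserved on the
natural scale), normal, with a uniform(low, high) fallback when moments
are infeasible (e.g. a beta around a mean of 1.0). Disease transition
rows are jittered with a Dirichlet over the full outgoing row including
the stay probability, concentration κ = 100 — an effective evidence size
of ~100 patients per row, the order of the paired-biopsy literature the
rows summarise — so rows renormalise by construction and row means equal
the base row. Draws are common across strategies within an iteration
(paired sampling; forced anyway by the shared natural history, and it
reduces the variance of increments), with one RNG stream per iteration
derived from `(seed, iteration)` so results are independent of execution
order. CEAC acceptance is the fraction of iterations maximising net
monetary benefit `wtp·Q − C`, ties split equally.

Because the model is mildly nonlinear (concave in transition
probabilities, convex in discounting), the PSA mean of an incremental
outcome sits slightly off the deterministic value — a Jensen gap of
roughly 3–4% of ΔQALY under the default κ — even though every parameter
is sampled mean-correctly. This is a property of the model, not a
sampling artefact.

## Synthetic data

Two layers of generated inputs exist, both first-class code:

* `synthetic.generate(seed)` emulates the statistical structure of the
  real inputs — net-progressive dynamics (NASH faster than NAFL,
  regression below progression), Gompertz background mortality
  `q = a·e^{b·age}` (a ∈ [1e-5, 1e-3], b ∈ [0.07, 0.11], male excess),
  utilities strictly decreasing and costs increasing with severity,
  probability parameters in [0,1], ±25% DSA bounds with family
  assignments by parameter class. It does *not* emulate: correlations
  between parameters, secular trends in background mortality, or any
  particular published cohort — so property tests passing on these sets
  demonstrate structural correctness, not numerical agreement with any
  real population.
* `synthetic.degenerate_fixture(kind)` gives closed-form-checkable sets
  (`no_death`, `two_state` geometric occupancy, `single_path` with
  cumulative incidence `1 − 0.9^n`).

The packaged base case is hybrid: published scalars, synthetic
natural-history tables (`transitions_synthetic.csv`,
`life_table_synthetic.csv`). The stand-in transition probabilities were
fixed once at magnitudes typical of the paired-biopsy and cirrhosis
literature (NASH stage progression ≈0.12/yr, NAFL ≈0.06/yr,
decompensation from cirrhosis ≈0.06/yr); liver-death relative risks were
chosen so implied absolute liver mortality matches literature-typical
values (DC ≈0.11/yr, HCC ≈0.33/yr at age 60). Under these inputs the
qualitative results hold (small molecule dominates lifestyle; the
curative therapy at $500k is cost-effective at $150k/QALY), but absolute
QALY/cost levels differ from the reference analysis the scalars come
from, and the reproduction tests document that gap rather than certify
agreement.

## Numerical choices and problem sizes

Cycle-matrix rows are validated to 1e-12; cohort mass conservation to
1e-9. The verification suite uses an individual-level microsimulation
(1e5 patients per set, exact-binomial 3σ bands per state×cycle cell with
a ≤1% multiplicity allowance, since ~0.3% of cells fall outside a 3-SE
band for a perfectly calibrated Monte-Carlo estimator), 1,000 random
parameter sets for row-stochasticity, and a 2,000-iteration PSA for
mean-convergence checks; these sizes keep the full suite around a minute
on one CPU while leaving Monte-Carlo error well below the effects tested.

## Known limitations

* No non-fatal cardiovascular event states; no NASH recurrence in the
  transplanted liver; no treatment side effects; no fibrosis-stage
  misclassification. These are deliberate scope bounds.
* The stand-in natural-history tables make absolute outputs indicative;
  replace `files:` entries in the config with transcribed tables to use
  the model against real inputs.
* Tunnel-state logic assumes annual cycles; shorter cycles would need
  explicit tunnel chains.
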