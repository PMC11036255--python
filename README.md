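# nafld-ce

A Markov cohort cost-utility model of non-alcoholic fatty liver disease
(NAFL) and non-alcoholic steatohepatitis (NASH), for health economists and
modellers evaluating disease-modifying liver therapies from a US
third-party-payer perspective.

## The model

A closed cohort (mean entry age 47.7 years, 55.8% female) moves annually
through 15 states: NAFL and NASH each split by early fibrosis stage
(F0–F2), shared advanced fibrosis (F3), compensated cirrhosis (a one-year
tunnel `F4_Y1` followed by `F4_LATER`), decompensated cirrhosis (DC),
hepatocellular carcinoma (HCC), one-year transplant tunnels, a
post-transplant state, and death. Patients switch between NAFL and NASH
within a fibrosis stage; a switch composes multiplicatively with the
destination group's own stage dynamics
(e.g. `P(NAFL_F0 → NASH_F1) = p_switch(F0) · p_NASH(F0→F1)`).

Each cycle, death is resolved first. The all-cause probability
`q(age, sex)` from a life table is split into cardiovascular, liver and
other components using cause-of-death fractions; the cardiovascular part is
scaled by a fibrosis-stage hazard ratio and the liver part by a
state-specific relative risk. Survivors then follow the disease matrix.

Four strategies share this natural history:

| strategy | mechanism | cost schedule |
|---|---|---|
| lifestyle | weight-loss mixture: NASH resolution Σπₖρₖ, progression multiplier Σπₖmₖ | $2,083/yr (F0–F3) |
| small molecule (pioglitazone add-on) | resolution 52.7%, progression ×0.4081 in NASH and F3 | $2,311/yr (F0–F3) |
| biologic | progression out of F3/F4 scaled by (1−e_B), e_B = 0.70 | $500,000 once, on first entry into F3/F4 |
| curative | entry into F4 cures to NAFL F0 with e_C = 0.70; retreatment on re-entry | $500,000 per administration |

Outcomes are discounted at 3%/yr: life years, QALYs (state utilities ×
age-band population norms), direct medical and treatment costs, lifetime
DC/HCC/transplant incidence and death-cause shares; pairwise ICERs
(ΔC/ΔQ) with dominance verdicts; efficacy sweeps; breakeven (value-based)
prices at willingness-to-pay thresholds of $50k/$100k/$150k per QALY;
one-way tornado analysis and probabilistic sensitivity analysis with
cost-effectiveness acceptability curves.

**Data caveat.** The published base-case *scalars* (costs, utilities,
efficacy, discounting, sensitivity bounds) are packaged as shipped. The
per-transition natural-history table, life table and mortality adjustments
were never published scalar-by-scalar; the packaged versions
(`*_synthetic.csv`) are a documented synthetic stand-in calibrated to the
magnitudes of the cited literature, so absolute outputs are indicative.
See `docs/methods.md`.

## Worked example

```python
import nafld_ce as nc

params = nc.base_case_parameters()
life = nc.run_strategy(params, "lifestyle")
cure = nc.run_strategy(params, "curative")
print(f"lifestyle: {life.qaly_disc:.2f} QALYs, ${life.total_cost_disc:,.0f}")
print(f"curative : {cure.qaly_disc:.2f} QALYs, ${cure.total_cost_disc:,.0f}")
print(nc.icer(cure, life))
print(f"breakeven at $150k/QALY: "
      f"${nc.breakeven_price(params, 'curative', 'lifestyle', 150_000):,.0f}")
```

prints

```
lifestyle: 14.64 QALYs, $232,985
curative : 15.18 QALYs, $296,716
curative vs lifestyle: ICER $117,801/QALY (dC $63,731, dQ 0.541)
breakeven at $150k/QALY: $594,432
```

i.e. under the packaged inputs the curative therapy gains 0.54 discounted
QALYs over lifestyle management for an extra $63,731 — cost-effective at a
$150,000/QALY threshold — and could be priced up to ~$594k per
administration before crossing that threshold. The same analyses are
available from the shell via `nafld-ce run|compare|price|sweep|dsa|psa|synth`.

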