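# Base-case configuration of the NAFL/NASH cohort model.
#
# Scalars (discounting, demographics, utilities, annual state costs,
# treatment costs and prices, efficacy, DSA bounds and PSA families) are the
# published base-case inputs of the analysis this package implements.
#
# The disease transition table, the life table with cause-of-death
# fractions, the cardiovascular hazard ratios and the liver-death relative
# risks are a SYNTHETIC stand-in: those inputs were never printed in the
# main text, so the shipped values are a one-off calibration to the
# magnitudes reported in the NASH natural-history literature.  Absolute
# model outputs under this file are indicative rather than a reproduction.

demographics:
  start_age: 47.7
  female_fraction: 0.558
  max_age: 110.0

economics:
  discount_rate_costs: 0.03
  discount_rate_outcomes: 0.03
  utility:            # annual health-state utilities (F0-F2 share one value)
    early: 0.76
    F3: 0.73
    F4: 0.66
    DC: 0.57
    HCC: 0.50
    LT: 0.73
  cost:               # annual direct medical costs, USD
    NAFL_F0: 2882.60
    NAFL_F1: 5765.20
    NAFL_F2: 8647.80
    NASH_F0: 4118.00
    NASH_F1: 8236.00
    NASH_F2: 12354.00
    F3: 17904.74
    F4: 29688.12
    DC: 106370.53
    HCC: 215504.24
    LT_Y1: 215504.24
    PLT: 53043.06
  treatment:
    lifestyle:
      annual: 2083.0          # routine care + lifestyle intervention
      one_time_price: 0.0
      eligible_states: &pre_cirrhosis
        [NAFL_F0, NAFL_F1, NAFL_F2, NASH_F0, NASH_F1, NASH_F2, F3]
    small_molecule:
      annual: 2311.0          # routine care + pioglitazone
      one_time_price: 0.0
      eligible_states: *pre_cirrhosis
    biologic:
      annual: 2083.0          # routine care continues
      one_time_price: 500000.0   # charged on first entry into F3/F4
      eligible_states: *pre_cirrhosis
    curative:
      annual: 2083.0
      one_time_price: 500000.0   # charged per administration on entry into F4 year 1
      eligible_states: *pre_cirrhosis

efficacy:
  weightloss_shares: [0.8019, 0.1287, 0.0692]          # <5%, 5-10%, >10%
  lifestyle_resolution_by_class: [0.1024, 0.4237, 0.8965]
  lifestyle_progression_mult_by_class: [1.0, 0.9893, 0.4081]
  smallmol_resolution: 0.527
  smallmol_progression_mult: 0.4081
  biologic_avoid_prob: 0.70
  curative_cure_prob: 0.70

mortality:
  # Synthetic calibration (see docs/methods.md): RRs chosen so that the
  # implied absolute liver-death probabilities at the cohort's mid ages
  # match literature-typical values (DC ~0.11/yr, HCC ~0.33/yr).
  liver_rr:
    F3: 25.0
    F4: 60.0
    DC: 900.0
    HCC: 2800.0
    LT: 1200.0
    PLT: 150.0
  cv_hr:
    F0_F2: 1.2
    F3: 1.6
    F4: 2.5

files:
  transitions: transitions_synthetic.csv
  life_table: life_table_synthetic.csv
  age_utility: age_utility.csv

wtp_grid: [50000.0, 100000.0, 150000.0]

psa:
  n_iter: 10000
  transition_kappa: 100.0

dsa:
  - {path: econ.discount_rate_costs, low: 0.015, high: 0.05, family: normal}
  - {path: econ.discount_rate_outcomes, low: 0.015, high: 0.05, family: normal}
  - {path: demographics.female_fraction, low: 0.50, high: 0.61, family: beta, cap: true}
  - {path: demographics.start_age, low: 45.9, high: 56.1, family: normal}
  - {path: econ.treatment.curative.one_time_price, low: 350000.0, high: 650000.0, family: lognormal}
  - {path: econ.treatment.biologic.one_time_price, low: 350000.0, high: 650000.0, family: lognormal}
  - {path: econ.treatment.small_molecule.annual, low: 1617.96, high: 3004.79, family: lognormal}
  - {path: econ.treatment.lifestyle.annual, low: 1458.43, high: 2708.51, family: lognormal}
  - {path: econ.cost.NAFL_F0, low: 2017.82, high: 3747.38, family: gamma}
  - {path: econ.cost.NAFL_F1, low: 4035.64, high: 7494.76, family: gamma}
  - {path: econ.cost.NAFL_F2, low: 6053.46, high: 11242.14, family: gamma}
  - {path: econ.cost.NASH_F0, low: 2882.60, high: 5353.40, family: gamma}
  - {path: econ.cost.NASH_F1, low: 5765.20, high: 10706.80, family: gamma}
  - {path: econ.cost.NASH_F2, low: 8647.80, high: 16060.20, family: gamma}
  - {path: econ.cost.F3, low: 12533.32, high: 23276.16, family: gamma}
  - {path: econ.cost.F4, low: 20781.68, high: 38594.56, family: gamma}
  - {path: econ.cost.DC, low: 74459.37, high: 138281.69, family: gamma}
  - {path: econ.cost.HCC, low: 150852.97, high: 280155.51, family: gamma}
  - {path: econ.cost.LT_Y1, low: 150852.97, high: 280155.51, family: gamma}
  - {path: econ.cost.PLT, low: 37130.14, high: 68955.98, family: gamma}
  - {path: econ.utility.early, low: 0.68, high: 0.84, family: beta, cap: true}
  - {path: econ.utility.F3, low: 0.66, high: 0.80, family: beta, cap: true}
  - {path: econ.utility.F4, low: 0.59, high: 0.73, family: beta, cap: true}
  - {path: econ.utility.DC, low: 0.51, high: 0.63, family: beta, cap: true}
  - {path: econ.utility.HCC, low: 0.45, high: 0.55, family: beta, cap: true}
  - {path: econ.utility.LT, low: 0.66, high: 0.80, family: beta, cap: true}
  - {path: efficacy.lifestyle_resolution_by_class.0, low: 0.0820, high: 0.1229, family: beta, cap: true}
  - {path: efficacy.lifestyle_resolution_by_class.1, low: 0.3390, high: 0.5085, family: beta, cap: true}
  - {path: efficacy.lifestyle_resolution_by_class.2, low: 0.7172, high: 1.0759, family: beta, cap: true}
  - {path: efficacy.smallmol_resolution, low: 0.4216, high: 0.6324, family: beta, cap: true}
  - {path: efficacy.lifestyle_progression_mult_by_class.0, low: 0.80, high: 1.20, family: beta}
  - {path: efficacy.lifestyle_progression_mult_by_class.1, low: 0.7915, high: 1.1872, family: beta}
  - {path: efficacy.lifestyle_progression_mult_by_class.2, low: 0.3265, high: 0.4898, family: beta, cap: true}
  - {path: efficacy.smallmol_progression_mult, low: 0.3265, high: 0.4898, family: beta, cap: true}
  - {path: efficacy.biologic_avoid_prob, low: 0.56, high: 0.84, family: beta, cap: true}
  - {path: efficacy.curative_cure_prob, low: 0.56, high: 0.84, family: beta, cap: true}
  - {path: efficacy.weightloss_shares.0, low: 0.6416, high: 0.9623, family: beta, cap: true}
  - {path: efficacy.weightloss_shares.1, low: 0.1030, high: 0.1545, family: beta, cap: true}
  - {path: efficacy.weightloss_shares.2, low: 0.0554, high: 0.0831, family: beta, cap: true}
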