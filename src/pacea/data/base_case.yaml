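# Base-case inputs for the leisure-centre membership cost-utility model.
# Scalars carry {value, lower, upper, dist} where a probabilistic/one-way
# sensitivity range is defined; bare numbers are fixed settings.
# Rates and proportions are dimensionless fractions; costs are GBP (2013/14).
settings:
  annual_discount_rate: 0.035
  cycle_length_months: 1
  starting_age: {value: 45, lower: 25, upper: 65, dist: normal}
  max_age: 110
  wtp_threshold: 20000

programme:
  n_recruited: 1025
  n_completers: 159
  dropout_counts:
    did_not_start: 300
    month_1: 280
    month_2: 138
    month_3: 107
    month_4: 41
  # completion fraction base value is n_completers / n_recruited
  completion: {lower: 0.01, upper: 0.5, dist: beta}
  general_cost_per_recruit: {value: 38.3, lower: 10.0, upper: 100.0, dist: gamma}
  sports_cost_per_completer: {value: 97.0, lower: 50.0, upper: 150.0, dist: gamma}
  sports_cost_per_noncompleter: {value: 16.75, lower: 5.0, upper: 50.0, dist: gamma}
  # per-completer sports cost components (GBP): induction, monthly membership
  # (charged for months 1 and 4 only), follow-up appointment, communication
  stage_cost_components:
    induction: 20.0
    membership_per_month: 28.0
    membership_months: [1, 4]
    follow_up: 20.0
    communication: 1.0
  duration_of_effect_months: {value: 12, lower: 4, upper: 20, dist: uniform}
  baseline_activity:
    low: {value: 0.324}
    moderate: {value: 0.376, lower: 0.25, upper: 0.5, dist: dirichlet}
    high: {value: 0.3, lower: 0.15, upper: 0.5, dist: dirichlet}
  followup_activity:
    low: {value: 0.235}
    moderate: {value: 0.235, lower: 0.1, upper: 0.4, dist: dirichlet}
    high: {value: 0.529, lower: 0.35, upper: 0.65, dist: dirichlet}

# incidence risk ratios versus the low-activity level
relative_risks:
  chd:
    moderate: {value: 0.9, lower: 0.83, upper: 0.99, dist: lognormal}
    high: {value: 0.81, lower: 0.68, upper: 0.96, dist: lognormal}
  stroke:
    moderate: {value: 0.86, lower: 0.79, upper: 0.93, dist: lognormal}
    high: {value: 0.74, lower: 0.64, upper: 0.85, dist: lognormal}
  diabetes:
    moderate: {value: 0.67, lower: 0.53, upper: 0.84, dist: lognormal}
    high: {value: 0.61, lower: 0.41, upper: 0.9, dist: lognormal}

# cause-specific background-mortality multipliers after a survived event
mortality_rrs:
  chd:
    cvd: {value: 3.89, lower: 3.81, upper: 3.97, dist: lognormal}
    non_cvd: {value: 1.71, lower: 1.44, upper: 1.98, dist: lognormal}
  stroke:
    cvd: {value: 3.89, lower: 3.81, upper: 3.97, dist: lognormal}
    non_cvd: {value: 1.71, lower: 1.44, upper: 1.98, dist: lognormal}
  diabetes:
    cvd: {value: 2.61, lower: 2.34, upper: 2.88, dist: lognormal}
    non_cvd: {value: 1.49, lower: 1.24, upper: 1.74, dist: lognormal}

utilities:
  # healthy, low-activity reference population by age band
  age_bands:
    - {age_lo: 33, age_hi: 44, value: 0.9, lower: 0.88, upper: 0.919, dist: beta}
    - {age_lo: 45, age_hi: 54, value: 0.86, lower: 0.84, upper: 0.879, dist: beta}
    - {age_lo: 55, age_hi: 64, value: 0.82, lower: 0.8, upper: 0.839, dist: beta}
    - {age_lo: 65, age_hi: 74, value: 0.78, lower: 0.76, upper: 0.799, dist: beta}
    - {age_lo: 75, age_hi: 110, value: 0.72, lower: 0.7, upper: 0.739, dist: beta}
  # disease multipliers on the age-specific healthy utility
  chd_first_event: {value: 0.8, lower: 0.622, upper: 0.931, dist: beta}
  chd_post_event: {value: 0.92, lower: 0.665, upper: 1.0, dist: beta}
  stroke_first_event: {value: 0.63, lower: 0.503, upper: 0.749, dist: beta}
  stroke_post_event: {value: 0.65, lower: 0.518, upper: 0.771, dist: beta}
  diabetes: {value: 0.9, lower: 0.665, upper: 0.997, dist: beta}
  # additive mental-wellbeing utility gain (QALY per person-year) by level
  mh_gain_moderate: {value: 0.023, lower: 0.0, upper: 0.2, dist: beta}
  mh_gain_high: {value: 0.104, lower: 0.0, upper: 0.2, dist: beta}
  # derivation inputs for the mental-health gains
  per_halfhour_gain: 0.000222433333
  extra_hours_moderate: 1.0
  extra_hours_high: 4.5

diseases:
  chd:
    incidence:  # yearly fraction, low-activity population
      - {age_lo: 33, age_hi: 34, value: 3.5e-05, lower: 1.7e-05, upper: 5.9e-05, dist: beta}
      - {age_lo: 35, age_hi: 44, value: 0.000465, lower: 0.000391, upper: 0.000546, dist: beta}
      - {age_lo: 45, age_hi: 54, value: 0.002095, lower: 0.001933, upper: 0.002263, dist: beta}
      - {age_lo: 55, age_hi: 64, value: 0.00631, lower: 0.006028, upper: 0.006599, dist: beta}
      - {age_lo: 65, age_hi: 74, value: 0.0097, lower: 0.00935, upper: 0.010056, dist: beta}
      - {age_lo: 75, age_hi: 81, value: 0.0097, lower: 0.00935, upper: 0.010056, dist: beta}
    fatal_fraction:  # probability an incident event is immediately fatal
      - {age_lo: 33, age_hi: 34, value: 0.0877, lower: 0.0713, upper: 0.10566, dist: beta}
      - {age_lo: 35, age_hi: 44, value: 0.0877, lower: 0.0713, upper: 0.10566, dist: beta}
      - {age_lo: 45, age_hi: 54, value: 0.0877, lower: 0.0713, upper: 0.10566, dist: beta}
      - {age_lo: 55, age_hi: 64, value: 0.1155, lower: 0.09386, upper: 0.1391, dist: beta}
      - {age_lo: 65, age_hi: 74, value: 0.2107, lower: 0.17087, upper: 0.25336, dist: beta}
      - {age_lo: 75, age_hi: 81, value: 0.1476, lower: 0.11988, upper: 0.17769, dist: beta}
    first_event_cost: {value: 4144.0, lower: 3372.0, upper: 4995.0, dist: gamma}
    annual_state_cost: {value: 473.0, lower: 385.0, upper: 571.0, dist: gamma}
  stroke:
    incidence:
      - {age_lo: 33, age_hi: 34, value: 8.0e-05, lower: 3.5e-05, upper: 0.000142, dist: beta}
      - {age_lo: 35, age_hi: 44, value: 0.00023, lower: 0.000148, upper: 0.00033, dist: beta}
      - {age_lo: 45, age_hi: 54, value: 0.00057, lower: 0.000435, upper: 0.000723, dist: beta}
      - {age_lo: 55, age_hi: 64, value: 0.00291, lower: 0.002593, upper: 0.003245, dist: beta}
      - {age_lo: 65, age_hi: 74, value: 0.0069, lower: 0.006408, upper: 0.00741, dist: beta}
      - {age_lo: 75, age_hi: 81, value: 0.01434, lower: 0.01363, upper: 0.015068, dist: beta}
    fatal_fraction:
      - {age_lo: 33, age_hi: 34, value: 0.2346, lower: 0.19024, upper: 0.28212, dist: beta}
      - {age_lo: 35, age_hi: 44, value: 0.2346, lower: 0.19024, upper: 0.28212, dist: beta}
      - {age_lo: 45, age_hi: 54, value: 0.2346, lower: 0.19024, upper: 0.28212, dist: beta}
      - {age_lo: 55, age_hi: 64, value: 0.2328, lower: 0.18876, upper: 0.27991, dist: beta}
      - {age_lo: 65, age_hi: 74, value: 0.2347, lower: 0.19026, upper: 0.28215, dist: beta}
      - {age_lo: 75, age_hi: 81, value: 0.2342, lower: 0.18989, upper: 0.2816, dist: beta}
    first_event_cost: {value: 10698.0, lower: 8704.0, upper: 12894.0, dist: gamma}
    annual_state_cost: {value: 2350.0, lower: 1912.0, upper: 2832.0, dist: gamma}
  diabetes:
    incidence:
      - {age_lo: 33, age_hi: 39, value: 9.0e-05, lower: 7.7e-05, upper: 0.000104, dist: beta}
      - {age_lo: 40, age_hi: 49, value: 0.00028, lower: 0.000257, upper: 0.000305, dist: beta}
      - {age_lo: 50, age_hi: 59, value: 0.000632, lower: 0.000596, upper: 0.000669, dist: beta}
      - {age_lo: 60, age_hi: 69, value: 0.001005, lower: 0.000959, upper: 0.001051, dist: beta}
      - {age_lo: 70, age_hi: 79, value: 0.001116, lower: 0.001068, upper: 0.001164, dist: beta}
      - {age_lo: 80, age_hi: 81, value: 0.001116, lower: 0.001068, upper: 0.001164, dist: beta}
    annual_state_cost: {value: 955.0, lower: 777.0, upper: 1152.0, dist: gamma}
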