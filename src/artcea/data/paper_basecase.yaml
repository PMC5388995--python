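# Base-case analysis configuration: every model input of the 2011 Zambian
# two-strategy comparison (hospital-only vs hospital + mobile ART), with the
# discretionary switches set to the calibration-grid winner.
cea:
  gdp_per_capita: 1408.0
  wtp_multiplier: 3
costing:
  annualization_rate: 0.03
  cost_table: null
  n_rural_centres: 5
  useful_life_years:
    building: 30.0
    furniture: 10.0
    vehicle: 5.0
  zmk_per_usd: 5000.0
model:
  cost_accrual: retained_only
  discount_rate: 0.03
  event_ordering: independent
  half_cycle_correction: initial_half_cycle
  horizon: 40
  mortality_not_retained: 0.375
  mortality_retained: 0.094
  start_age: 30.0
  utility_not_retained: 0.53
  utility_retained: 0.82
retention:
  interpolation: linear
  intervention_anchors:
  - - 1.0
    - 0.926
  - - 2.0
    - 0.841
  - - 3.0
    - 0.79
  - - 10.0
    - 0.7
  - - 20.0
    - 0.65
  - - 30.0
    - 0.6
  - - 40.0
    - 0.55
  original_anchors:
  - - 1.0
    - 0.886
  - - 2.0
    - 0.81
  - - 3.0
    - 0.72
  - - 10.0
    - 0.65
  - - 20.0
    - 0.6
  - - 30.0
    - 0.55
  - - 40.0
    - 0.5
seed: 20110412
sensitivity:
  psa:
    n_iterations: 10000
    seed: 20110412
  ranges:
    cost_intervention:
      high: 500.26
      low: 125.1
    cost_original:
      high: 492.9
      low: 123.23
    discount_rate:
      high: 0.15
      low: 0.0
    mortality_not_retained:
      high: 0.51
      low: 0.27
    mortality_retained:
      high: 0.17
      low: 0.04
    start_age:
      high: 50.0
      low: 20.0
    utility_retained:
      high: 0.98
      low: 0.62
  scenarios:
    best:
      intervention_reduction: 0.03
      original_reduction: 0.1
    worst:
      intervention_reduction: 0.1
      original_reduction: 0.03
  wtp_grid:
    start: 0.0
    step: 100.0
    stop: 6000.0
synthetic:
  age_median: 33.0
  age_sd: 10.0
  censor_date: '2012-12-31'
  enrol_end: '2011-12-31'
  enrol_start: '2010-01-01'
  ltfu_gap_months: 3
  n_patients: 32428
  visit_interval_months: 1
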