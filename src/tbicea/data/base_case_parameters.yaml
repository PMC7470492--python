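# Base-case parameter catalogue for the tranexamic-acid TBI decision model.
#
# One record per model parameter: point value, distribution tag, distribution
# parameters and a short source note.  Values are 2018 prices (GBP for the UK,
# USD for Pakistan).  Beta risk parameters are (events, non-events) so that
# alpha + beta equals the trial arm size.
version: 1
shared:
  rr_head:
    value: 0.78
    dist: lognormal
    params: {mu: -0.248, sigma: 0.1}
    source: trial risk ratio of head-injury death, mild/moderate TBI, 95% CI 0.64-0.95
  rr_nonhead:
    value: 1.0
    dist: fixed
    params: {value: 1.0}
    source: non-head-injury death risk assumed equal across arms
  smr_year1:
    value: 4.00
    dist: normal_ci
    params: {mean: 4.00, lo: 3.27, hi: 4.90}
    source: standardised mortality ratio, first year post-injury, head-injury cohort study
  smr_later:
    value: 2.26
    dist: normal_ci
    params: {mean: 2.26, lo: 1.84, hi: 2.77}
    source: standardised mortality ratio beyond the first year post-injury
  utility_good:
    value: 0.894
    dist: beta
    params: {alpha: 50.0, beta: 5.9}
    source: EQ-5D utility, GOS good recovery (mapping study)
  utility_moderate:
    value: 0.675
    dist: beta
    params: {alpha: 30.5, beta: 14.7}
    source: EQ-5D utility, GOS moderate disability
  utility_severe:
    value: 0.382
    dist: beta
    params: {alpha: 10.9, beta: 17.7}
    source: EQ-5D utility, GOS severe disability
  utility_vegetative:
    value: -0.178
    dist: fixed
    params: {value: -0.178}
    source: EQ-5D utility, vegetative state; held fixed (worse than death, no valid beta)
  gos_counts:
    value: [3094, 1288, 677, 124]
    dist: fixed
    source: estimated GOS mix of trial survivors (good, moderate, severe, vegetative)
  entry_age: {value: 42, source: mean age at model entry, from the trial}
  max_age: {value: 100, source: terminal age closure for the lifetime horizon}
countries:
  UK:
    currency: GBP
    discount_rate: {value: 0.035, source: national HTA guidance}
    threshold_per_qaly: {value: 20000, source: lower bound of the national 20k-30k per-QALY range}
    p28_head:
      value: 0.061
      dist: beta
      params: {alpha: 42.0, beta: 643.0}
      source: 28-day head-injury death risk, placebo, high-income stratum
    p28_nonhead:
      value: 0.018
      dist: beta
      params: {alpha: 12.0, beta: 673.0}
      source: 28-day non-head-injury death risk, placebo, high-income stratum
    costs:
      drug_cost: {value: 6.00, source: tranexamic acid 2 g, national formulary}
      fluid_cost: {value: 3.25, source: sodium chloride infusion bags (100 mL + 500 mL)}
      consumables_cost: {value: 0.05, source: needle and syringe, national costing template}
      admin_minutes: {value: 21, source: nurse administration time}
      admin_hourly_rate: {value: 37.00, source: default hospital-nurse hourly cost, 2018 unit-cost compendium level (configurable)}
      hospital_cost_total: {value: 4741.0, source: inpatient stay, national reference costs}
      los_days:
        value: 13.7
        dist: gamma
        params: {shape: 31.4, scale: 0.43}
        source: hospital length of stay, high-income stratum; 13.7-day point estimate
      monitoring_year1: {value: 11662.0, source: first-year post-discharge monitoring, national costing study}
      monitoring_annual: {value: 2505.0, source: annual long-term monitoring, HTA expert estimate}
      monitoring_duration_years: {value: lifetime, source: monitoring assumed until death}
  Pakistan:
    currency: USD
    discount_rate: {value: 0.03, source: international reference-case guidance for LMICs}
    threshold_per_qaly: {value: 158, source: opportunity-cost threshold, 10.75% of GDP per capita, 2018}
    p28_head:
      value: 0.079
      dist: beta
      params: {alpha: 165.0, beta: 1919.0}
      source: 28-day head-injury death risk, placebo, LMIC stratum
    p28_nonhead:
      value: 0.005
      dist: beta
      params: {alpha: 11.0, beta: 2073.0}
      source: 28-day non-head-injury death risk, placebo, LMIC stratum
    costs:
      drug_cost: {value: 1.92, source: tranexamic acid 2 g, local drug information system}
      fluid_cost: {value: 0.46, source: sodium chloride infusion bags}
      consumables_cost: {value: 0.20, source: needle and syringe, global costing study}
      admin_minutes: {value: 21, source: postgraduate-doctor administration time}
      admin_hourly_rate: {value: 5.20, source: postgraduate doctor hourly wage, trial hospital}
      hospital_cost_total: {value: 92.0, source: inpatient stay, WHO-CHOICE level}
      los_days:
        value: 7.4
        dist: gamma
        params: {shape: 21.8, scale: 0.34}
        source: hospital length of stay, LMIC stratum; 7.4-day point estimate
      monitoring_year1: {value: 0.0, source: no routine post-discharge monitoring provided}
      monitoring_annual: {value: 0.0, source: no routine post-discharge monitoring provided}
      monitoring_duration_years: {value: lifetime, source: not applicable (zero cost)}
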