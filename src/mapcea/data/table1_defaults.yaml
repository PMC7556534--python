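# Canonical base-case inputs for the MAP cost-effectiveness model.
# All money in 2019 USD; rates per year.

cohort_size: 1000
mean_age: 40
horizon: 30
discount_rate: 0.030
inflation_multiplier: 1.0     # CPI inflation pre-applied in the cost inputs
medical_cost_multiplier: 1.0  # scales symptomatic-state medical costs only
half_cycle_credit: true       # decedents receive half a cycle of utility and cost
intake_rounding: adjusted     # adjusted | printed (printed counts sum to 1,001)
life_table: us_lifetable_2007_synthetic.csv

# Cohort severity distributions (persons per 1,000).
intake_counts_printed:
  asymptomatic: 0
  mild: 0
  moderate: 122
  severe: 311
  extreme: 568
intake_counts_adjusted:
  asymptomatic: 0
  mild: 0
  moderate: 121
  severe: 311
  extreme: 568
followup_counts:
  asymptomatic: 216
  mild: 270
  moderate: 135
  severe: 230
  extreme: 149

# Pooled trial effect on CAPS-IV total score (patient-level SD; n active).
effectiveness:
  mean_caps_change: -37.9
  sd_caps_change: 28.9
  trial_n: 74
baseline_caps:
  mean: 85.8
  sd: 19.3

# Micro-costed per-patient intervention cost components.
intervention_components:
  therapists: 6194
  screening_diagnostics: 997
  pharmaceutical: 353

# Annual medical costs: severe-state anchor plus fixed severity multipliers.
severe_cost_anchor: 19888
asymptomatic_cost: 4946
cost_multipliers:
  extreme: 1.2
  moderate: 0.75
  mild: 0.5

# All-cause mortality RR for PTSD; per-state RRs derived from it.
base_mortality_rr: 2.28

utilities:
  asymptomatic: 1.0
  mild: 0.97
  moderate: 0.851
  severe: 0.477
  extreme: 0.369

# Fraction of the medical-cost reduction realised in cycles 1..5+.
cost_phase_in: [0.0, 0.25, 0.50, 0.75, 1.0]

# Relapse scenario: annual one-step severity progression in the MAP arm.
progression:
  rate: 0.06
  range: [0.0, 0.12]
  start_cycle: 5          # applied at the end of cycles >= 5
  table_variant:
    rate: 0.05
    range: [0.0, 0.10]

# Deterministic / probabilistic sensitivity ranges and spreads.
sensitivity:
  intervention_cost_rel_range: 0.30
  medical_cost_multiplier_range: [0.7, 1.3]
  discount_rate_range: [0.023, 0.038]
  mean_age_range: [35, 45]
  utility_ranges:
    mild: [0.90, 1.00]
    moderate_rel: 0.10
    severe_rel: 0.10
    extreme_rel: 0.10
  rr_sds:
    mild: 0.70
    moderate: 0.80
    severe: 1.10
    extreme: 1.25
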