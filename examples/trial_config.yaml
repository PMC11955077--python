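# Prespecified analysis settings for the attendance trial design
prior:
  control: {mean: 0.0, scale: 0.3, convention: precision}   # logit(p) ~ norm(0, 0.3) (JAGS precision)
  effect: {mean: 0.0, or_ci_upper: 30, level: 0.95}         # neutral OR prior, 95% CI 1/30-30
posterior: {n_draws: 10000, seed: 0}
stopping: {E: 0.95, F: 0.95, D: 0.01}
scenario:
  p_control: 0.30
  delta: 0.03
  cohort_size: 300
  outcome_lag_weeks: 2
  max_weeks: 50
  enrolment_cap: 15000
scenarios:
  - {p_control: 0.30, delta: 0.00}
  - {p_control: 0.30, delta: 0.01}
  - {p_control: 0.30, delta: 0.03}
  - {p_control: 0.30, delta: -0.01}
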