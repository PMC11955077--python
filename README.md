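# adaptrial

A Bayesian adaptive two-arm trial engine, built for a pragmatic trial embedded
in a vision-screening programme: adults who screen positive are referred to a
triage clinic, and the trial asks whether enhanced referral information (plus
SMS reminders) increases the proportion attending within 14 days, compared to
standard care. Enrolment is continuous (about 300 adults aged 18–44 per week,
randomized 1:1), and every week *all* accumulated outcome data are re-analysed
against prespecified stopping rules, so the trial ends as soon as the evidence
is sufficient — without a fixed sample size.

The package provides the four pieces of that design as reusable components:

- **Posterior engine** — the joint posterior of the two arms' attendance
  probabilities under a binomial outcome model with
  `logit(p_control) = α`, `logit(p_intervention) = α + β`,
  `α ~ N(0, 1/0.3)` on the logit scale (a JAGS-style precision of 0.3,
  i.e. sd ≈ 1.826, approximately uniform on the probability scale) and a
  neutral log-odds-ratio prior `β ~ N(0, (ln 30 / 1.96)²)` whose 95% interval
  on the odds-ratio scale is 1/30 to 30. The posterior is evaluated on an
  adaptive 2-D grid and resampled to 10,000 Monte-Carlo draws per analysis.
- **Stopping rules** — stop for *efficacy* when
  `max{P(Δ > 0), P(Δ < 0)} ≥ E` with Δ = p_intervention − p_control (the arm
  with the higher posterior mean is declared superior and adopted), or for
  *futility/equivalence* when `P(|Δ| < D) ≥ F` (control adopted). The
  prespecified thresholds are E = 0.95, F = 0.95, D = 0.01.
- **Trial simulator** — week-by-week enrolment with a 2-week outcome lag
  (the 14-day attendance window), weekly interims from week 3, a 50-week
  horizon and a 15,000-participant cap, fully reproducible from one seed.
- **Operating characteristics & reporting** — replicate simulations that
  estimate power, type I error and the sample-size distribution per truth
  scenario; plus participant-CSV validation, baseline tables, and the final
  intention-to-treat analysis for the 18–44, 45+ and all-adults groups.

## Worked example

```python
from adaptrial import ScenarioSpec, run_trial

# Truth: control attendance 30%, intervention 3 points better.
result = run_trial(ScenarioSpec(p_control=0.30, delta=0.03), seed=7)
print(result.decision.status.value, result.decision.adopted_arm.value)
print(result.stop_week, result.n_enrolled_at_stop, result.n_with_outcome_at_stop)
s = result.interim_trace[-1].summary
print(f"P(diff>0)={s.prob_diff_positive:.4f}  mean diff={s.mean_diff:.4f}  "
      f"95% CI=({s.ci95_diff[0]:.4f}, {s.ci95_diff[1]:.4f})")
```

prints

```
stop_efficacy intervention
4 1200 600
P(diff>0)=0.9994  mean diff=0.1179  95% CI=(0.0457, 0.1905)
```

This trial stopped at its second interim (week 4): with 600 observed outcomes
the posterior probability that the intervention is better reached 0.9994 ≥ E,
so the intervention was adopted after enrolling 1,200 participants. Note the
posterior mean difference (0.118) far exceeds the true effect (0.03): stopping
early on an efficacy boundary selects for lucky data, so effect magnitudes at
early stops should be interpreted cautiously — the design is built to get the
*adoption decision* right, not an unbiased effect estimate.

Design-level frequencies come from replicating such trials:

```python
from adaptrial import estimate_oc
oc = estimate_oc(ScenarioSpec(p_control=0.30, delta=0.0), n_replicates=500, seed=11)
print(oc.prob_adopt_intervention, oc.median_sample_size)
```

The same functionality is available from the shell:

```bash
adaptrial simulate-trial --config examples/trial_config.yaml --seed 7 --out trial.json
adaptrial estimate-oc    --config examples/trial_config.yaml --replicates 500 --seed 11 --out oc.csv
adaptrial interim        --data participants.csv --config examples/trial_config.yaml
adaptrial final-report   --data participants.csv --config examples/trial_config.yaml --out report.json
```

Every command logs the package version, seed and a configuration hash, so any
analysis can be re-run bit-for-bit from its log line.

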