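# Methods

## Outcome model and priors

Each arm's primary outcome — attendance at the referral triage appointment on
the scheduled date or within 14 days — is binary, and arm totals are modelled
binomially. The two arms are linked on the logit scale:

    alpha = logit(p_control),   logit(p_intervention) = alpha + beta,
    successes_c ~ Binomial(n_c, p_control),
    successes_i ~ Binomial(n_i, p_intervention).

`beta` is the log odds ratio of attendance. The priors are the trial's
prespecified ones:

- `alpha ~ Normal(0, sd = 1/sqrt(0.3) ≈ 1.826)`. The scale is written as a
  *precision* of 0.3 in the BUGS/JAGS convention. Read as a standard
  deviation instead, 0.3 would concentrate the attendance probability
  tightly around 0.5, contradicting the prior's stated role as approximately
  uniform over (0, 1); sd ≈ 1.826 on the logit scale is close to the
  standard-logistic density that corresponds exactly to a uniform prior on
  the probability. The convention is configurable
  (`PriorSpec.control_scale_convention ∈ {sd, variance, precision}`).
- `beta ~ Normal(0, sd = ln(30)/1.96 ≈ 1.735)`: a neutral prior (odds ratio
  1.0) whose equal-tailed 95% interval on the odds-ratio scale is 1/30 to 30.
  `logor_sd_from_ci` performs this conversion for any interval.

"Effect difference" is reported throughout as the absolute risk difference
`Δ = p_intervention − p_control` in proportion units, because the stopping
margin and the effects of interest are stated in percentage points of
attendance; D = 1% therefore means 0.01.

## Posterior computation

The log posterior in (alpha, beta) is strictly concave, so it is computed
deterministically rather than by MCMC:

1. Newton ascent (analytic gradient and Hessian, step-halving guard) finds
   the mode; the inverse negative Hessian gives the Laplace covariance.
2. The posterior is evaluated on a 101 × 101 grid spanning ±7 marginal
   standard deviations per axis around the mode.
3. 10,000 draws (the prespecified Monte-Carlo size; configurable) are
   produced by inverse-CDF resampling of grid cells plus a uniform
   within-cell jitter, making the draw distribution a piecewise-constant
   approximation of the posterior.

Numerical properties: the within-cell width is ~0.14 posterior sd, so
discretisation error in tail probabilities is O(h²) and far below the
Monte-Carlo resolution; a tail probability estimated from 10,000 draws has
standard error ≤ 0.005. Because the posterior is log-concave its tails are
sub-Gaussian, so mass outside the ±7 sd box is negligible. Empty arms are
legal (the posterior is then the prior; the Laplace step degenerates cleanly
to the prior mode). Identical inputs and seed give bitwise-identical draws.

Under near-flat priors the engine matches exact independent-Beta quadrature
of P(p_i > p_c) to within 0.01 at 50 observations per arm. One caveat worth
knowing: a *wide* normal prior on the logit scale is flat on the logit, not
on the probability, so for very small arms (n ≲ 30) its tail probabilities
genuinely differ from a uniform-on-p Beta posterior by more than 0.01 —
a property of the priors, not a numerical error.

## Stopping rules and decision semantics

At each interim the summary feeding the rules is: `P(Δ > 0)`, `P(Δ < 0)`,
and `P(|Δ| < D)` as plain draw fractions, plus posterior means and
equal-tailed 95% percentile intervals.

- **Efficacy**: fire when `max{P(Δ > 0), P(Δ < 0)} ≥ E`. The rule is
  two-sided — the trial's decision flow has symmetric superiority branches
  for the two arms even though the rule is often written one-sidedly — and
  the superior (adopted) arm is the one with the higher posterior mean
  proportion. An exact tie of means adopts control (conservative;
  configurable via `tie_breaker`).
- **Futility/equivalence**: fire when `P(|Δ| < D) ≥ F`; control is adopted.
- Boundary cases use ≥, so a probability exactly at a threshold stops.
- If both rules fire at one interim (possible in principle), efficacy wins:
  adopting a demonstrably superior arm dominates declaring equivalence.
- At the duration horizon with no rule fired, the arms are declared equally
  effective and control is adopted.

The decision is a pure function of (summary, thresholds); the evaluator
refuses a summary whose negligible margin differs from the thresholds' D.

## Trial simulation

A scenario fixes the truth: `p_control`, `delta`, weekly cohort size
(default 300, the observed 18–44 weekly accrual), outcome lag (default 2
weeks: appointments are taken to fall in the enrolment week, and the 14-day
window completes two weeks later — hence the first interim in week 3,
matching the design's 14-day first-interim allowance), maximum enrolment
weeks (default 50, so 50 × 300 matches the 15,000 one-year enrolment
estimate) and the enrolment cap itself.

Randomization is an exact 1:1 split per cohort by default ("equal numbers"),
with per-participant Bernoulli assignment as an option; accrual is fixed-size
by default with a Poisson option, since the stated 300 is an average. Interims
run weekly from the first week with any observable outcomes through
`max_weeks + lag`, each re-analysing all accumulated outcomes; enrolment
continues during the outcome lag, which is why enrolment at stop exceeds
outcomes observed at stop — both are reported, enrolment being the
operationally binding number.

RNG: one root `SeedSequence`; per-week cohort streams, per-interim posterior
streams and per-replicate trial streams are derived with fixed spawn keys
(counter-based), so results are independent of evaluation order and any unit
is individually reproducible. Replicates in the operating-characteristics
estimator are embarrassingly parallel by construction.

## Operating characteristics

`estimate_oc` replicates seeded trials (default 500 per scenario, giving a
binomial standard error of ~2 percentage points on adoption probabilities)
and aggregates: adoption probability per arm, the efficacy/futility/
max-duration split (these partition the replicates exactly), median and IQR
of enrolment at stop and of outcomes observed at stop, and the mean stop
week. `oc_table` maps a scenario list to one row each, with per-scenario
derived seeds so rows are mutually independent.

Simulated frequencies under this design worth knowing when interpreting
results (500 replicates, control rate 0.30): the weekly two-sided efficacy
check at E = 0.95 over ~50 interims is a heavily repeated test, so even with
identical arms the trial ends at an efficacy boundary roughly half the time
(~25% adopting the intervention — the design deliberately trades a large
type I error for speed in a negligible-risk setting). The equivalence rule
at D = 0.01 needs the posterior sd of Δ below ~0.005, i.e. more outcomes per
arm than the cap allows at baseline rates near 30%, so equal-arm trials that
never cross an efficacy boundary run to maximum duration.

The published design-phase table was produced under conditions (true
baseline rate, accrual detail, replicate count, sampler noise) that are not
public; with the assumptions above this package reproduces its −1% and +3%
adoption probabilities and its sample-size medians (within a factor of two),
while its +1% power and type-I-error figures come out lower here (~64% vs
81%, ~25% vs 36%). The discrepancy is robust to the baseline rate — the
null-crossing probability is essentially invariant to it — and was
cross-checked against an independent random-walk approximation of the same
monitoring scheme, which agrees with this package, so those two published
figures evidently reflect unstated simulation conditions rather than a
property reproducible from the published design parameters alone.

## What the simulator does and does not emulate

Emulated: weekly batched enrolment at the observed 18–44 accrual rate, 1:1
randomization, binomial outcomes at fixed true rates, the 14-day outcome
window as a whole-week lag, weekly cumulative re-analysis, both stopping
rules, the duration horizon and enrolment cap.

Not emulated: appointment-date heterogeneity and partially elapsed windows
(a week-resolution lag stands in for per-participant timing), SMS delivery
timing, loss to follow-up, seasonal or drifting attendance rates, and
age-group mixtures within the stopping cohort (stopping uses only the
18–44 stratum, as prespecified). Passing tests therefore demonstrate the
decision machinery's calibration under the idealised accrual-and-outcome
process, not under real-world irregular accrual or outcome drift.

## Final analysis and reporting

Participant CSVs are validated row-by-row (eligibility ≥ 18 years, known
arm, boolean outcome, positive enrolment week); any invalid row fails the
read with its line number listed, so records can never be dropped silently.
Baseline tables give per-arm n, sex frequencies and percentages, and age
mean and sample sd (n−1; undefined for a single participant), flagging ages
beyond 3 sd. The final analysis is intention-to-treat: every validated
record counts in its randomized arm. It reports, for ages 18–44 (primary),
45+ and all adults: each arm's posterior probability of being superior, the
probability of a negligible (< 1 point) difference, and means with 95%
credible intervals for both proportions and their difference. The age
partition is 18–44 inclusive versus 45 and older (age at enrolment); a group
with an empty arm is reported as not estimable without aborting the run.

## Default parameters at a glance

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| E (efficacy threshold) | 0.95 | posterior prob. | prespecified |
| F (futility threshold) | 0.95 | posterior prob. | prespecified |
| D (negligible margin) | 0.01 | risk difference | prespecified (1 point) |
| control prior | N(0, prec. 0.3) | logit | ~uniform on p |
| effect prior | N(0, 1.735²) | log OR | 95% CI 1/30–30 |
| draws per interim | 10,000 | — | prespecified MC size |
| cohort | 300/week | participants | observed 18–44 accrual |
| outcome lag | 2 | weeks | 14-day window |
| horizon | 50 | weeks | ~1 year |
| enrolment cap | 15,000 | participants | stated estimate |
| replicates | 500 | trials | ~2pp MC se |
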