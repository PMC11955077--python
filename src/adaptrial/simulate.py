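"""Week-by-week simulation of the adaptive trial.

Each simulated week a cohort of (by default) 300 participants enrols, split
1:1 between arms, and attendance outcomes are drawn from each arm's true
binomial probability.  Outcomes become observable ``outcome_lag_weeks`` (by
default 2) weeks after enrolment, reflecting the 14-day attendance window, so
the first interim analysis of week-1 enrolees happens in week 3.  At every
interim all accumulated outcome data are re-analysed with the posterior
engine and checked against the stopping rules; if no rule fires by the final
interim (``max_weeks + outcome_lag_weeks``), the trial stops for maximum
duration and the control arm is adopted.

Randomness is split into deterministic per-week substreams derived from one
root seed via ``numpy.random.SeedSequence`` spawn keys, so any week, trial or
replicate is individually reproducible and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .decisions import (
    Decision,
    DecisionStatus,
    DecisionThresholds,
    evaluate_stopping,
    max_duration_decision,
)
from .posterior import ArmCounts, InterimData, PosteriorSummary, sample_posterior, summarize_posterior
from .priors import PriorSpec

__all__ = ["ScenarioSpec", "InterimRecord", "TrialResult", "simulate_weekly_cohort", "run_trial"]


@dataclass(frozen=True)
class ScenarioSpec:
    """A truth scenario for simulation.

    ``p_control`` is the true control-arm attendance probability and
    ``delta`` the true risk difference, so the intervention arm attends with
    probability ``p_control + delta``.  Defaults mirror the trial design:
    weekly cohorts of 300 (150 per arm), a 2-week outcome lag, at most 50
    enrolment weeks and an enrolment cap of 15,000.
    """

    p_control: float
    delta: float
    cohort_size: int = 300
    outcome_lag_weeks: int = 2
    max_weeks: int = 50
    enrolment_cap: int = 15_000
    accrual: Literal["fixed", "poisson"] = "fixed"
    randomization: Literal["exact", "bernoulli"] = "exact"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_control < 1.0:
            raise ValueError(f"p_control must be in (0, 1), got {self.p_control}")
        if not 0.0 < self.p_control + self.delta < 1.0:
            raise ValueError(
                f"p_control + delta must lie in (0, 1), got {self.p_control + self.delta}"
            )
        if self.cohort_size <= 0 or self.cohort_size % 2:
            raise ValueError(
                f"cohort_size must be a positive even integer (1:1 randomization), got {self.cohort_size}"
            )
        if self.outcome_lag_weeks < 0:
            raise ValueError("outcome_lag_weeks must be non-negative")
        if self.max_weeks <= 0 or self.enrolment_cap <= 0:
            raise ValueError("max_weeks and enrolment_cap must be positive")

    @property
    def p_intervention(self) -> float:
        return self.p_control + self.delta


@dataclass(frozen=True)
class InterimRecord:
    """One weekly interim analysis: the accumulated data it saw and the
    decision it produced."""

    week: int
    data: InterimData
    n_enrolled: int
    summary: PosteriorSummary
    decision: Decision


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated (or real) trial."""

    decision: Decision
    stop_week: int
    n_enrolled_at_stop: int
    n_with_outcome_at_stop: int
    interim_trace: tuple[InterimRecord, ...] = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "decision": self.decision.to_dict(),
            "stop_week": self.stop_week,
            "n_enrolled_at_stop": self.n_enrolled_at_stop,
            "n_with_outcome_at_stop": self.n_with_outcome_at_stop,
            "interim_trace": [
                {
                    "week": r.week,
                    "n_enrolled": r.n_enrolled,
                    "n_control": r.data.control.n,
                    "successes_control": r.data.control.successes,
                    "n_intervention": r.data.intervention.n,
                    "successes_intervention": r.data.intervention.successes,
                    **r.summary.to_dict(),
                    "decision": r.decision.to_dict(),
                }
                for r in self.interim_trace
            ],
        }

    def trace_dataframe(self) -> pd.DataFrame:
        """Interim trace as a tidy table (one row per weekly analysis)."""
        rows = [
            {
                "week": r.week,
                "n_c": r.data.control.n,
                "s_c": r.data.control.successes,
                "n_i": r.data.intervention.n,
                "s_i": r.data.intervention.successes,
                "prob_superior": max(r.summary.prob_diff_positive, r.summary.prob_diff_negative),
                "prob_diff_positive": r.summary.prob_diff_positive,
                "prob_negligible": r.summary.prob_negligible,
                "decision": r.decision.status.value,
            }
            for r in self.interim_trace
        ]
        return pd.DataFrame(rows)


def _child(root: np.random.SeedSequence, *key: int) -> np.random.SeedSequence:
    """Deterministic counter-based child stream (independent of spawn order)."""
    return np.random.SeedSequence(entropy=root.entropy, spawn_key=root.spawn_key + tuple(key))


def _as_seedseq(seed: int | np.random.SeedSequence) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


def simulate_weekly_cohort(
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    n_total: int | None = None,
) -> InterimData:
    """Draw one weekly cohort's arm sizes and attendance outcomes.

    With the default exact 1:1 randomization, ``cohort_size / 2`` participants
    enter each arm; under ``randomization="bernoulli"`` each participant is
    assigned by a fair coin.  Successes per arm are binomial in the arm's true
    attendance probability.
    """
    if n_total is None:
        n_total = scenario.cohort_size
        if scenario.accrual == "poisson":
            n_total = int(rng.poisson(scenario.cohort_size))
            n_total += n_total % 2  # keep pairs under exact randomization
    if scenario.randomization == "bernoulli":
        n_c = int(rng.binomial(n_total, 0.5))
    else:
        n_c = n_total // 2
    n_i = n_total - n_c
    s_c = int(rng.binomial(n_c, scenario.p_control)) if n_c else 0
    s_i = int(rng.binomial(n_i, scenario.p_intervention)) if n_i else 0
    return InterimData(control=ArmCounts(n_c, s_c), intervention=ArmCounts(n_i, s_i))


def run_trial(
    scenario: ScenarioSpec,
    prior: PriorSpec | None = None,
    thresholds: DecisionThresholds | None = None,
    n_draws: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> TrialResult:
    """Simulate one full adaptive trial under a truth scenario.

    Enrolment proceeds weekly until the cap or ``max_weeks``; interim analyses
    run every week from the first week with any observable outcomes
    (``outcome_lag_weeks + 1``) and evaluate all accumulated outcome data.
    The trial stops at the first fired rule, or for maximum duration at week
    ``max_weeks + outcome_lag_weeks`` when no rule ever fires.

    Fully reproducible: the result, including the interim trace, is a pure
    function of ``(scenario, prior, thresholds, n_draws, seed)``.
    """
    prior = prior or PriorSpec()
    thresholds = thresholds or DecisionThresholds()
    root = _as_seedseq(seed)
    lag = scenario.outcome_lag_weeks

    cohorts: list[InterimData] = []  # cohorts[j] enrolled in week j+1
    cum_c_n = cum_c_s = cum_i_n = cum_i_s = 0  # outcome-observed totals
    n_enrolled = 0
    trace: list[InterimRecord] = []

    last_week = scenario.max_weeks + lag
    for week in range(1, last_week + 1):
        # Enrolment this week
        if week <= scenario.max_weeks and n_enrolled < scenario.enrolment_cap:
            remaining = scenario.enrolment_cap - n_enrolled
            rng = np.random.default_rng(_child(root, 1, week))
            n_total = scenario.cohort_size
            if scenario.accrual == "poisson":
                n_total = int(rng.poisson(scenario.cohort_size))
                n_total += n_total % 2
            cohort = simulate_weekly_cohort(scenario, rng, n_total=min(n_total, remaining))
            cohorts.append(cohort)
            n_enrolled += cohort.control.n + cohort.intervention.n
        # Outcomes of the cohort enrolled in week (week - lag) become observable
        j = week - lag
        if 1 <= j <= len(cohorts):
            c = cohorts[j - 1]
            cum_c_n += c.control.n
            cum_c_s += c.control.successes
            cum_i_n += c.intervention.n
            cum_i_s += c.intervention.successes
        if cum_c_n + cum_i_n == 0:
            continue

        data = InterimData(
            control=ArmCounts(cum_c_n, cum_c_s), intervention=ArmCounts(cum_i_n, cum_i_s)
        )
        samples = sample_posterior(data, prior, n_draws=n_draws, seed=_child(root, 2, week))
        summary = summarize_posterior(samples, negligible_margin=thresholds.negligible_D)
        decision = evaluate_stopping(summary, thresholds)
        if decision.status is DecisionStatus.CONTINUE and week == last_week:
            decision = max_duration_decision()
        trace.append(InterimRecord(week, data, n_enrolled, summary, decision))
        if decision.status is not DecisionStatus.CONTINUE:
            return TrialResult(
                decision=decision,
                stop_week=week,
                n_enrolled_at_stop=n_enrolled,
                n_with_outcome_at_stop=cum_c_n + cum_i_n,
                interim_trace=tuple(trace),
            )

    # Unreachable for lag >= 0 with at least one enrolment week, but kept for safety
    decision = max_duration_decision()
    return TrialResult(decision, last_week, n_enrolled, cum_c_n + cum_i_n, tuple(trace))
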