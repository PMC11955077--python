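"""Prespecified efficacy and futility stopping rules.

At each weekly interim analysis the trial stops for efficacy when the
posterior probability that one arm is better exceeds threshold E (the arm
with the higher mean posterior outcome proportion is declared superior), or
for futility when the posterior probability that the absolute risk difference
is below the negligible margin D reaches threshold F.  Both rules use ">="
boundaries; a probability exactly at the threshold triggers the rule.  The
efficacy rule is two-sided: either arm can be declared superior.  On futility,
and at maximum duration, the control arm (standard care) is adopted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .posterior import PosteriorSummary

__all__ = [
    "Arm",
    "DecisionStatus",
    "DecisionThresholds",
    "Decision",
    "MarginMismatchError",
    "evaluate_stopping",
    "max_duration_decision",
]


class DecisionStatus(str, Enum):
    CONTINUE = "continue"
    STOP_EFFICACY = "stop_efficacy"
    STOP_FUTILITY = "stop_futility"
    STOP_MAX_DURATION = "stop_max_duration"


class Arm(str, Enum):
    INTERVENTION = "intervention"
    CONTROL = "control"
    NONE = "none"


class MarginMismatchError(ValueError):
    """The summary's negligible margin differs from the thresholds' D."""


@dataclass(frozen=True)
class DecisionThresholds:
    """The (E, F, D) triple governing stopping.

    efficacy_E : posterior-probability threshold for declaring one arm
        superior (default 0.95).
    futility_F : posterior-probability threshold for declaring the arms
        equivalent (default 0.95).
    negligible_D : largest absolute risk difference treated as practically
        zero, in proportion units (default 0.01, i.e. one percentage point).
    """

    efficacy_E: float = 0.95
    futility_F: float = 0.95
    negligible_D: float = 0.01

    def __post_init__(self) -> None:
        for name in ("efficacy_E", "futility_F", "negligible_D"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in the open interval (0, 1), got {v}")


@dataclass(frozen=True)
class Decision:
    status: DecisionStatus
    adopted_arm: Arm = Arm.NONE
    superior_arm: Arm = Arm.NONE

    def __post_init__(self) -> None:
        if self.status is DecisionStatus.CONTINUE and self.adopted_arm is not Arm.NONE:
            raise ValueError("a continuing trial adopts no arm")
        if self.status is DecisionStatus.STOP_EFFICACY:
            if self.superior_arm is Arm.NONE or self.adopted_arm is not self.superior_arm:
                raise ValueError("an efficacy stop adopts the superior arm")
        if self.status in (DecisionStatus.STOP_FUTILITY, DecisionStatus.STOP_MAX_DURATION):
            if self.adopted_arm is not Arm.CONTROL:
                raise ValueError("futility and max-duration stops adopt the control arm")

    def to_dict(self) -> dict:
        return {
            "status": self.status.value,
            "adopted_arm": self.adopted_arm.value,
            "superior_arm": self.superior_arm.value,
        }


def evaluate_stopping(
    summary: PosteriorSummary,
    thresholds: DecisionThresholds,
    *,
    tie_breaker: Arm = Arm.CONTROL,
) -> Decision:
    """Apply the two stopping rules to one interim posterior summary.

    Efficacy fires when ``max(P(diff > 0), P(diff < 0)) >= E``; the superior
    arm is the one with the higher posterior mean proportion (an exact tie
    goes to ``tie_breaker``, by default standard care).  Futility fires when
    ``P(|diff| < D) >= F``.  Should both fire at the same interim, efficacy
    takes precedence.  Otherwise the trial continues.

    Raises
    ------
    MarginMismatchError
        If the summary's negligible margin was not computed at the
        thresholds' D.
    """
    if summary.negligible_margin != thresholds.negligible_D:
        raise MarginMismatchError(
            f"summary margin {summary.negligible_margin} != thresholds D {thresholds.negligible_D}"
        )

    if max(summary.prob_diff_positive, summary.prob_diff_negative) >= thresholds.efficacy_E:
        if summary.mean_p_intervention > summary.mean_p_control:
            superior = Arm.INTERVENTION
        elif summary.mean_p_intervention < summary.mean_p_control:
            superior = Arm.CONTROL
        else:
            superior = tie_breaker
        return Decision(
            status=DecisionStatus.STOP_EFFICACY, adopted_arm=superior, superior_arm=superior
        )

    if summary.prob_negligible >= thresholds.futility_F:
        return Decision(status=DecisionStatus.STOP_FUTILITY, adopted_arm=Arm.CONTROL)

    return Decision(status=DecisionStatus.CONTINUE)


def max_duration_decision() -> Decision:
    """Decision at the one-year horizon: arms declared equally effective,
    control adopted."""
    return Decision(status=DecisionStatus.STOP_MAX_DURATION, adopted_arm=Arm.CONTROL)
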