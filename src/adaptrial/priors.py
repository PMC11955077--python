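"""Prior specifications for the two-arm logistic-binomial attendance model.

The model places a normal prior on the logit of the control-arm attendance
probability and a zero-mean normal prior on the log odds ratio between the
intervention and control arms.  The control prior is conventionally written
``logit(p) ~ norm(0, 0.3)`` in JAGS notation, where the second argument is a
*precision*; on the standard-deviation scale this is ``1/sqrt(0.3) ~= 1.826``,
which makes the implied prior on ``p`` close to uniform on (0, 1).  The effect
prior is neutral (odds ratio 1.0) with a wide 95% interval, by default
1/30 to 30 on the odds-ratio scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from scipy.stats import norm

__all__ = ["PriorSpec", "logor_sd_from_ci", "default_prior"]

ScaleConvention = Literal["sd", "variance", "precision"]


def logor_sd_from_ci(ci_upper: float, level: float = 0.95) -> float:
    """Standard deviation of a zero-mean normal log-odds-ratio prior from its CI.

    Given the upper endpoint of the equal-tailed credible interval at ``level``
    for the odds ratio (e.g. 30 for a 95% interval of 1/30 to 30), returns the
    standard deviation ``ln(ci_upper) / z`` where ``z`` is the standard-normal
    quantile at ``(1 + level) / 2``.

    Parameters
    ----------
    ci_upper : float
        Upper credible-interval endpoint on the odds-ratio scale; must be > 1.
    level : float
        Credible level of the interval, in (0, 1).

    Returns
    -------
    float
        Standard deviation on the log-odds-ratio scale.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if ci_upper <= 1.0:
        raise ValueError(
            f"ci_upper must exceed 1 (a neutral prior is symmetric about OR=1), got {ci_upper}"
        )
    z = norm.ppf(0.5 + level / 2.0)
    return math.log(ci_upper) / z


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the control-rate and effect (log-odds-ratio) priors.

    Attributes
    ----------
    control_logit_mean : float
        Mean of the normal prior on logit(p_control).
    control_logit_scale : float
        Scale parameter of the control prior, interpreted per
        ``control_scale_convention``.
    control_scale_convention : {"sd", "variance", "precision"}
        How ``control_logit_scale`` is read.  Default "precision" (the JAGS
        convention, under which 0.3 gives sd ~= 1.826 and an approximately
        uniform prior on the probability scale).
    effect_logor_mean : float
        Mean of the normal prior on the log odds ratio (0 = neutral).
    effect_logor_sd : float
        Standard deviation of the log-odds-ratio prior.  The default derives
        from a 95% interval of 1/30 to 30: ln(30)/1.96 ~= 1.735.
    """

    control_logit_mean: float = 0.0
    control_logit_scale: float = 0.3
    control_scale_convention: ScaleConvention = "precision"
    effect_logor_mean: float = 0.0
    effect_logor_sd: float = field(default_factory=lambda: logor_sd_from_ci(30.0, 0.95))

    def __post_init__(self) -> None:
        if self.control_logit_scale <= 0:
            raise ValueError("control_logit_scale must be strictly positive")
        if self.effect_logor_sd <= 0:
            raise ValueError("effect_logor_sd must be strictly positive")
        if self.control_scale_convention not in ("sd", "variance", "precision"):
            raise ValueError(
                "control_scale_convention must be one of 'sd', 'variance', 'precision'; "
                f"got {self.control_scale_convention!r}"
            )

    @property
    def control_logit_sd(self) -> float:
        """Control prior scale converted to a standard deviation."""
        s = self.control_logit_scale
        if self.control_scale_convention == "sd":
            return s
        if self.control_scale_convention == "variance":
            return math.sqrt(s)
        return 1.0 / math.sqrt(s)


def default_prior() -> PriorSpec:
    """The trial's prespecified prior: logit(p) ~ N(0, precision 0.3), OR CI 1/30-30."""
    return PriorSpec()
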