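import numpy as np
import pytest

from adaptrial import DecisionThresholds, PosteriorSamples, PriorSpec


@pytest.fixture
def prior() -> PriorSpec:
    return PriorSpec()


@pytest.fixture
def thresholds() -> DecisionThresholds:
    return DecisionThresholds()


@pytest.fixture
def flat_prior() -> PriorSpec:
    """Near-flat priors on the logit scale, for conjugate-oracle comparisons."""
    return PriorSpec(
        control_logit_scale=50.0, control_scale_convention="sd", effect_logor_sd=50.0
    )


def samples_from_diff(diff: np.ndarray) -> PosteriorSamples:
    """Build a PosteriorSamples whose diff vector is given, with proportions
    placed consistently around 0.5."""
    diff = np.asarray(diff, dtype=float)
    p_c = np.full_like(diff, 0.5) - diff / 2
    return PosteriorSamples(p_control=p_c, p_intervention=p_c + diff, diff=diff, n_draws=diff.size)
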