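import numpy as np
import pytest

from embaudit.datasets import (
    BehaviorVector,
    PromptSet,
    generate_linear_target,
    generate_number_prompts,
)
from embaudit.encoders import SyntheticEncoder


@pytest.fixture
def number_prompts():
    """The 0..100 step-10 concept grid (11 prompts)."""
    return generate_number_prompts(0, 100, 10)


@pytest.fixture
def dense_prompts():
    """The 0..100 step-1 concept grid (101 prompts)."""
    return generate_number_prompts(0, 100, 1)


@pytest.fixture
def linear_study(dense_prompts):
    return generate_linear_target(dense_prompts, slope=1.0, intercept=0.0,
                                  noise_sd=2.0, seed=11)


@pytest.fixture
def small_encoder():
    return SyntheticEncoder(dim=32, length_scale=1.0, distractor_fraction=0.25,
                            noise_sd=0.0, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
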