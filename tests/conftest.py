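import numpy as np
import pytest

from nlsempower import (
    moderated_mediation_model,
    moderation_model,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def study2_spec():
    """Moderated mediation model with high-reliability indicators."""
    return moderated_mediation_model("high")


@pytest.fixture(scope="session")
def moderation_spec():
    return moderation_model("high")


@pytest.fixture(scope="session")
def perfect_spec():
    """Error-free indicators: estimators should recover the population values."""
    return moderated_mediation_model("perfect")


@pytest.fixture(scope="session")
def study2_sample_large(study2_spec):
    return simulate_dataset(study2_spec, 200_000, seed=20_240)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
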