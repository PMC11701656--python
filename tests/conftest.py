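import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from coupnet import (
    generate_evidence,
    generate_gold_standard,
    generate_world,
)


@pytest.fixture(scope="session")
def small_world():
    """A 40-protein world with 20% planted couplings."""
    return generate_world(40, 0.2, seed=7)


@pytest.fixture(scope="session")
def small_evidence(small_world):
    return generate_evidence(small_world, dataset_id="d1")


@pytest.fixture(scope="session")
def small_gs(small_world):
    return generate_gold_standard(small_world, recall=1.0, fpr=0.0, seed=1)
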