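import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def apeki():
    from symbiorad.enzymes import get_enzyme

    return get_enzyme("ApeKI")


@pytest.fixture
def small_genome():
    from symbiorad.synth import random_genome

    return random_genome(50_000, 0.5, seed=12345)
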