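import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from jumbophage.config import RunConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig(seed=0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
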