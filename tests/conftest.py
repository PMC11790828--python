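import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sayolo.boxgeom import Box, BoxPair

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240612)


def random_box_array(rng: np.random.Generator, n: int) -> np.ndarray:
    """(n, 4) boxes with centers in [-50, 50] and sizes in [0.5, 30]."""
    out = np.empty((n, 4))
    out[:, :2] = rng.uniform(-50, 50, size=(n, 2))
    out[:, 2:] = rng.uniform(0.5, 30, size=(n, 2))
    return out


def random_pair(rng: np.random.Generator) -> BoxPair:
    a, b = random_box_array(rng, 2)
    return BoxPair(pred=Box(*a), gt=Box(*b))
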