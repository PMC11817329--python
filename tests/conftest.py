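import numpy as np
import pytest

from dentfuse import PROFILES, SimulatorConfig, make_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A 40-image two-detector benchmark shared by slower tests."""
    config = SimulatorConfig(n_images=40, seed=7)
    records, split = make_benchmark(
        config, [PROFILES["recall_heavy"], PROFILES["precision_heavy"]]
    )
    return records, split


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, min_size=0.02, max_size=0.3):
    """A random valid normalized box whose extent stays inside the frame."""
    w = rng.uniform(min_size, max_size)
    h = rng.uniform(min_size, max_size)
    cx = rng.uniform(w / 2, 1 - w / 2)
    cy = rng.uniform(h / 2, 1 - h / 2)
    from dentfuse import Box

    return Box(cx, cy, w, h)
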