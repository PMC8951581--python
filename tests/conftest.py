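import numpy as np
import pytest

from uqseg.phantoms import PhantomSpec, generate_phantom
from uqseg.segnet import ProbabilitySampleStack, SegNetConfig, build_network


def random_stack(rng: np.random.Generator, T: int = 7, C: int = 4,
                 shape: tuple = (5, 6, 4)) -> ProbabilitySampleStack:
    """A random softmax sample stack (Dirichlet-like via normalised gamma)."""
    raw = rng.gamma(1.0, 1.0, size=(T, C) + shape)
    probs = raw / raw.sum(axis=1, keepdims=True)
    return ProbabilitySampleStack(probs.astype(np.float32))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """One 32^3 phantom with a single tumor focus (deterministic)."""
    spec = PhantomSpec(grid_shape=(32, 32, 32), radius_range_wt=(5.0, 8.0))
    return generate_phantom(spec, seed=7)


@pytest.fixture(scope="session")
def tiny_net():
    """A small untrained network shared by shape/cost tests."""
    return build_network(SegNetConfig(base_channels=4, depth=2, seed=3))
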