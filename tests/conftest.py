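import numpy as np
import pytest

from octostack import ImageSample, PhantomConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_phantoms():
    """A small, clean 32x32 phantom set shared by the fast training tests."""
    cfg = PhantomConfig(width=32, height=32, n_layers=3,
                        boundary_smoothness=1.5, speckle_looks=8.0,
                        gaussian_sigma=0.01)
    return generate_dataset(12, cfg, seed=77), cfg


def dummy_samples(n: int, shape=(8, 8), C: int = 3, seed: int = 0):
    """Lightweight random samples for split/augment bookkeeping tests."""
    g = np.random.default_rng(seed)
    return [ImageSample(image=g.random(shape), mask=g.integers(0, C, shape),
                        source_id=f"s{i}") for i in range(n)]
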