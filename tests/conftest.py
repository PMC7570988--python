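import numpy as np
import pytest

from sleepkit import GeneratorSpec, Hypnogram, sample_hypnogram


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_hypnogram():
    """L L D D R R L L at 30-s epochs."""
    return Hypnogram(np.array([2, 2, 3, 3, 1, 1, 2, 2]), epoch_seconds=30.0)


@pytest.fixture
def night_hypnogram():
    """One 840-epoch night sampled from the prior chain."""
    return sample_hypnogram(GeneratorSpec(seed=77))


def random_hypnogram(rng, n=None, epoch_seconds=30.0):
    n = int(rng.integers(20, 200)) if n is None else n
    return Hypnogram(rng.integers(0, 4, size=n).astype(np.int8),
                     epoch_seconds=epoch_seconds)
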