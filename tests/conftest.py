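import dataclasses

import numpy as np
import pytest

import histoseg as hs


@pytest.fixture(scope="session")
def moderate_phantom():
    """64^3 moderate-noise phantom shared by the end-to-end tests."""
    spec = hs.default_specs(seed=1)["moderate_noise"]
    stack, truth, mask = hs.generate_phantom(spec)
    return spec, stack, truth, mask


@pytest.fixture(scope="session")
def small_clean_phantom():
    """32^3 noise-free phantom for fast structural tests."""
    base = hs.default_specs(seed=7)["clean"]
    spec = dataclasses.replace(
        base, grid_size=(32, 32, 32), radii=(7.0, 10.0, 13.0))
    stack, truth, mask = hs.generate_phantom(spec)
    return spec, stack, truth, mask


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_volume(rng, shape=(8, 8, 8), lo=0.0, hi=1.0):
    return hs.ScalarVolume(rng.uniform(lo, hi, size=shape))


@pytest.fixture()
def random_volume_factory(rng):
    def make(shape=(8, 8, 8), lo=0.0, hi=1.0):
        return random_volume(rng, shape, lo, hi)
    return make
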