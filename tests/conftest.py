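"""Shared fixtures: small rendered scenes reused across test modules."""

import numpy as np
import pytest

from gridstereo import synthetic


@pytest.fixture(scope="session")
def noise_free_scene():
    return synthetic.default_scene(seed=11, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noise_free_render(noise_free_scene):
    left, right, truth = synthetic.render_stereo(noise_free_scene)
    return left, right, truth


@pytest.fixture(scope="session")
def noisy_scene():
    return synthetic.default_scene(seed=12)


@pytest.fixture(scope="session")
def noisy_render(noisy_scene):
    left, right, truth = synthetic.render_stereo(noisy_scene)
    return left, right, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
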