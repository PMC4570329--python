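import numpy as np
import pytest

from rowcount.synthetic import SceneSpec, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_scene():
    """A nominal ten-plant 640x480 scene, shared across read-only tests."""
    spec = SceneSpec(seed=7)
    image, truth = render_scene(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_scene():
    """A compact five-plant scene for fast pipeline tests."""
    spec = SceneSpec(n_plants=5, width=360, height=260, plant_height=110, seed=11)
    image, truth = render_scene(spec)
    return spec, image, truth
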