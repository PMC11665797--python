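import numpy as np
import pytest

from surgipose.simulator import (
    SceneConfig,
    build_instrument,
    default_intrinsics,
    generate_sample,
)


@pytest.fixture(scope="session")
def instrument():
    return build_instrument(
        shaft_length=80.0, radius=4.0, tip_length=12.0,
        surface_density=8000, n_keypoints=10,
    )


@pytest.fixture(scope="session")
def camera():
    return default_intrinsics(480, 270)


@pytest.fixture(scope="session")
def scene_config():
    return SceneConfig(width=480, height=270, surface_density=8000)


@pytest.fixture(scope="session")
def sample(instrument, scene_config):
    return generate_sample(instrument, scene_config, np.random.default_rng(5), 0)


@pytest.fixture(scope="session")
def toy_scene_config():
    return SceneConfig(width=96, height=96, surface_density=3000, seed=1)


@pytest.fixture(scope="session")
def toy_instrument():
    return build_instrument(
        shaft_length=80.0, radius=4.0, tip_length=12.0,
        surface_density=3000, n_keypoints=10,
    )
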