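import numpy as np
import pytest

from wolfvision import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fruit_scene():
    """One moderate fruit scene with gradient, occlusion and noise."""
    spec = SceneSpec(
        width=320,
        height=240,
        n_fruits=5,
        illumination_strength=0.3,
        illumination_angle_deg=0.0,
        occlusion_fraction=0.1,
        impulse_noise_rate=0.005,
        seed=3,
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def branch_scene():
    """One branch scene with fruits, gradient and noise."""
    spec = SceneSpec(
        width=320,
        height=240,
        n_fruits=3,
        branch_present=True,
        illumination_strength=0.35,
        illumination_angle_deg=90.0,
        impulse_noise_rate=0.005,
        seed=11,
    )
    return generate_scene(spec)
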