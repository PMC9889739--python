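import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def quiet_spec():
    """Noise-free, jitter-free phantom spec: geometry is exact."""
    from orbitvae.phantom import PhantomSpec

    return PhantomSpec(noise_sd=0.0, jitter=0.0)


@pytest.fixture(scope="session")
def small_spec():
    """A small phantom grid for fast end-to-end tests."""
    from orbitvae.phantom import PhantomSpec

    return PhantomSpec(grid_shape=(24, 48, 48), muscle_radius_vox=2.0)


@pytest.fixture(scope="session")
def tiny_config():
    from orbitvae.model import ModelConfig

    return ModelConfig(input_edge=16, encoder_channels=(2, 3, 4, 5),
                       latent_dim=3, fc_hidden=8)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    from orbitvae.model import build_model

    return build_model(tiny_config, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
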