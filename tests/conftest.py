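import numpy as np
import pytest

from edofmask.optics import AberrationModel, OpticalConfig, make_pupil_grid


@pytest.fixture(scope="session")
def small_config() -> OpticalConfig:
    """64x64 pupil, 21 planes around focus — fast enough for property tests."""
    return OpticalConfig(
        grid_size=64, n_depths=21, depth_step_um=2.0, z_start_um=-20.0
    )


@pytest.fixture(scope="session")
def small_grid(small_config):
    return make_pupil_grid(small_config)


@pytest.fixture(scope="session")
def medium_config() -> OpticalConfig:
    """128x128 pupil for tests that need some lateral resolution."""
    return OpticalConfig(
        grid_size=128, n_depths=41, depth_step_um=2.0, z_start_um=-40.0
    )


@pytest.fixture(scope="session")
def medium_grid(medium_config):
    return make_pupil_grid(medium_config)


@pytest.fixture(scope="session")
def native_aberration() -> AberrationModel:
    return AberrationModel(w040=29.4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
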