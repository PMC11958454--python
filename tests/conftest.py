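import numpy as np
import pytest

from slimquant.config import PipelineConfig, SimulationConfig, StoichiometryConfig
from slimquant.simulate import simulate_confocal_timelapse, simulate_slimfield_movie


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture(scope="session")
def small_slimfield():
    """Ten-cell Slimfield movie, one 20-molecule aggregate per cell."""
    cfg = SimulationConfig(n_frames=500, rng_seed=7, dark_fraction=0.0)
    return simulate_slimfield_movie(cfg, [20] * 10, d_coeff=0.5)


@pytest.fixture(scope="session")
def vacuole_timelapse():
    cfg = SimulationConfig(image_shape=(80, 80), rng_seed=3)
    return simulate_confocal_timelapse(cfg, organelle="vacuole")


@pytest.fixture(scope="session")
def nucleus_timelapse():
    cfg = SimulationConfig(image_shape=(80, 80), rng_seed=4)
    return simulate_confocal_timelapse(cfg, organelle="nucleus")


@pytest.fixture
def default_pipeline_config():
    return PipelineConfig(stoichiometry=StoichiometryConfig(dark_fraction=0.0))
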