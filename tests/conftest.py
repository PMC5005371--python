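import numpy as np
import pytest

from pinetherm.synthetic import (
    ExperimentParams,
    SceneParams,
    default_region_layout,
    generate_experiment,
    generate_thermal_scene,
)


@pytest.fixture(scope="session")
def pswd_obs():
    """Moderate-noise soil-water-deficit table at the study design size."""
    obs, truth = generate_experiment(ExperimentParams(seed=42), model="pswd")
    return obs, truth


@pytest.fixture(scope="session")
def treatment_obs():
    """Treatment-family table with the printed stress-period main effects."""
    obs, truth = generate_experiment(ExperimentParams(seed=43), model="treatment")
    return obs, truth


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free scene without an edge-mixture band (exact-recovery case)."""
    params = SceneParams(noise_sd=0.0, edge_mix_fraction=0.0, seed=7)
    return generate_thermal_scene(params), default_region_layout(params)


@pytest.fixture(scope="session")
def noisy_scene():
    params = SceneParams(noise_sd=0.1, edge_mix_fraction=0.3, seed=11)
    return generate_thermal_scene(params), default_region_layout(params)


@pytest.fixture
def rng():
    return np.random.default_rng(20130705)
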