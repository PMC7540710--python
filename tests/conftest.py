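import numpy as np
import pytest

from mangrove_drivers.pipeline import PipelineConfig, run_pipeline
from mangrove_drivers.synthetic import (EventSpec, SceneConfig, generate_scene,
                                        noise_free)


def small_events(area_ha: float = 9.0) -> list[EventSpec]:
    return [
        EventSpec("ER", area_ha, "2003-07-15"),
        EventSpec("CM", area_ha, "2003-01-15"),
        EventSpec("ST", area_ha, "2007-06-15"),
        EventSpec("NPC", area_ha, "2007-01-15"),
        EventSpec("EWE", area_ha, "2010-07-15"),
    ]


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    """64 x 64 scene with one 9 ha event per driver; fast unit-test input."""
    return SceneConfig(grid_rows=64, grid_cols=64, event_specs=small_events(),
                       seed=11)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def default_config() -> SceneConfig:
    """Full-size 200 x 200 scene: one 90 ha event per driver (450 ha total)."""
    return SceneConfig(seed=7)


@pytest.fixture(scope="session")
def scene(default_config):
    return generate_scene(default_config)


@pytest.fixture(scope="session")
def pipeline_result(default_config):
    return run_pipeline(PipelineConfig(scene=default_config))


@pytest.fixture(scope="session")
def noise_free_result(default_config):
    return run_pipeline(PipelineConfig(scene=noise_free(default_config)))


@pytest.fixture(scope="session")
def noise_free_scene(default_config):
    return generate_scene(noise_free(default_config))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
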