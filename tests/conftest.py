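import numpy as np
import pytest

from srmd.config import StudyConfig
from srmd.grid import Grid
from srmd.scene import SceneConfig, generate_scene


@pytest.fixture
def grid10():
    """Plain 10x10 grid, 100 m cells, origin at (0, 0)."""
    return Grid(values=np.zeros((10, 10)), cell_size_m=100.0, origin_xy=(0.0, 1000.0))


@pytest.fixture(scope="session")
def small_scene():
    """Desk-scale synthetic scene: 30x30, four no-mining years + one mining year."""
    return generate_scene(
        SceneConfig(
            seed=7,
            shape=(30, 30),
            no_mining_years=[1992, 1993, 1994, 1995],
            mining_years=[2020],
        )
    )


@pytest.fixture(scope="session")
def fast_config(small_scene):
    """Trainer settings sized for the small test scene."""
    return StudyConfig(
        years=small_scene.years,
        no_mining_years=small_scene.no_mining_years,
        max_epochs=80,
        seed=7,
    )


@pytest.fixture(scope="session")
def trained_mining_model(small_scene, fast_config):
    """One trained network for the small scene's mining year."""
    from srmd.gwann import train

    year = small_scene.mining_years[0]
    results = train(
        {year: small_scene.stacks[year]},
        {year: small_scene.fvc[year]},
        fast_config,
    )
    return results[year][0]
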