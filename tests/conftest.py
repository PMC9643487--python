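import numpy as np
import pytest

from sundaland import synthetic, tcn
from sundaland.grids import TerrainGrid


@pytest.fixture(scope="session")
def site():
    """Sampling-site context used throughout (tropical, near sea level)."""
    return tcn.SiteContext(latitude=-7.466, elevation=99.0)


@pytest.fixture(scope="session")
def constants():
    return tcn.NuclideConstants()


@pytest.fixture(scope="session")
def small_landscape():
    """48x48 synthetic shelf landscape (elevation, uplift, precipitation)."""
    sc = synthetic.LandscapeScenario(seed=5, nrows=48, ncols=48)
    return synthetic.make_landscape(sc)


@pytest.fixture()
def flat_resistance():
    """Zero-resistance 40x40 grid, 1 km cells."""
    return TerrainGrid(np.zeros((40, 40)), 1000.0, variable="resistance")
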