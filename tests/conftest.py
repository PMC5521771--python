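import numpy as np
import pytest

import chitosim as cs


@pytest.fixture(scope="session")
def library():
    """The bundled synthetic nine-map library (calibration is cached)."""
    return cs.MapLibrary.synthetic()


@pytest.fixture(scope="session")
def geometry():
    return cs.GeometryParams.ideal_pyranose()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_well_map():
    """Synthetic two-basin map with a known 4.0 k_BT gap, well separated."""
    return cs.synthesize_map(
        [
            cs.Well(4.997, 2.188, 12.0, 0.2, 0.2),
            cs.Well(4.997, 2.188 - np.pi, 8.0, 0.2, 0.2),
        ],
        background=14.0,
    )
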