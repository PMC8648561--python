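import numpy as np
import pytest

from hiptomo import phantom as ph


@pytest.fixture(scope="session")
def small_jar():
    """128-px jar phantom with a coaxial tissue cylinder (one slice)."""
    return ph.build_jar_phantom(
        (2, 128, 128), 25.0, jar_radius=1400.0, jar_wall=300.0,
        tissue_radius=700.0, seed=1,
    )


@pytest.fixture(scope="session")
def foam_phantom():
    """Alveolar foam, 3-voxel walls, no consolidation."""
    return ph.build_alveolar_phantom(
        (64, 64, 64), 2.5, mean_cell_diameter=50.0, wall_thickness=7.5, seed=3
    )


@pytest.fixture(scope="session")
def ball48():
    """Voxel-centred digitized ball of radius 20 in a 49-cube."""
    z, y, x = np.mgrid[0:49, 0:49, 0:49]
    return (z - 24) ** 2 + (y - 24) ** 2 + (x - 24) ** 2 <= 20**2
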