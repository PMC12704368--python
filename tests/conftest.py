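import numpy as np
import pytest

from hsikit.calibration import CalibrationSet, attenuation, reflectance
from hsikit.cubes import RawCube, SpectralGrid
from hsikit.synthetic import (
    NoiseModel,
    TissueScene,
    simulate_tissue,
    synthetic_extinction_library,
)


@pytest.fixture(scope="session")
def full_grid():
    """The instrument's full 385-1015 nm grid in 5-nm steps (127 bands)."""
    return SpectralGrid.default()


@pytest.fixture(scope="session")
def small_grid():
    return SpectralGrid(np.array([400.0, 405.0, 410.0]))


@pytest.fixture(scope="session")
def library(full_grid):
    return synthetic_extinction_library(full_grid)


@pytest.fixture()
def raw_cube(small_grid):
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 60000, size=(4, 5, 3), dtype=np.uint16)
    return RawCube(counts=counts, grid=small_grid, integration_times=50.0)


@pytest.fixture(scope="session")
def tissue_case(library):
    """Noiseless tissue scene plus its calibrated attenuation cube."""
    names = ("HbO2", "HHb", "oxCCO", "redCCO")
    lib = library.subset(names)
    rng = np.random.default_rng(11)
    shape = (12, 12)
    fields = {n: 0.5 * rng.random(shape) for n in names}
    background = np.full(len(lib.grid), 0.2)
    scene = TissueScene(fields, lib, background_spectrum=background, seed=3)
    sample, white, dark, truth = simulate_tissue(scene)
    att = attenuation(reflectance(sample, CalibrationSet(white=white, dark=dark)))
    return {"lib": lib, "fields": fields, "background": background,
            "att": att, "truth": truth,
            "triplet": (sample, white, dark)}
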