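import numpy as np
import pytest

from dualniche.geodata import GridGeometry, OccurrenceSet, RasterGrid, PRESENCE
from dualniche.synthland import LandscapeConfig, generate_landscape, sample_occurrences


@pytest.fixture
def geometry10():
    return GridGeometry(10, 10, origin_lon=100.0, origin_lat=45.0, cell_size=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_surface(geometry, seed=0, nodata_frac=0.0):
    r = np.random.default_rng(seed)
    vals = r.random(geometry.shape)
    mask = r.random(geometry.shape) < nodata_frac
    vals = np.where(mask, 0, vals)
    return RasterGrid(vals, geometry, nodata_mask=mask)


def presence_points(geometry, rows, cols, species="sp"):
    lon = geometry.origin_lon + (np.asarray(cols) + 0.5) * geometry.cell_size
    lat = geometry.origin_lat - (np.asarray(rows) + 0.5) * geometry.cell_size
    n = len(lon)
    return OccurrenceSet(lon, lat, np.full(n, PRESENCE, object),
                         np.full(n, species, object))


@pytest.fixture(scope="session")
def small_landscape():
    """A 40x40 landscape shared by tests that only need realistic structure."""
    config = LandscapeConfig(n_rows=40, n_cols=40, seed=7)
    stack, truth = generate_landscape(config)
    return config, stack, truth


@pytest.fixture(scope="session")
def small_presences(small_landscape):
    _, _, truth = small_landscape
    return sample_occurrences(truth.host_final_truth, 120, seed=11, species_id="host")
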