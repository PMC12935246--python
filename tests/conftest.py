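import numpy as np
import pytest

from droughtnpp.grids import GridCube, GridMeta, LandCoverMap, month_range


@pytest.fixture
def meta():
    return GridMeta(n_rows=4, n_cols=5, cell_size=0.5, origin_x=110.0,
                    origin_y=40.0, crs_tag="EPSG:4326")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cube(meta, values, start=(2001, 1), units=""):
    """Cube from a (t, r, c) array with an inferred monthly time axis."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    y, m = start
    times = []
    for _ in range(n):
        times.append((y, m))
        m += 1
        if m > 12:
            m, y = 1, y + 1
    return GridCube(meta=meta, times=times, values=values, units=units)


def constant_cube(meta, value, n_months=12, start=(2001, 1)):
    return make_cube(meta, np.full((n_months, *meta.shape), float(value)),
                     start=start)


@pytest.fixture
def uniform_landcover():
    def _make(meta, code=3):
        return LandCoverMap(meta=meta,
                            classes=np.full(meta.shape, code, dtype=np.int16))
    return _make
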