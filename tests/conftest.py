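import datetime as dt

import numpy as np
import pytest

from casafuse.grids import GridSpec, RasterGrid, RasterSeries


@pytest.fixture
def tiny_spec() -> GridSpec:
    return GridSpec(4, 4, origin_x=500000.0, origin_y=4540000.0,
                    pixel_size_x=10.0, pixel_size_y=-10.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_series(values_per_date, dates=None, spec=None) -> RasterSeries:
    """Stack 2-D arrays into a RasterSeries with simple dates."""
    arrays = [np.asarray(v, dtype=float) for v in values_per_date]
    if spec is None:
        spec = GridSpec(*arrays[0].shape)
    if dates is None:
        dates = [dt.date(2025, 6, 1) + dt.timedelta(days=16 * i)
                 for i in range(len(arrays))]
    return RasterSeries(list(dates), [RasterGrid(spec, a) for a in arrays])


@pytest.fixture(scope="session")
def default_run():
    """The default synthetic-scene pipeline run (seed 42), shared by the
    end-to-end acceptance checks."""
    from casafuse.pipeline import default_config, run_pipeline

    return run_pipeline(default_config(42))
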