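import numpy as np
import pandas as pd
import pytest

import maxrange as mx


@pytest.fixture(scope="session")
def small_grid() -> mx.GridSpec:
    return mx.GridSpec(lon_min=0.0, lat_min=0.0, n_cols=12, n_rows=10, cell_size=0.5)


@pytest.fixture(scope="session")
def full_mask(small_grid) -> mx.RegionMask:
    return mx.RegionMask(grid=small_grid, member=np.ones(small_grid.shape, dtype=bool))


@pytest.fixture(scope="session")
def world() -> mx.SyntheticWorld:
    """A 40x40 synthetic world with a 2-variable niche and 2 nuisance layers."""
    grid = mx.GridSpec(lon_min=0.0, lat_min=0.0, n_cols=40, n_rows=40, cell_size=0.5)
    return mx.make_world(grid=grid, n_climate=4, n_active=2, n_blobs=2, seed=11)


@pytest.fixture(scope="session")
def occurrences(world) -> pd.DataFrame:
    return mx.simulate_species(world, n_records=60, seed=21)


def records_table(lons, lats, years, species="Testia exempli", flags=None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "species": species,
            "decimalLongitude": lons,
            "decimalLatitude": lats,
            "year": years,
        }
    )
    if flags is not None:
        df["flags"] = flags
    return df
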