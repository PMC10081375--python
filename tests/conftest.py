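"""Shared fixtures: a small synthetic world reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import peilink as pl
from peilink.features import build_feature_table
from peilink.grids import Raster
from peilink.synthetic import ClimateField, TerrainModel


@pytest.fixture(scope="session")
def world():
    """Compact study world: 12 areas, 50 facilities, 15 noiseless monitors."""
    region = pl.generate_region(seed=11, n_areas=12, n_tracts=40, extent_km=(150, 150))
    inventory = pl.generate_emissions(region, n_facilities=50, seed=12)
    climate = pl.generate_climate(region, seed=13)
    terrain = pl.generate_terrain(region, seed=14)
    params = pl.DispersionParams()
    oracle = pl.make_oracle(inventory, climate, terrain, params)
    monitors = pl.sample_monitors(region, oracle, n_sites=15, noise_cv=0.0, seed=15)
    return {"region": region, "inventory": inventory, "climate": climate,
            "terrain": terrain, "params": params, "oracle": oracle,
            "monitors": monitors}


@pytest.fixture(scope="session")
def mercury_training(world):
    """Feature table + monitor records for one chemical across all years."""
    monitors = world["monitors"]
    rec = monitors[monitors["chemical"] == "mercury"].reset_index(drop=True)
    sites = (monitors[["site_id", "x", "y"]].drop_duplicates("site_id")
             .rename(columns={"site_id": "receptor_id"}))
    tables = [build_feature_table(world["inventory"], world["climate"],
                                  world["terrain"], sites, "mercury", int(y))
              for y in world["region"].years]
    return pd.concat(tables, ignore_index=True), rec


@pytest.fixture(scope="session")
def trained_net(mercury_training):
    from peilink.network import TrainConfig, train

    table, rec = mercury_training
    return train(table, rec, TrainConfig(epochs=300, seed=3))


def make_uniform_climate(extent, years, temp=15.0, humidity=0.4,
                         sector_freqs=None, ncells=3):
    """Hand-built climate with a chosen wind histogram in every cell."""
    x0, y0, x1, y1 = extent
    cell = max(x1 - x0, y1 - y0) / ncells
    nrows = ncols = ncells
    if sector_freqs is None:
        sector_freqs = np.full(16, 1.0 / 16.0)
    sector_freqs = np.asarray(sector_freqs, dtype=float)
    grid = Raster(x0, y0, cell, np.zeros((nrows, ncols)))
    mk = lambda v: Raster(x0, y0, cell, np.full((nrows, ncols), float(v)))
    freq = np.broadcast_to(sector_freqs, (nrows, ncols, len(sector_freqs))).copy()
    return ClimateField(years=tuple(years), grid=grid,
                        temperature={y: mk(temp) for y in years},
                        humidity={y: mk(humidity) for y in years},
                        wind_u={y: mk(0.0) for y in years},
                        wind_v={y: mk(0.0) for y in years},
                        sector_freq={y: freq.copy() for y in years})


def make_flat_terrain(extent, elev=1000.0, ncells=3):
    x0, y0, x1, y1 = extent
    cell = max(x1 - x0, y1 - y0) / ncells
    return TerrainModel(raster=Raster(x0, y0, cell,
                                      np.full((ncells, ncells), float(elev))))
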