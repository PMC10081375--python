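"""Simulate a synthetic study region and summarize what it contains.

Generates the default-style world at a reduced size: a population-weighted
small-area partition, an industrial point-source inventory, climate and
terrain fields, and a monitoring network whose records follow the built-in
dispersion ground truth.
"""

import numpy as np

import peilink as pl

region = pl.generate_region(seed=1, n_areas=30, n_tracts=80, extent_km=(200, 200))
inventory = pl.generate_emissions(region, n_facilities=120, seed=2)
climate = pl.generate_climate(region, seed=3)
terrain = pl.generate_terrain(region, seed=4)
oracle = pl.make_oracle(inventory, climate, terrain)
monitors = pl.sample_monitors(region, oracle, n_sites=25, noise_cv=0.15, seed=5)

areas_km2 = np.array([p.area for p in region.areas]) / 1e6
print(f"small areas: {len(region.areas)} covering "
      f"{areas_km2.sum():.0f} km^2 (extent 200x200 km)")
print(f"area sizes km^2: min {areas_km2.min():.0f}, median "
      f"{np.median(areas_km2):.0f}, max {areas_km2.max():.0f}")
print(f"facilities reporting at least one metal: "
      f"{inventory.emissions['facility_id'].nunique()} of {len(inventory.facilities)}")
print(f"monitor records: {len(monitors)} "
      f"({monitors['site_id'].nunique()} sites x 10 chemicals x 5 years)")
hg = monitors[monitors["chemical"] == "mercury"]["measured_value"]
print(f"mercury record mean +/- sd: {hg.mean():.3f} +/- {hg.std():.3f} "
      "(arbitrary concentration-index units)")
# Small areas are Voronoi cells of population-weighted points, so sizes vary
# by two orders of magnitude: dense 'urban' places get many small areas.
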