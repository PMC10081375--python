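"""Areal interpolation of census-style covariates to small areas.

Tract-level *counts* (population, female, less-than-high-school, unmarried,
race/ethnicity categories) are reaggregated to the small-area partition by
simple area weighting: each tract's counts are split across areas in
proportion to intersection area, then converted to percentages of the
interpolated population.  Counts are interpolated, never rates, so total
population (and every other count) is conserved exactly — the
mass-preserving (pycnophylactic) property.

A tract whose geometry misses every area (possible with malformed inputs)
is assigned, with a warning, to the area nearest its centroid so no mass is
lost.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from shapely.strtree import STRtree

__all__ = [
    "RACE_CATEGORIES",
    "REFERENCE_RACE",
    "ADJUSTMENT_COLUMNS",
    "TRACT_COUNT_COLUMNS",
    "areal_interpolate",
]

#: race/ethnicity composition categories (shares sum to 1)
RACE_CATEGORIES = ("hispanic", "white", "native_american", "other")
#: category dropped from regression designs to avoid exact collinearity
REFERENCE_RACE = "white"

#: covariate columns entering adjusted regression models (K-1 race shares)
ADJUSTMENT_COLUMNS = (
    "pct_female",
    "pct_less_than_hs",
    "pct_unmarried",
) + tuple(f"race_{c}" for c in RACE_CATEGORIES if c != REFERENCE_RACE)

TRACT_COUNT_COLUMNS = (
    "population",
    "n_female",
    "n_less_than_hs",
    "n_unmarried",
) + tuple(f"n_{c}" for c in RACE_CATEGORIES)


def _validate_tracts(tract_table: pd.DataFrame) -> None:
    missing = [c for c in ("tract_id",) + TRACT_COUNT_COLUMNS if c not in tract_table.columns]
    if missing:
        raise ValueError(f"tract table missing required columns: {missing}")
    counts = tract_table[list(TRACT_COUNT_COLUMNS)].to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("tract counts must be non-negative")
    pop = tract_table["population"].to_numpy(dtype=float)
    for col in TRACT_COUNT_COLUMNS[1:]:
        if (tract_table[col].to_numpy(dtype=float) > pop + 1e-9).any():
            raise ValueError(f"tract column {col!r} exceeds population")


def intersection_weights(tract_geoms, area_geoms) -> np.ndarray:
    """(n_tracts, n_areas) share of each tract's area inside each area."""
    tree = STRtree(list(area_geoms))
    W = np.zeros((len(tract_geoms), len(area_geoms)))
    for t, tg in enumerate(tract_geoms):
        for a in tree.query(tg):
            inter = tg.intersection(area_geoms[a])
            if not inter.is_empty:
                W[t, a] = inter.area
    tot = W.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Wn = np.where(tot > 0, W / np.where(tot > 0, tot, 1.0), 0.0)
    return Wn


def areal_interpolate(tract_table: pd.DataFrame, tract_geoms, area_ids, area_geoms) -> pd.DataFrame:
    """Reaggregate tract counts to small areas, returning percentage covariates.

    Returns a DataFrame with one row per area: ``area_id``, interpolated
    ``population``, ``pct_female``, ``pct_less_than_hs``, ``pct_unmarried``
    (percent of population, 0-100) and one ``race_<category>`` share column
    per category (shares sum to 1).
    """
    _validate_tracts(tract_table)
    if len(tract_table) != len(tract_geoms):
        raise ValueError("tract table and tract geometries differ in length")
    W = intersection_weights(tract_geoms, area_geoms)
    lost = np.flatnonzero(W.sum(axis=1) < 1e-12)
    if len(lost):
        warnings.warn(
            f"{len(lost)} tract(s) intersect no area; assigning each to the nearest area",
            stacklevel=2,
        )
        for t in lost:
            cen = tract_geoms[t].centroid
            dists = [cen.distance(g) for g in area_geoms]
            W[t, int(np.argmin(dists))] = 1.0

    counts = tract_table[list(TRACT_COUNT_COLUMNS)].to_numpy(dtype=float)
    area_counts = W.T @ counts  # (n_areas, n_count_cols)
    out = pd.DataFrame({"area_id": list(area_ids)})
    cols = dict(zip(TRACT_COUNT_COLUMNS, area_counts.T))
    pop = cols["population"]
    safe_pop = np.where(pop > 0, pop, 1.0)
    out["population"] = pop
    out["pct_female"] = 100.0 * cols["n_female"] / safe_pop
    out["pct_less_than_hs"] = 100.0 * cols["n_less_than_hs"] / safe_pop
    out["pct_unmarried"] = 100.0 * cols["n_unmarried"] / safe_pop
    race_tot = sum(cols[f"n_{c}"] for c in RACE_CATEGORIES)
    safe_race = np.where(race_tot > 0, race_tot, 1.0)
    for c in RACE_CATEGORIES:
        out[f"race_{c}"] = cols[f"n_{c}"] / safe_race
    return out
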