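"""Gridded exposure surfaces and small-area aggregation.

The exposure model is evaluated at the centroids of a regular grid (4050 m
cells by default) covering the study extent; per-area exposure is the
unweighted mean of the cells whose centroids fall inside the area — the
population is assumed evenly distributed within each small area.  Centroids
on a shared boundary are owned by the area with the lexicographically
smallest id (deterministic half-open rule).  An area too small to contain
any centroid falls back, with a warning, to an area-weighted mean over the
cells it intersects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import STRtree, points as shp_points
from shapely.geometry import box

from .grids import Raster

__all__ = [
    "GridSpec",
    "build_grid",
    "predict_surface",
    "aggregate_to_areas",
    "aggregate_surface",
    "multi_year_average",
    "exposure_table",
]


@dataclass
class GridSpec:
    """Regular prediction grid; cells are ``cell_m`` squares, row 0 north."""

    xll: float
    yll: float
    cell_m: float
    nrows: int
    ncols: int

    @classmethod
    def for_region(cls, region, cell_m: float = 4050.0) -> "GridSpec":
        if cell_m <= 0:
            raise ValueError("cell size must be positive")
        x0, y0, _, _ = region.extent
        return cls(xll=x0, yll=y0, cell_m=float(cell_m),
                   nrows=int(np.ceil(region.height / cell_m)),
                   ncols=int(np.ceil(region.width / cell_m)))

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    def centroid_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (row-major, north first) centroid coordinates."""
        cs = self.cell_m
        xs = self.xll + (np.arange(self.ncols) + 0.5) * cs
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * cs
        X, Y = np.meshgrid(xs, ys)
        return X.ravel(), Y.ravel()

    def empty_raster(self) -> Raster:
        return Raster(xll=self.xll, yll=self.yll, cellsize=self.cell_m,
                      data=np.full((self.nrows, self.ncols), np.nan))

    def cell_box(self, flat_index: int):
        r, c = divmod(int(flat_index), self.ncols)
        x0 = self.xll + c * self.cell_m
        y1 = self.yll + (self.nrows - r) * self.cell_m
        return box(x0, y1 - self.cell_m, x0 + self.cell_m, y1)

    def assign_centroids(self, area_ids, areas) -> np.ndarray:
        """Area index owning each centroid (-1 = none), smallest-id tie-break."""
        cx, cy = self.centroid_arrays()
        pts = shp_points(np.column_stack([cx, cy]))
        tree = STRtree(pts)
        assign = np.full(self.n_cells, -1, dtype=int)
        for k in sorted(range(len(areas)), key=lambda i: str(area_ids[i])):
            hits = tree.query(areas[k], predicate="covers")
            free = hits[assign[hits] == -1]
            assign[free] = k
        return assign


def build_grid(region, cell_m: float = 4050.0) -> GridSpec:
    """Prediction grid covering the region extent (rows/cols = ceil(extent/cell))."""
    return GridSpec.for_region(region, cell_m)


def predict_surface(net, grid: GridSpec, inventory, climate, terrain,
                    chemical: str, year: int, chunk: int = 512) -> Raster:
    """Exposure surface: the model's PEI at every cell centroid.

    ``net`` is anything exposing ``pei_at_points(x, y, inventory, climate,
    terrain, chemical, year)`` — a trained network or a ground-truth oracle
    adapter.  Pure function of its inputs.
    """
    cx, cy = grid.centroid_arrays()
    vals = np.empty(grid.n_cells)
    for lo in range(0, grid.n_cells, chunk):
        hi = min(lo + chunk, grid.n_cells)
        vals[lo:hi] = net.pei_at_points(cx[lo:hi], cy[lo:hi], inventory,
                                        climate, terrain, chemical, year)
    out = grid.empty_raster()
    out.data = vals.reshape(grid.nrows, grid.ncols)
    return out


def aggregate_to_areas(cell_values: np.ndarray, assign: np.ndarray, area_ids,
                       grid: GridSpec | None = None, areas=None) -> np.ndarray:
    """Per-area unweighted mean of cell values by centroid membership.

    ``assign`` maps each flattened cell to an area index (-1 = outside).
    NaN cells are excluded.  Areas with no contributing centroid fall back to
    an area-weighted intersection mean (requires ``grid`` and ``areas``);
    with no coverage at all, an error names the area.
    """
    vals = np.asarray(cell_values, dtype=float).ravel()
    n_areas = len(area_ids)
    out = np.full(n_areas, np.nan)
    ok = (assign >= 0) & np.isfinite(vals)
    sums = np.bincount(assign[ok], weights=vals[ok], minlength=n_areas)
    cnts = np.bincount(assign[ok], minlength=n_areas)
    has = cnts > 0
    out[has] = sums[has] / cnts[has]
    for k in np.flatnonzero(~has):
        if grid is None or areas is None:
            raise ValueError(f"area {area_ids[k]!r} contains no cell centroid")
        warnings.warn(f"area {area_ids[k]!r} contains no cell centroid; "
                      "falling back to area-weighted cell intersection", stacklevel=2)
        poly = areas[k]
        cs = grid.cell_m
        c0 = max(0, int((poly.bounds[0] - grid.xll) // cs))
        c1 = min(grid.ncols - 1, int((poly.bounds[2] - grid.xll) // cs))
        r_top = grid.yll + grid.nrows * cs
        r0 = max(0, int((r_top - poly.bounds[3]) // cs))
        r1 = min(grid.nrows - 1, int((r_top - poly.bounds[1]) // cs))
        w_sum = v_sum = 0.0
        for r in range(r0, r1 + 1):
            for c in range(c0, c1 + 1):
                idx = r * grid.ncols + c
                if not np.isfinite(vals[idx]):
                    continue
                w = poly.intersection(grid.cell_box(idx)).area
                w_sum += w
                v_sum += w * vals[idx]
        if w_sum == 0.0:
            raise ValueError(f"area {area_ids[k]!r} has no grid coverage")
        out[k] = v_sum / w_sum
    return out


def aggregate_surface(surface: Raster, area_ids, areas) -> np.ndarray:
    """Aggregate a surface raster to per-area means (centroid rule)."""
    grid = GridSpec(xll=surface.xll, yll=surface.yll, cell_m=surface.cellsize,
                    nrows=surface.nrows, ncols=surface.ncols)
    assign = grid.assign_centroids(area_ids, areas)
    return aggregate_to_areas(surface.data, assign, area_ids, grid=grid, areas=areas)


def multi_year_average(annual: pd.DataFrame) -> pd.DataFrame:
    """Equal-weight mean over years of a long (area_id, chemical, year, pei) table."""
    req = {"area_id", "chemical", "year", "pei"}
    if not req.issubset(annual.columns):
        raise ValueError(f"annual table must have columns {sorted(req)}")
    return (annual.groupby(["area_id", "chemical"], as_index=False)["pei"].mean()
            .rename(columns={"pei": "pei_mean"}))


def exposure_table(annual: pd.DataFrame) -> pd.DataFrame:
    """Annual rows plus 'mean' rows, the on-disk exposures.csv layout."""
    mean = multi_year_average(annual).rename(columns={"pei_mean": "pei"})
    mean.insert(2, "year", "mean")
    out = pd.concat([annual[["area_id", "chemical", "year", "pei"]], mean],
                    ignore_index=True)
    return out.sort_values(["chemical", "area_id", "year"], key=lambda s: s.astype(str),
                           ignore_index=True)
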