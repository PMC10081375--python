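"""Synthetic study region with a known dispersion ground truth.

This module generates everything the exposure/association pipeline consumes —
point emission sources, a sparse monitoring network, annual climate fields, a
terrain model, a population-weighted small-area partition, and small-area
low-birth-weight (LBW) outcomes — together with a :class:`TruthBundle`
recording the quantities the pipeline is supposed to recover (true per-area
exposures and the injected per-IQR outcome effects).

Ground-truth concentrations come from a modified exponential-decay plume::

    C(i) = scale * sum_j EM_jk * exp(-D_ij / lambda)
                        * (1 + a * W_ij) * u(ED_ij) * m(T_i, H_i)

additive over sources, with a downwind-alignment enhancement ``W`` (the same
wind index the exposure features use), and mild smooth terrain/climate
modifiers ``u`` and ``m`` bounded in [0.5, 1.5].  This is not an atmospheric
chemistry model; it is a smooth, additive, cheap surrogate with the
qualitative structure (distance decay, downwind enhancement, terrain and
climate modulation) a source-receptor exposure model has to learn.

Defaults mirror the study conditions the pipeline targets: 108 small areas,
369 facilities, 63 monitoring sites, ten PM2.5 metal components, five years.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from . import covariates as cov
from .features import N_WIND_SECTORS, SourceSet, pair_feature_block, sector_angles
from .geometry import bounded_voronoi
from .grids import Raster

__all__ = [
    "CHEMICALS",
    "StudyRegion",
    "EmissionInventory",
    "ClimateField",
    "TerrainModel",
    "DispersionParams",
    "TruthBundle",
    "generate_region",
    "generate_emissions",
    "generate_climate",
    "generate_terrain",
    "generate_tracts",
    "generate_outcomes",
    "dispersion_oracle",
    "oracle_at_points",
    "make_oracle",
    "sample_monitors",
    "true_area_exposures",
]

#: the ten PM2.5 metal components shared between emission and monitor data
CHEMICALS = (
    "barium", "chromium", "cobalt", "copper", "lead",
    "manganese", "nickel", "mercury", "vanadium", "zinc",
)

DEFAULT_YEARS = (2012, 2013, 2014, 2015, 2016)


# ---------------------------------------------------------------------------
# study region
# ---------------------------------------------------------------------------

@dataclass
class StudyRegion:
    """Rectangular study region with nested polygon partitions.

    ``areas`` is the small-area partition used for outcome analysis (built on
    population, so areas are small where people are); ``tracts`` is a finer,
    independently drawn partition standing in for census tracts.
    ``pop_centers`` holds the Gaussian population mixture (x, y, sigma_m,
    amplitude) from which seed points, monitor sites and facility locations
    are preferentially drawn.
    """

    extent: tuple[float, float, float, float]
    years: tuple[int, ...]
    area_ids: list[str]
    areas: list[Polygon]
    area_weights: np.ndarray
    tract_ids: list[str]
    tracts: list[Polygon]
    tract_weights: np.ndarray
    pop_centers: np.ndarray
    pop_background: float
    grid_res_m: float
    seed: int

    @property
    def width(self) -> float:
        return self.extent[2] - self.extent[0]

    @property
    def height(self) -> float:
        return self.extent[3] - self.extent[1]

    def contains(self, x, y) -> np.ndarray:
        x0, y0, x1, y1 = self.extent
        return (np.asarray(x) >= x0) & (np.asarray(x) <= x1) & \
               (np.asarray(y) >= y0) & (np.asarray(y) <= y1)

    def population_density(self, x, y) -> np.ndarray:
        """Unnormalized population density (urban Gaussian mixture + floor)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        dens = np.full(np.broadcast(x, y).shape, self.pop_background, dtype=float)
        for cx, cy, sig, amp in self.pop_centers:
            r2 = (x - cx) ** 2 + (y - cy) ** 2
            dens = dens + amp * np.exp(-0.5 * r2 / sig**2)
        return dens

    def partition_coverage_error(self) -> float:
        """Relative |union(areas) - extent| area mismatch (should be ~0)."""
        total = sum(p.area for p in self.areas)
        ext = self.width * self.height
        return abs(total - ext) / ext


def _sample_from_density(rng, region_like, n, extent, max_density):
    """Rejection-sample n points from the population density."""
    x0, y0, x1, y1 = extent
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(4 * (n - got), 64)
        cand = np.column_stack([rng.uniform(x0, x1, m), rng.uniform(y0, y1, m)])
        dens = region_like(cand[:, 0], cand[:, 1])
        keep = cand[rng.random(m) * max_density < dens]
        take = min(len(keep), n - got)
        out[got:got + take] = keep[:take]
        got += take
    return out


def generate_region(seed: int = 0, n_areas: int = 108, n_tracts: int = 300,
                    extent_km: tuple[float, float] = (400.0, 400.0),
                    grid_res_m: float = 4000.0,
                    years: tuple[int, ...] = DEFAULT_YEARS,
                    n_pop_centers: int = 6) -> StudyRegion:
    """Generate a study region as population-weighted Voronoi partitions.

    Small areas are Voronoi cells of points sampled from an urban-mixture
    population density, so dense places get many small areas — areas are
    built on population size rather than land area.  Deterministic for a
    fixed seed.
    """
    if n_areas < 1 or n_tracts < 1:
        raise ValueError("n_areas and n_tracts must be positive")
    if min(extent_km) < 20.0:
        raise ValueError("extent must be at least 20 km per side")
    if grid_res_m <= 0:
        raise ValueError("grid_res_m must be positive")
    if not years:
        raise ValueError("years must be non-empty")
    rng = np.random.default_rng(seed)
    w, h = extent_km[0] * 1000.0, extent_km[1] * 1000.0
    extent = (0.0, 0.0, w, h)

    cx = rng.uniform(0.15 * w, 0.85 * w, n_pop_centers)
    cy = rng.uniform(0.15 * h, 0.85 * h, n_pop_centers)
    sig = rng.uniform(20e3, 60e3, n_pop_centers)
    amp = rng.uniform(0.5, 2.0, n_pop_centers)
    pop_centers = np.column_stack([cx, cy, sig, amp])
    background = 0.05

    def density(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d = np.full(np.broadcast(x, y).shape, background, dtype=float)
        for px, py, s, a in pop_centers:
            d = d + a * np.exp(-0.5 * ((x - px) ** 2 + (y - py) ** 2) / s**2)
        return d

    max_density = background + amp.sum()

    def partition(n, prefix):
        if n == 1:
            return [f"{prefix}001"], [box(*extent)], np.array([1.0])
        pts = _sample_from_density(rng, density, n, extent, max_density)
        polys = bounded_voronoi(pts, extent)
        ids = [f"{prefix}{i + 1:03d}" for i in range(n)]
        wts = density(pts[:, 0], pts[:, 1])
        return ids, polys, wts / wts.sum()

    area_ids, areas, area_w = partition(n_areas, "SA")
    tract_ids, tracts, tract_w = partition(n_tracts, "TR")
    return StudyRegion(extent=extent, years=tuple(int(y) for y in years),
                       area_ids=area_ids, areas=areas, area_weights=area_w,
                       tract_ids=tract_ids, tracts=tracts, tract_weights=tract_w,
                       pop_centers=pop_centers, pop_background=background,
                       grid_res_m=float(grid_res_m), seed=int(seed))


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

@dataclass
class EmissionInventory:
    """Point-source inventory: facilities plus per-(chemical, year) masses.

    ``emissions`` holds only rows with positive total mass; a (facility,
    chemical) pair absent from it emits zero — facilities report only the
    chemicals they actually release.
    """

    facilities: pd.DataFrame   # facility_id, x, y
    emissions: pd.DataFrame    # facility_id, chemical, year, fugitive_kg, stack_kg
    chemicals: tuple[str, ...]
    years: tuple[int, ...]

    def __post_init__(self) -> None:
        em = self.emissions
        if len(em) and ((em["fugitive_kg"] < 0).any() or (em["stack_kg"] < 0).any()):
            raise ValueError("emission masses must be non-negative")
        self._loc = self.facilities.set_index("facility_id")[["x", "y"]]
        self._by: dict[tuple[str, int], tuple] = {}
        if len(em):
            em = em.assign(total=em["fugitive_kg"] + em["stack_kg"])
            for (chem, year), grp in em[em["total"] > 0].groupby(["chemical", "year"]):
                ids = grp["facility_id"].to_numpy()
                xy = self._loc.loc[ids]
                self._by[(chem, int(year))] = (
                    ids,
                    xy["x"].to_numpy(dtype=float),
                    xy["y"].to_numpy(dtype=float),
                    grp["total"].to_numpy(dtype=float),
                )

    def positive_sources(self, chemical: str, year: int):
        """(ids, x, y, fugitive+stack mass) of sources emitting this pair."""
        if chemical not in self.chemicals:
            raise KeyError(f"chemical {chemical!r} not in inventory")
        empty = (np.empty(0, dtype=object), np.empty(0), np.empty(0), np.empty(0))
        return self._by.get((chemical, int(year)), empty)

    def absent_pairs(self) -> list[tuple[str, int]]:
        """(chemical, year) pairs with no positive emission anywhere."""
        return [(c, y) for c in self.chemicals for y in self.years
                if (c, y) not in self._by]

    def subset(self, facility_ids) -> "EmissionInventory":
        """Inventory restricted to the given facilities (for additivity checks)."""
        keep = set(facility_ids)
        return EmissionInventory(
            facilities=self.facilities[self.facilities["facility_id"].isin(keep)].reset_index(drop=True),
            emissions=self.emissions[self.emissions["facility_id"].isin(keep)].reset_index(drop=True),
            chemicals=self.chemicals, years=self.years,
        )


def generate_emissions(region: StudyRegion, n_facilities: int = 369,
                       chemicals: tuple[str, ...] = CHEMICALS, seed: int = 0,
                       zero_fraction: float = 0.7, log_mean_kg: float = 5.0,
                       log_sd_kg: float = 1.5, year_jitter_sd: float = 0.2,
                       urban_fraction: float = 0.6) -> EmissionInventory:
    """Synthetic facility inventory with log-normal annual emissions.

    A (facility, chemical) pair is a structural zero with probability
    ``zero_fraction`` (facilities release only a few of the ten metals);
    reported pairs carry a log-normal base mass split into fugitive and
    stack shares, with mild year-to-year jitter.
    """
    if n_facilities < 1:
        raise ValueError("n_facilities must be >= 1")
    if not chemicals:
        raise ValueError("chemicals must be non-empty")
    if not 0.0 <= zero_fraction <= 1.0:
        raise ValueError("zero_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = region.extent
    n_urban = int(round(urban_fraction * n_facilities))
    max_density = region.pop_background + region.pop_centers[:, 3].sum()
    pts_urban = _sample_from_density(rng, region.population_density, n_urban,
                                     region.extent, max_density)
    pts_rand = np.column_stack([
        rng.uniform(x0, x1, n_facilities - n_urban),
        rng.uniform(y0, y1, n_facilities - n_urban),
    ])
    pts = np.vstack([pts_urban, pts_rand])
    fac_ids = np.array([f"F{i + 1:04d}" for i in range(n_facilities)], dtype=object)
    facilities = pd.DataFrame({"facility_id": fac_ids, "x": pts[:, 0], "y": pts[:, 1]})

    K = len(chemicals)
    reported = rng.random((n_facilities, K)) >= zero_fraction
    base = rng.lognormal(log_mean_kg, log_sd_kg, (n_facilities, K))
    fug_share = rng.beta(2.0, 3.0, (n_facilities, K))
    rows = []
    fi, ki = np.nonzero(reported)
    for year in region.years:
        jitter = rng.lognormal(0.0, year_jitter_sd, len(fi))
        total = base[fi, ki] * jitter
        rows.append(pd.DataFrame({
            "facility_id": fac_ids[fi],
            "chemical": np.asarray(chemicals, dtype=object)[ki],
            "year": int(year),
            "fugitive_kg": total * fug_share[fi, ki],
            "stack_kg": total * (1.0 - fug_share[fi, ki]),
        }))
    emissions = (pd.concat(rows, ignore_index=True) if rows and len(fi) else
                 pd.DataFrame(columns=["facility_id", "chemical", "year",
                                       "fugitive_kg", "stack_kg"]))
    return EmissionInventory(facilities=facilities, emissions=emissions,
                             chemicals=tuple(chemicals), years=region.years)


# ---------------------------------------------------------------------------
# climate and terrain
# ---------------------------------------------------------------------------

def _smooth_field(rng, xs, ys, amplitude=1.0, length_m=120e3, n_modes=6):
    """Smooth random field on a grid: a low-order random Fourier series."""
    X, Y = np.meshgrid(xs, ys)
    out = np.zeros_like(X)
    for _ in range(n_modes):
        ang = rng.uniform(0, 2 * np.pi)
        k = rng.uniform(0.5, 1.5) * 2 * np.pi / length_m
        phase = rng.uniform(0, 2 * np.pi)
        out += rng.normal(0, 1) * np.sin(k * (X * np.cos(ang) + Y * np.sin(ang)) + phase)
    sd = out.std()
    if sd > 0:
        out *= amplitude / (sd * np.sqrt(1.0))
    return out


@dataclass
class ClimateField:
    """Annual gridded climate: temperature, humidity, wind, sector histograms.

    ``sector_freq[year]`` has shape (nrows, ncols, 16): the frequency with
    which wind at a cell blows *toward* each of 16 compass sectors (east = 0,
    counter-clockwise); frequencies are non-negative and sum to 1 per cell.
    """

    years: tuple[int, ...]
    grid: Raster  # geometry template
    temperature: dict[int, Raster]
    humidity: dict[int, Raster]
    wind_u: dict[int, Raster]
    wind_v: dict[int, Raster]
    sector_freq: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        for y in self.years:
            h = self.humidity[y].data
            if np.nanmin(h) < 0 or np.nanmax(h) > 1:
                raise ValueError(f"humidity outside [0, 1] for year {y}")
            f = self.sector_freq[y]
            if (f < 0).any() or not np.allclose(f.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"sector frequencies invalid for year {y}")

    def _year(self, year: int) -> int:
        year = int(year)
        if year not in self.temperature:
            raise KeyError(f"year {year} not in climate field {self.years}")
        return year

    def temperature_at(self, x, y, year):
        return self.temperature[self._year(year)].sample_bilinear(x, y)

    def humidity_at(self, x, y, year):
        return np.clip(self.humidity[self._year(year)].sample_bilinear(x, y), 0.0, 1.0)

    def sector_freq_at(self, x, y, year):
        r, c = self.grid.sample_nearest_cell(x, y)
        return self.sector_freq[self._year(year)][r, c]


def generate_climate(region: StudyRegion, seed: int = 0, cell_m: float = 20000.0,
                     mean_temp_c: float = 13.0, temp_amp_c: float = 3.0,
                     humidity_mean: float = 0.35, wind_kappa: float = 2.0,
                     mean_speed_ms: float = 4.0) -> ClimateField:
    """Smooth annual climate fields with a von-Mises-like wind rose per cell."""
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = region.extent
    ncols = max(2, int(np.ceil(region.width / cell_m)))
    nrows = max(2, int(np.ceil(region.height / cell_m)))
    template = Raster(xll=x0, yll=y0, cellsize=cell_m, data=np.zeros((nrows, ncols)))
    xs, ys = template.cell_centers()
    lat_gradient = -3.0 * ((ys[:, None] - y0) / region.height - 0.5)  # cooler north

    temperature, humidity, wind_u, wind_v, sector_freq = {}, {}, {}, {}, {}
    ang = sector_angles(N_WIND_SECTORS)
    for year in region.years:
        t = (mean_temp_c + rng.normal(0, 0.5) + lat_gradient
             + _smooth_field(rng, xs, ys, temp_amp_c))
        logit = np.log(humidity_mean / (1 - humidity_mean))
        h = 1.0 / (1.0 + np.exp(-(logit + _smooth_field(rng, xs, ys, 0.6))))
        theta0 = rng.uniform(0, 2 * np.pi) + _smooth_field(rng, xs, ys, 0.5)
        speed = mean_speed_ms * np.exp(_smooth_field(rng, xs, ys, 0.2))
        raw = np.exp(wind_kappa * np.cos(ang[None, None, :] - theta0[:, :, None]))
        freq = raw / raw.sum(axis=-1, keepdims=True)
        mk = lambda d: Raster(xll=x0, yll=y0, cellsize=cell_m, data=d)
        temperature[year] = mk(t)
        humidity[year] = mk(h)
        wind_u[year] = mk(speed * np.cos(theta0))
        wind_v[year] = mk(speed * np.sin(theta0))
        sector_freq[year] = freq
    return ClimateField(years=region.years, grid=template, temperature=temperature,
                        humidity=humidity, wind_u=wind_u, wind_v=wind_v,
                        sector_freq=sector_freq)


@dataclass
class TerrainModel:
    """Elevation raster with bilinear access and finite-difference slope/aspect."""

    raster: Raster

    def __post_init__(self) -> None:
        if not np.isfinite(self.raster.data).all():
            raise ValueError("terrain elevations must be finite")

    def elevation_at(self, x, y):
        return self.raster.sample_bilinear(x, y)

    def slope_aspect_at(self, x, y):
        """(slope in rise/run, aspect radians east=0) by central differences."""
        d = self.raster.cellsize
        dzdx = (self.elevation_at(np.asarray(x) + d, y) -
                self.elevation_at(np.asarray(x) - d, y)) / (2 * d)
        dzdy = (self.elevation_at(x, np.asarray(y) + d) -
                self.elevation_at(x, np.asarray(y) - d)) / (2 * d)
        slope = np.hypot(dzdx, dzdy)
        aspect = np.arctan2(-dzdy, -dzdx)  # downslope direction
        return slope, aspect


def generate_terrain(region: StudyRegion, seed: int = 0, cell_m: float | None = None,
                     base_elev_m: float = 1400.0, relief_m: float = 500.0) -> TerrainModel:
    """Smooth synthetic elevation raster (no drainage realism intended)."""
    rng = np.random.default_rng(seed)
    cell_m = float(cell_m or region.grid_res_m)
    x0, y0, _, _ = region.extent
    ncols = max(2, int(np.ceil(region.width / cell_m)))
    nrows = max(2, int(np.ceil(region.height / cell_m)))
    template = Raster(xll=x0, yll=y0, cellsize=cell_m, data=np.zeros((nrows, ncols)))
    xs, ys = template.cell_centers()
    elev = base_elev_m + _smooth_field(rng, xs, ys, relief_m, length_m=150e3, n_modes=8)
    return TerrainModel(raster=Raster(xll=x0, yll=y0, cellsize=cell_m, data=elev))


# ---------------------------------------------------------------------------
# dispersion oracle
# ---------------------------------------------------------------------------

@dataclass
class DispersionParams:
    """Parameters of the ground-truth plume surrogate.

    ``decay_km`` is the e-folding distance of the exponential decay;
    ``alignment_gain`` scales the downwind enhancement ``(1 + a*W)``;
    the tanh modifiers keep climate/terrain factors within [0.5, 1.5];
    ``output_scale`` sets the arbitrary concentration-index unit.
    """

    decay_km: float = 15.0
    alignment_gain: float = 1.0
    temp_ref_c: float = 13.0
    temp_scale_c: float = 10.0
    humidity_scale: float = 0.3
    elev_scale_m: float = 400.0
    modifier_gain: float = 0.25
    output_scale: float = 1e-3

    def climate_modifier(self, T, H):
        g = self.modifier_gain
        return (1.0 + g * np.tanh((np.asarray(T) - self.temp_ref_c) / self.temp_scale_c)
                - g * np.tanh((np.asarray(H) - 0.5) / self.humidity_scale))

    def elevation_modifier(self, ED):
        return 1.0 + self.modifier_gain * np.tanh(np.asarray(ED) / self.elev_scale_m)


def oracle_at_points(inventory: EmissionInventory, climate: ClimateField,
                     terrain: TerrainModel, x, y, chemical: str, year: int,
                     params: DispersionParams | None = None,
                     src: SourceSet | None = None) -> np.ndarray:
    """Vectorized ground-truth concentration index at points (x, y).

    Points must lie inside the climate grid's extent.  Exactly additive over
    sources; zero when no source emits the chemical in the year.
    """
    params = params or DispersionParams()
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    ex0, ey0, ex1, ey1 = climate.grid.extent
    if ((x < ex0) | (x > ex1) | (y < ey0) | (y > ey1)).any():
        raise ValueError("oracle evaluation point outside the region extent")
    if src is None:
        src = SourceSet.from_inventory(inventory, climate, terrain, chemical, year)
    if len(src) == 0:
        return np.zeros(len(x))
    blk = pair_feature_block(x, y, src, climate, terrain)
    decay = np.exp(-blk["D"] / params.decay_km)
    align = np.where(blk["D"] == 0.0, 1.0, 1.0 + params.alignment_gain * blk["W"])
    u = params.elevation_modifier(blk["ED"])
    m = params.climate_modifier(blk["T"], blk["H"])
    contrib = src.emission[None, :] * decay * align * u
    return params.output_scale * m * contrib.sum(axis=1)


def dispersion_oracle(inventory, climate, terrain, point, chemical, year,
                      params: DispersionParams | None = None) -> float:
    """Scalar ground-truth concentration at one point."""
    return float(oracle_at_points(inventory, climate, terrain,
                                  [point[0]], [point[1]], chemical, year, params)[0])


def make_oracle(inventory, climate, terrain, params: DispersionParams | None = None):
    """Callable ``oracle(x, y, chemical, year) -> ndarray`` with cached sources."""
    params = params or DispersionParams()
    cache: dict[tuple[str, int], SourceSet] = {}

    def oracle(x, y, chemical, year):
        key = (chemical, int(year))
        if key not in cache:
            cache[key] = SourceSet.from_inventory(inventory, climate, terrain,
                                                  chemical, int(year))
        return oracle_at_points(inventory, climate, terrain, x, y, chemical,
                                int(year), params, src=cache[key])

    return oracle


# ---------------------------------------------------------------------------
# monitors
# ---------------------------------------------------------------------------

def sample_monitors(region: StudyRegion, oracle, n_sites: int = 63,
                    chemicals: tuple[str, ...] = CHEMICALS,
                    years: tuple[int, ...] | None = None,
                    noise_cv: float = 0.15, seed: int = 0) -> pd.DataFrame:
    """Monitor records: oracle truth times multiplicative log-normal noise.

    Sites are preferentially placed where the population density is high
    (monitoring networks cluster in urban areas).  The log-normal noise has
    unit mean and coefficient of variation ``noise_cv``; ``noise_cv=0``
    reproduces the oracle exactly.  Returns one record per
    (site, chemical, year): columns site_id, x, y, chemical, year,
    measured_value.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    years = tuple(int(v) for v in (years or region.years))
    rng = np.random.default_rng(seed)
    max_density = region.pop_background + region.pop_centers[:, 3].sum()
    pts = _sample_from_density(rng, region.population_density, n_sites,
                               region.extent, max_density)
    site_ids = [f"M{i + 1:03d}" for i in range(n_sites)]
    rows = []
    sigma = np.sqrt(np.log1p(noise_cv**2))
    for chem in chemicals:
        for year in years:
            truth = np.asarray(oracle(pts[:, 0], pts[:, 1], chem, year), dtype=float)
            if noise_cv > 0:
                mult = np.exp(rng.normal(0.0, sigma, n_sites) - sigma**2 / 2.0)
                vals = truth * mult
            else:
                vals = truth
            rows.append(pd.DataFrame({
                "site_id": site_ids, "x": pts[:, 0], "y": pts[:, 1],
                "chemical": chem, "year": year, "measured_value": vals,
            }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# true exposures and outcomes
# ---------------------------------------------------------------------------

def true_area_exposures(region: StudyRegion, oracle,
                        chemicals: tuple[str, ...] = CHEMICALS,
                        years: tuple[int, ...] | None = None,
                        cell_m: float = 4050.0) -> pd.DataFrame:
    """Ground-truth per-area annual exposures: oracle averaged over grid cells.

    Uses the same centroid-membership aggregation rule as the pipeline so the
    recovery target is defined on the identical spatial support.  Returns a
    long DataFrame (area_id, chemical, year, exposure).
    """
    from .gridagg import GridSpec, aggregate_to_areas

    years = tuple(int(v) for v in (years or region.years))
    grid = GridSpec.for_region(region, cell_m)
    cx, cy = grid.centroid_arrays()
    assign = grid.assign_centroids(region.area_ids, region.areas)
    rows = []
    for chem in chemicals:
        for year in years:
            vals = oracle(cx, cy, chem, year)
            agg = aggregate_to_areas(vals, assign, region.area_ids,
                                     grid=grid, areas=region.areas)
            rows.append(pd.DataFrame({"area_id": region.area_ids,
                                      "chemical": chem, "year": year,
                                      "exposure": agg}))
    return pd.concat(rows, ignore_index=True)


def generate_tracts(region: StudyRegion, seed: int = 0,
                    total_population: int = 2_100_000) -> pd.DataFrame:
    """Tract-level demographic counts consistent with the tract partition.

    Population is allocated proportionally to density x tract area; category
    counts come from plausible per-tract proportions (female ~ 50%, education
    and marriage from beta draws, race/ethnicity from a Dirichlet over four
    categories).
    """
    rng = np.random.default_rng(seed)
    n = len(region.tracts)
    areas = np.array([p.area for p in region.tracts])
    cen = np.array([[p.centroid.x, p.centroid.y] for p in region.tracts])
    mass = region.population_density(cen[:, 0], cen[:, 1]) * areas
    pop = np.maximum(np.round(total_population * mass / mass.sum()), 1).astype(int)

    p_female = np.clip(rng.normal(0.503, 0.008, n), 0.45, 0.55)
    p_less_hs = np.clip(rng.beta(2.5, 8.0, n), 0.01, 0.6)
    p_unmarried = np.clip(rng.beta(4.0, 6.0, n), 0.05, 0.8)
    race = rng.dirichlet([4.5, 3.5, 1.2, 0.8], size=n)  # hispanic, white, native, other

    df = pd.DataFrame({"tract_id": region.tract_ids, "population": pop})
    df["n_female"] = np.round(pop * p_female).astype(int)
    df["n_less_than_hs"] = np.round(pop * p_less_hs).astype(int)
    df["n_unmarried"] = np.round(pop * p_unmarried).astype(int)
    counts = np.floor(pop[:, None] * race).astype(int)
    counts[:, 0] += pop - counts.sum(axis=1)  # remainder to first category
    for j, cat in enumerate(cov.RACE_CATEGORIES):
        df[f"n_{cat}"] = counts[:, j]
    return df


DEFAULT_EFFECTS = {"mercury": 0.43}
DEFAULT_COVARIATE_COEFS = {
    "pct_female": 0.05,
    "pct_less_than_hs": 0.04,
    "pct_unmarried": 0.03,
    "race_hispanic": 2.0,
    "race_native_american": 3.0,
    "race_other": 1.0,
}


@dataclass
class TruthBundle:
    """Everything a test needs to score recovery; never read by the pipeline.

    ``iqr`` are the interquartile ranges of the five-year-average true
    exposures across areas, so ``effects_per_iqr[k]`` is exactly the slope of
    the noiseless outcome model in IQR-scaled exposure units.
    """

    effects_per_iqr: dict[str, float]
    covariate_coefs: dict[str, float]
    baseline_rate: float
    noise_sd: float
    iqr: dict[str, float]
    mean_exposure: pd.DataFrame      # area_id x chemical (wide)
    area_year_exposure: pd.DataFrame  # long (area_id, chemical, year, exposure)
    seed: int

    def to_json(self, path) -> None:
        doc = {
            "effects_per_iqr": self.effects_per_iqr,
            "covariate_coefs": self.covariate_coefs,
            "baseline_rate": self.baseline_rate,
            "noise_sd": self.noise_sd,
            "iqr": self.iqr,
            "seed": self.seed,
            "mean_exposure": self.mean_exposure.to_dict(orient="list"),
            "area_year_exposure": self.area_year_exposure.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "TruthBundle":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(effects_per_iqr=doc["effects_per_iqr"],
                   covariate_coefs=doc["covariate_coefs"],
                   baseline_rate=doc["baseline_rate"], noise_sd=doc["noise_sd"],
                   iqr=doc["iqr"],
                   mean_exposure=pd.DataFrame(doc["mean_exposure"]),
                   area_year_exposure=pd.DataFrame(doc["area_year_exposure"]),
                   seed=doc["seed"])


def generate_outcomes(region: StudyRegion, truth_exposures: pd.DataFrame,
                      effects_per_iqr: dict[str, float] | None = None,
                      covariate_coefs: dict[str, float] | None = None,
                      noise_sd: float = 0.6, seed: int = 0,
                      baseline_rate: float = 8.8,
                      area_covariates: pd.DataFrame | None = None,
                      tract_table: pd.DataFrame | None = None,
                      total_births: int = 130_000) -> tuple[pd.DataFrame, TruthBundle]:
    """Small-area LBW rates with a known injected per-IQR exposure effect.

    The generator inverts the ecological regression: for each area,
    ``rate = b0 + sum_k beta_k * Xbar_k / IQR_k + gamma . (C - mean(C)) + eps``
    where ``Xbar_k`` is the multi-year-average true exposure, IQRs are taken
    across areas, covariates ``C`` come from areal interpolation of the tract
    table (the same values the association stage later adjusts for, so the
    noiseless round trip is exact), and ``eps ~ Normal(0, noise_sd)`` on the
    percentage-point rate scale.  Rates are clipped to [0, 100]; defaults are
    set so rates land in the mid-single digits to low teens.
    """
    from .association import compute_iqr

    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    effects = DEFAULT_EFFECTS if effects_per_iqr is None else dict(effects_per_iqr)
    coefs = DEFAULT_COVARIATE_COEFS if covariate_coefs is None else dict(covariate_coefs)
    rng = np.random.default_rng(seed)

    long = truth_exposures
    mean_exp = (long.groupby(["area_id", "chemical"])["exposure"].mean()
                .unstack("chemical").reindex(region.area_ids))
    iqr = {c: compute_iqr(mean_exp[c].to_numpy()) for c in mean_exp.columns}
    for chem in effects:
        if chem not in mean_exp.columns:
            raise KeyError(f"injected effect for {chem!r} but no exposure column")
        if iqr[chem] == 0:
            raise ValueError(f"IQR of {chem!r} exposure is zero; cannot scale effect")

    if area_covariates is None:
        if tract_table is None:
            tract_table = generate_tracts(region, seed=seed + 1)
        area_covariates = cov.areal_interpolate(tract_table, region.tracts,
                                                region.area_ids, region.areas)
    C = area_covariates.set_index("area_id").reindex(region.area_ids)

    rate = np.full(len(region.area_ids), float(baseline_rate))
    for chem, beta in effects.items():
        rate += beta * mean_exp[chem].to_numpy() / iqr[chem]
    for col, gamma in coefs.items():
        v = C[col].to_numpy(dtype=float)
        rate += gamma * (v - v.mean())
    if noise_sd > 0:
        rate += rng.normal(0.0, noise_sd, len(rate))
    rate = np.clip(rate, 0.0, 100.0)

    pop = C["population"].to_numpy(dtype=float)
    births = np.maximum(np.round(total_births * pop / pop.sum()), 20).astype(int)
    table = pd.DataFrame({"area_id": region.area_ids, "lbw_rate": rate,
                          "n_births": births})
    for col in ("pct_female", "pct_less_than_hs", "pct_unmarried",
                *(f"race_{c}" for c in cov.RACE_CATEGORIES)):
        table[col] = C[col].to_numpy(dtype=float)
    truth = TruthBundle(effects_per_iqr=effects, covariate_coefs=coefs,
                        baseline_rate=float(baseline_rate), noise_sd=float(noise_sd),
                        iqr={k: float(v) for k, v in iqr.items()},
                        mean_exposure=mean_exp.reset_index(),
                        area_year_exposure=long.reset_index(drop=True),
                        seed=int(seed))
    return table, truth
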