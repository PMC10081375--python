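"""Typed CSV readers/writers and the validated pipeline configuration.

All on-disk artifacts are plain text (CSV, GeoJSON, ESRI ASCII grids, JSON)
so runs diff cleanly and need no binary geodata stack.  Readers validate
schemas and report the offending column by name.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .grids import Raster, read_esri_ascii, write_esri_ascii
from .synthetic import CHEMICALS, ClimateField, EmissionInventory, TerrainModel

__all__ = [
    "PipelineConfig",
    "read_table",
    "write_table",
    "read_inventory_csv",
    "write_inventory_csv",
    "read_climate_dir",
    "write_climate_dir",
]

FACILITY_COLUMNS = ("facility_id", "x", "y", "chemical", "year", "fugitive_kg", "stack_kg")
MONITOR_COLUMNS = ("site_id", "x", "y", "chemical", "year", "measured_value")
OUTCOME_COLUMNS = ("area_id", "lbw_rate", "n_births")
EXPOSURE_COLUMNS = ("area_id", "chemical", "year", "pei")


def read_table(path, required: Sequence[str]) -> pd.DataFrame:
    """CSV reader tolerant of LF/CRLF dialects; errors name missing columns."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def write_inventory_csv(path, inventory: EmissionInventory) -> None:
    """facilities.csv: one row per (facility, chemical, year) with coordinates."""
    em = inventory.emissions.merge(inventory.facilities, on="facility_id")
    write_table(path, em[list(FACILITY_COLUMNS)])


def read_inventory_csv(path, chemicals=None, years=None) -> EmissionInventory:
    df = read_table(path, FACILITY_COLUMNS)
    facilities = df[["facility_id", "x", "y"]].drop_duplicates("facility_id").reset_index(drop=True)
    chemicals = tuple(chemicals or sorted(df["chemical"].unique()))
    years = tuple(int(v) for v in (years or sorted(df["year"].unique())))
    return EmissionInventory(
        facilities=facilities,
        emissions=df[["facility_id", "chemical", "year", "fugitive_kg", "stack_kg"]].copy(),
        chemicals=chemicals, years=years)


def write_climate_dir(dirpath, climate: ClimateField) -> None:
    """One ESRI ASCII grid per variable-year (wind roses: one per sector)."""
    os.makedirs(dirpath, exist_ok=True)
    g = climate.grid
    for year in climate.years:
        for name, ras in (("temperature", climate.temperature[year]),
                          ("humidity", climate.humidity[year]),
                          ("wind_u", climate.wind_u[year]),
                          ("wind_v", climate.wind_v[year])):
            write_esri_ascii(os.path.join(dirpath, f"{name}_{year}.asc"), ras)
        freq = climate.sector_freq[year]
        for s in range(freq.shape[-1]):
            write_esri_ascii(os.path.join(dirpath, f"sector{s:02d}_{year}.asc"),
                             Raster(g.xll, g.yll, g.cellsize, freq[..., s]))


def read_climate_dir(dirpath, years) -> ClimateField:
    years = tuple(int(y) for y in years)
    temperature, humidity, wind_u, wind_v, sector_freq = {}, {}, {}, {}, {}
    template = None
    for year in years:
        temperature[year] = read_esri_ascii(os.path.join(dirpath, f"temperature_{year}.asc"))
        humidity[year] = read_esri_ascii(os.path.join(dirpath, f"humidity_{year}.asc"))
        wind_u[year] = read_esri_ascii(os.path.join(dirpath, f"wind_u_{year}.asc"))
        wind_v[year] = read_esri_ascii(os.path.join(dirpath, f"wind_v_{year}.asc"))
        template = temperature[year]
        layers = []
        s = 0
        while True:
            p = os.path.join(dirpath, f"sector{s:02d}_{year}.asc")
            if not os.path.exists(p):
                break
            layers.append(read_esri_ascii(p).data)
            s += 1
        if not layers:
            raise FileNotFoundError(f"no wind sector grids for year {year} in {dirpath}")
        sector_freq[year] = np.stack(layers, axis=-1)
    return ClimateField(years=years, grid=template, temperature=temperature,
                        humidity=humidity, wind_u=wind_u, wind_v=wind_v,
                        sector_freq=sector_freq)


def read_terrain(path) -> TerrainModel:
    return TerrainModel(raster=read_esri_ascii(path))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RegionConfig(_Strict):
    n_areas: int = 108
    n_tracts: int = 300
    extent_km: tuple[float, float] = (400.0, 400.0)
    grid_res_m: float = 4000.0
    years: tuple[int, ...] = (2012, 2013, 2014, 2015, 2016)


class EmissionsConfig(_Strict):
    n_facilities: int = 369
    zero_fraction: float = 0.7
    log_mean_kg: float = 5.0
    log_sd_kg: float = 1.5


class OracleConfig(_Strict):
    decay_km: float = 15.0
    alignment_gain: float = 1.0


class MonitorConfig(_Strict):
    n_sites: int = 63
    noise_cv: float = 0.15


class OutcomeConfig(_Strict):
    effects_per_iqr: dict[str, float] = Field(default_factory=lambda: {"mercury": 0.43})
    noise_sd: float = 0.6
    baseline_rate: float = 8.8


class FNNConfig(_Strict):
    hidden: tuple[int, ...] = (16, 8)
    lr: float = 0.03
    epochs: int = 400
    patience: int = 50
    val_fraction: float = 0.1
    log_target: bool = True
    prune_fractions: tuple[float, ...] = (0.3, 0.5)
    prune_retrain_epochs: int = 150
    prune_tolerance: float = 0.10
    cv_folds: int = 10
    run_cv: bool = True
    run_prune: bool = True


class AssociationConfig(_Strict):
    fdr: float = 0.05
    corr_threshold: float = 0.5


class PipelineConfig(_Strict):
    """Validated end-to-end pipeline configuration (unknown keys rejected)."""

    seed: int = 0
    chemicals: tuple[str, ...] = CHEMICALS
    cell_m: float = 4050.0
    region: RegionConfig = Field(default_factory=RegionConfig)
    emissions: EmissionsConfig = Field(default_factory=EmissionsConfig)
    oracle: OracleConfig = Field(default_factory=OracleConfig)
    monitors: MonitorConfig = Field(default_factory=MonitorConfig)
    outcomes: OutcomeConfig = Field(default_factory=OutcomeConfig)
    fnn: FNNConfig = Field(default_factory=FNNConfig)
    association: AssociationConfig = Field(default_factory=AssociationConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.model_validate(doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)
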