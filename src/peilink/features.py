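"""Source–receptor features for the exposure model.

For every (receptor i, emission source j, chemical k, year) tuple the exposure
model consumes six variables:

* ``T`` — air temperature at the receptor (degrees C)
* ``H`` — relative humidity at the receptor (fraction, 0-1)
* ``EM`` — total (fugitive + stack) emission of chemical k from source j (kg/yr)
* ``D`` — planar receptor-source distance (km)
* ``ED`` — elevation of the source minus elevation of the receptor (m)
* ``W`` — wind index in [0, 1]: how often, frequency-weighted, the wind at the
  source blows toward the receptor

The wind index is a frequency-weighted clamped-cosine alignment over the 16
compass sectors of the source's wind-direction histogram:
``W = sum_s f_s * max(0, cos(theta_s - bearing))**p`` with exponent ``p = 1``
by default.  It is 1 when all wind blows exactly along the source-to-receptor
bearing, 0 when the wind never has a component toward the receptor, and about
1/pi for a uniform histogram.

Network inputs use ``log1p`` transforms of EM and D (both heavy right-tailed)
and are z-standardized with a :class:`FeatureScaler` whose parameters are
persisted so prediction-time features are scaled identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "N_WIND_SECTORS",
    "FeatureScaler",
    "SourceSet",
    "build_feature_table",
    "compute_distance",
    "compute_elevation_difference",
    "compute_wind_index",
    "feature_matrix",
    "wind_alignment",
]

N_WIND_SECTORS = 16

#: transformed network-input columns, in canonical order
FEATURE_COLUMNS = ("T", "H", "logEM", "logD", "ED", "W")


def compute_distance(p_i, p_j, extent=None) -> float:
    """Euclidean receptor-source distance in km (projected plane).

    If ``extent`` is given, points outside it trigger a warning (not an
    error): edge facilities just outside the study rectangle still disperse
    into it.
    """
    xi, yi = float(p_i[0]), float(p_i[1])
    xj, yj = float(p_j[0]), float(p_j[1])
    if extent is not None:
        x0, y0, x1, y1 = extent
        for (x, y), name in (((xi, yi), "receptor"), ((xj, yj), "source")):
            if not (x0 <= x <= x1 and y0 <= y <= y1):
                warnings.warn(f"{name} point ({x}, {y}) lies outside the region extent",
                              stacklevel=2)
    return float(np.hypot(xi - xj, yi - yj) / 1000.0)


def compute_elevation_difference(terrain, p_i, p_j) -> float:
    """Source elevation minus receptor elevation (m), bilinear on the DEM."""
    e_j = float(terrain.elevation_at(p_j[0], p_j[1]))
    e_i = float(terrain.elevation_at(p_i[0], p_i[1]))
    return e_j - e_i


def sector_angles(n: int = N_WIND_SECTORS) -> np.ndarray:
    """Sector centre directions (radians, east = 0, counter-clockwise)."""
    return 2.0 * np.pi * np.arange(n) / n


def wind_alignment(freqs: np.ndarray, bearings: np.ndarray, exponent: float = 1.0) -> np.ndarray:
    """Clamped-cosine alignment of wind histograms with bearings.

    Parameters
    ----------
    freqs
        (..., 16) sector frequencies (wind blowing *toward* sector angle).
    bearings
        (...) bearing of the receptor as seen from the source (radians).
    """
    freqs = np.asarray(freqs, dtype=float)
    bearings = np.asarray(bearings, dtype=float)
    ang = sector_angles(freqs.shape[-1])
    c = np.maximum(0.0, np.cos(ang - bearings[..., None]))
    if exponent != 1.0:
        c = c ** exponent
    return np.einsum("...s,...s->...", freqs, c)


def compute_wind_index(climate, p_i, p_j, year: int, exponent: float = 1.0) -> float:
    """Wind index between source ``p_j`` and receptor ``p_i`` for one year.

    Coincident points return 1 by convention (a receptor on top of a source
    is "fully downwind").
    """
    xi, yi = float(p_i[0]), float(p_i[1])
    xj, yj = float(p_j[0]), float(p_j[1])
    if xi == xj and yi == yj:
        return 1.0
    freqs = climate.sector_freq_at(xj, yj, year)
    bearing = np.arctan2(yi - yj, xi - xj)
    return float(wind_alignment(freqs, np.asarray(bearing), exponent))


@dataclass
class SourceSet:
    """Positive-emission sources of one chemical in one year, precomputed."""

    chemical: str
    year: int
    ids: np.ndarray          # source identifiers
    x: np.ndarray
    y: np.ndarray
    emission: np.ndarray     # fugitive + stack, kg/yr, all > 0
    elevation: np.ndarray
    sector_freqs: np.ndarray  # (n_sources, 16) at the source grid cell

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_inventory(cls, inventory, climate, terrain, chemical: str, year: int) -> "SourceSet":
        ids, x, y, em = inventory.positive_sources(chemical, year)
        elev = terrain.elevation_at(x, y) if len(x) else np.empty(0)
        freqs = (climate.sector_freq_at(x, y, year)
                 if len(x) else np.empty((0, N_WIND_SECTORS)))
        return cls(chemical=chemical, year=year, ids=ids, x=x, y=y,
                   emission=em, elevation=np.asarray(elev, dtype=float),
                   sector_freqs=np.asarray(freqs, dtype=float))


def pair_feature_block(rx, ry, src: SourceSet, climate, terrain, wind_exponent: float = 1.0):
    """Raw feature arrays for every (receptor, source) pair in a block.

    Returns a dict with receptor-shaped ``T``/``H`` (R,) and pair-shaped
    ``D``/``ED``/``W`` (R, S) arrays.
    """
    rx = np.asarray(rx, dtype=float)
    ry = np.asarray(ry, dtype=float)
    T = np.asarray(climate.temperature_at(rx, ry, src.year), dtype=float)
    H = np.asarray(climate.humidity_at(rx, ry, src.year), dtype=float)
    r_elev = np.asarray(terrain.elevation_at(rx, ry), dtype=float)
    dx = rx[:, None] - src.x[None, :]
    dy = ry[:, None] - src.y[None, :]
    D = np.hypot(dx, dy) / 1000.0
    ED = src.elevation[None, :] - r_elev[:, None]
    bearing = np.arctan2(dy, dx)
    W = wind_alignment(src.sector_freqs[None, :, :], bearing, wind_exponent)
    # coincident receptor/source: bearing undefined, index 1 by convention
    W = np.where(D == 0.0, 1.0, W)
    return {"T": T, "H": H, "D": D, "ED": ED, "W": W}


def build_feature_table(inventory, climate, terrain, receptors, chemical: str, year: int,
                        wind_exponent: float = 1.0) -> pd.DataFrame:
    """Long feature table: one row per (receptor, positive-emission source).

    ``receptors`` is a DataFrame with columns (receptor_id, x, y) or an
    iterable of (receptor_id, x, y) tuples.  Sources with zero emission of
    ``chemical`` in ``year`` are excluded (no emission, no contribution).
    A chemical absent from the inventory raises; a chemical present but with
    no positive emission this year yields an empty table with a warning.
    """
    if chemical not in inventory.chemicals:
        raise KeyError(f"chemical {chemical!r} not present in the emission inventory")
    if isinstance(receptors, pd.DataFrame):
        rec = receptors
    else:
        rec = pd.DataFrame(list(receptors), columns=["receptor_id", "x", "y"])
    src = SourceSet.from_inventory(inventory, climate, terrain, chemical, year)
    cols = ["receptor_id", "x", "y", "source_id", "chemical", "year",
            "T", "H", "EM", "D", "ED", "W"]
    if len(src) == 0:
        warnings.warn(f"no positive-emission source of {chemical!r} in {year}; empty table",
                      stacklevel=2)
        return pd.DataFrame(columns=cols)
    rx = rec["x"].to_numpy(dtype=float)
    ry = rec["y"].to_numpy(dtype=float)
    blk = pair_feature_block(rx, ry, src, climate, terrain, wind_exponent)
    R, S = len(rec), len(src)
    out = pd.DataFrame({
        "receptor_id": np.repeat(rec["receptor_id"].to_numpy(), S),
        "x": np.repeat(rx, S),
        "y": np.repeat(ry, S),
        "source_id": np.tile(src.ids, R),
        "chemical": chemical,
        "year": year,
        "T": np.repeat(blk["T"], S),
        "H": np.repeat(blk["H"], S),
        "EM": np.tile(src.emission, R),
        "D": blk["D"].ravel(),
        "ED": blk["ED"].ravel(),
        "W": blk["W"].ravel(),
    })
    return out[cols]


def raw_to_network_inputs(T, H, EM, D, ED, W) -> np.ndarray:
    """Stack raw features into the (n, 6) transformed network-input matrix."""
    return np.column_stack([
        np.asarray(T, dtype=float),
        np.asarray(H, dtype=float),
        np.log1p(np.asarray(EM, dtype=float)),
        np.log1p(np.asarray(D, dtype=float)),
        np.asarray(ED, dtype=float),
        np.asarray(W, dtype=float),
    ])


@dataclass
class FeatureScaler:
    """Per-column z-standardization of the transformed network inputs.

    Constant columns get unit scale so standardization never divides by zero.
    """

    mean: np.ndarray
    scale: np.ndarray
    columns: tuple[str, ...] = FEATURE_COLUMNS

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def to_dict(self) -> dict:
        return {"columns": list(self.columns),
                "mean": self.mean.tolist(),
                "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaler":
        return cls(mean=np.asarray(d["mean"], dtype=float),
                   scale=np.asarray(d["scale"], dtype=float),
                   columns=tuple(d["columns"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FeatureScaler":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def feature_matrix(table: pd.DataFrame, scaler: FeatureScaler | None = None) -> np.ndarray:
    """Transformed (and, with a scaler, standardized) inputs from a table."""
    X = raw_to_network_inputs(table["T"], table["H"], table["EM"],
                              table["D"], table["ED"], table["W"])
    return scaler.transform(X) if scaler is not None else X
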