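"""Planar geometry helpers: bounded Voronoi partitions and GeoJSON polygons.

All coordinates are in a projected plane (meters).  Partitions are built by
clipping the Voronoi diagram of seed points to the study rectangle; mirroring
the seeds across the four rectangle edges guarantees every interior cell is
bounded, so the clipped cells tile the rectangle exactly (up to floating
point).
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box, mapping, shape

__all__ = [
    "bounded_voronoi",
    "polygon_area",
    "read_geojson_polygons",
    "write_geojson_polygons",
]


def polygon_area(poly: Polygon) -> float:
    """Planar (shoelace) area of a polygon, holes subtracted."""
    return float(poly.area)


def _mirror_points(pts: np.ndarray, extent) -> np.ndarray:
    x0, y0, x1, y1 = extent
    left = pts.copy()
    left[:, 0] = 2 * x0 - pts[:, 0]
    right = pts.copy()
    right[:, 0] = 2 * x1 - pts[:, 0]
    down = pts.copy()
    down[:, 1] = 2 * y0 - pts[:, 1]
    up = pts.copy()
    up[:, 1] = 2 * y1 - pts[:, 1]
    return np.vstack([pts, left, right, down, up])


def bounded_voronoi(points: np.ndarray, extent) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to the rectangle ``extent``.

    Parameters
    ----------
    points
        (n, 2) seed coordinates strictly inside the extent.
    extent
        (xmin, ymin, xmax, ymax).

    Returns one polygon per seed point, in seed order; the polygons are
    pairwise interior-disjoint and jointly cover the rectangle.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(points)
    rect = box(*_extent_to_bounds(extent))
    if n == 1:
        return [rect]
    vor = Voronoi(_mirror_points(points, _extent_to_bounds(extent)))
    cells: list[Polygon] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("mirrored Voronoi produced an unbounded interior cell")
        poly = Polygon(vor.vertices[region]).intersection(rect)
        if poly.geom_type != "Polygon" or poly.is_empty:
            raise RuntimeError(f"degenerate Voronoi cell for seed {i}")
        cells.append(poly)
    return cells


def _extent_to_bounds(extent) -> tuple[float, float, float, float]:
    x0, y0, x1, y1 = (float(v) for v in extent)
    if not (x1 > x0 and y1 > y0):
        raise ValueError(f"extent must have positive width and height, got {extent}")
    return x0, y0, x1, y1


def write_geojson_polygons(path, ids: Sequence[str], polys: Sequence[Polygon],
                           properties: Sequence[dict] | None = None) -> None:
    """Write polygons as a GeoJSON FeatureCollection with an ``id`` property.

    Exterior rings are normalized to counter-clockwise winding.
    """
    feats = []
    for k, (pid, poly) in enumerate(zip(ids, polys)):
        if not poly.is_valid:
            raise ValueError(f"polygon {pid!r} is invalid (self-intersecting?)")
        geom = mapping(_normalize_winding(poly))
        props = {"id": str(pid)}
        if properties is not None:
            props.update(properties[k])
        feats.append({"type": "Feature", "geometry": geom, "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _normalize_winding(poly: Polygon) -> Polygon:
    ext = poly.exterior
    shell = list(ext.coords) if ext.is_ccw else list(ext.coords)[::-1]
    holes = []
    for ring in poly.interiors:
        holes.append(list(ring.coords)[::-1] if ring.is_ccw else list(ring.coords))
    return Polygon(shell, holes)


def read_geojson_polygons(path) -> tuple[list[str], list[Polygon], list[dict]]:
    """Read a polygon FeatureCollection; rejects invalid geometry.

    Returns (ids, polygons, extra property dicts).
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    ids, polys, props = [], [], []
    for feat in doc["features"]:
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(f"expected Polygon geometry, got {geom.geom_type}")
        if not geom.is_valid:
            raise ValueError(f"invalid polygon for feature {feat['properties'].get('id')!r}")
        p = dict(feat.get("properties") or {})
        ids.append(str(p.pop("id", len(ids))))
        polys.append(geom)
        props.append(p)
    return ids, polys, props
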