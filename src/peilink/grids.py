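"""Plain-text raster container and ESRI ASCII grid reader/writer.

A :class:`Raster` stores a regular grid in projected meters with row 0 at the
*northern* edge (the on-disk order of the ESRI ASCII format).  Bilinear
sampling treats cell values as point values at cell centres and clamps
coordinates to the outermost centres, so queries on the boundary ring are
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Raster", "read_esri_ascii", "write_esri_ascii"]


@dataclass
class Raster:
    """Regular grid; ``data[0, :]`` is the northernmost row."""

    xll: float
    yll: float
    cellsize: float
    data: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered rectangle."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cellsize,
            self.yll + self.nrows * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Centre coordinates: (x of each column, y of each row, north first)."""
        cs = self.cellsize
        xs = self.xll + (np.arange(self.ncols) + 0.5) * cs
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * cs
        return xs, ys

    def _frac_index(self, x, y):
        cs = self.cellsize
        # fractional index into the (row, col) lattice of cell centres
        fc = (np.asarray(x, dtype=float) - self.xll) / cs - 0.5
        fr = (self.yll + self.nrows * cs - np.asarray(y, dtype=float)) / cs - 0.5
        fc = np.clip(fc, 0.0, self.ncols - 1.0)
        fr = np.clip(fr, 0.0, self.nrows - 1.0)
        return fr, fc

    def sample_bilinear(self, x, y) -> np.ndarray:
        """Bilinear interpolation at (x, y); accepts scalars or arrays."""
        fr, fc = self._frac_index(x, y)
        r0 = np.floor(fr).astype(int)
        c0 = np.floor(fc).astype(int)
        r1 = np.minimum(r0 + 1, self.nrows - 1)
        c1 = np.minimum(c0 + 1, self.ncols - 1)
        tr = fr - r0
        tc = fc - c0
        d = self.data
        out = (
            d[r0, c0] * (1 - tr) * (1 - tc)
            + d[r1, c0] * tr * (1 - tc)
            + d[r0, c1] * (1 - tr) * tc
            + d[r1, c1] * tr * tc
        )
        return out

    def sample_nearest_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cell containing (x, y), clamped to the grid."""
        cs = self.cellsize
        c = np.clip(
            np.floor((np.asarray(x, dtype=float) - self.xll) / cs).astype(int),
            0,
            self.ncols - 1,
        )
        r = np.clip(
            np.floor((self.yll + self.nrows * cs - np.asarray(y, dtype=float)) / cs).astype(int),
            0,
            self.nrows - 1,
        )
        return r, c


def write_esri_ascii(path, raster: Raster) -> None:
    """Write an ESRI ASCII grid (.asc); NaN cells become NODATA."""
    data = np.where(np.isfinite(raster.data), raster.data, raster.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xll!r}\n")
        fh.write(f"yllcorner {raster.yll!r}\n")
        fh.write(f"cellsize {raster.cellsize!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in data:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_esri_ascii(path) -> Raster:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ESRI ASCII grid missing header field {req!r}")
    data = np.vstack(rows)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid body shape {data.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    return Raster(
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        data=data,
        nodata=nodata,
    )
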