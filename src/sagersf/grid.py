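"""Minimal projected-raster container and disc geometry helpers.

All layers live on one projected, meter-based grid.  A :class:`Raster` stores a
2-D array with its lower-left corner and square cell size; row 0 is the
northernmost row.  Rasters round-trip through the plain-text ESRI ASCII grid
format so every artifact stays human-readable.

The unit of analysis downstream is a disc (movement buffer) around a point.
Cell-disc overlap areas are computed by exact polygon clipping of square cells
against a 32-gon approximation of the disc, which removes the center-in /
center-out ambiguity of coarser zonal statistics (32-gon area error < 1e-3
relative to the true circle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

DISC_QUAD_SEGS = 8  # 4 * 8 = 32-gon disc approximation


@dataclass
class Raster:
    """A single-band raster on a projected meter grid.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; row 0 is the top (north) row.
    x0, y0 : float
        Coordinates of the lower-left corner of the grid, in meters.
    cell : float
        Cell edge length in meters.
    """

    values: np.ndarray
    x0: float
    y0: float
    cell: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.cell,
            self.y0 + self.nrows * self.cell,
        )

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell, other.cell)
        )

    # -- coordinate transforms ------------------------------------------------

    def cell_center(self, row, col):
        """Projected coordinates of the center of cell (row, col)."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell
        y = self.y0 + (self.nrows - np.asarray(row) - 0.5) * self.cell
        return x, y

    def cell_centers(self):
        """(x, y) arrays of all cell centers, shape (nrows, ncols)."""
        rows, cols = np.indices(self.values.shape)
        return self.cell_center(rows, cols)

    def index_of(self, x, y):
        """(row, col) of the cell containing projected point(s) (x, y)."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell).astype(int)
        row = self.nrows - 1 - np.floor((np.asarray(y) - self.y0) / self.cell).astype(int)
        return row, col

    def value_at(self, x, y):
        """Cell value(s) at projected point(s); raises if out of bounds."""
        row, col = self.index_of(x, y)
        if np.any((row < 0) | (row >= self.nrows) | (col < 0) | (col >= self.ncols)):
            raise ValueError("point outside raster extent")
        return self.values[row, col]

    def contains(self, x, y):
        xmin, ymin, xmax, ymax = self.bounds
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(values=values, x0=self.x0, y0=self.y0, cell=self.cell, nodata=self.nodata)

    # -- text IO --------------------------------------------------------------

    def to_ascii(self, path) -> None:
        """Write the raster as an ESRI ASCII grid (plain text)."""
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {self.y0!r}\n"
            f"cellsize {self.cell!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            fmt = "%.10g" if self.values.dtype.kind == "f" else "%d"
            np.savetxt(fh, self.values, fmt=fmt)

    @classmethod
    def from_ascii(cls, path) -> "Raster":
        meta = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        return cls(
            values=values,
            x0=meta["xllcorner"],
            y0=meta["yllcorner"],
            cell=meta["cellsize"],
            nodata=meta.get("nodata_value", -9999.0),
        )


def disc_polygon(x: float, y: float, radius_m: float) -> Polygon:
    """32-gon approximation of the disc of given radius around (x, y)."""
    return Point(x, y).buffer(radius_m, quad_segs=DISC_QUAD_SEGS)


def disc_cell_weights(raster: Raster, x: float, y: float, radius_m: float):
    """Exact overlap areas between a disc and the raster's cells.

    Returns ``(rows, cols, weights)`` for every cell with positive overlap with
    the 32-gon disc centered at (x, y); weights are overlap areas in m^2.
    Raises if the disc lies wholly outside the raster.
    """
    disc = disc_polygon(x, y, radius_m)
    xmin, ymin, xmax, ymax = disc.bounds
    r0, c0 = raster.index_of(xmin + 1e-9, ymax - 1e-9)  # top-left cell index
    r1, c1 = raster.index_of(xmax - 1e-9, ymin + 1e-9)  # bottom-right cell index
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, raster.nrows - 1), min(c1, raster.ncols - 1)
    if r0 > r1 or c0 > c1:
        raise ValueError("buffer lies wholly outside the raster extent")
    rows, cols = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    cx, cy = raster.cell_center(rows, cols)
    half = raster.cell / 2.0
    boxes = shapely.box(cx - half, cy - half, cx + half, cy + half)
    areas = shapely.area(shapely.intersection(boxes, disc))
    keep = areas > 0
    if not np.any(keep):
        raise ValueError("buffer lies wholly outside the raster extent")
    return rows[keep], cols[keep], areas[keep]


@dataclass
class DiscKernel:
    """Disc-cell overlap weights for a disc centered on a cell center.

    For grid-aligned centers the overlap pattern is identical everywhere, so it
    can be computed once and applied as a convolution kernel.
    """

    weights: np.ndarray  # (2h+1, 2h+1) overlap areas, m^2
    radius_m: float
    cell: float

    @property
    def halfwidth(self) -> int:
        return self.weights.shape[0] // 2


def disc_kernel(cell: float, radius_m: float) -> DiscKernel:
    """Overlap-area kernel of a disc centered at a cell center."""
    h = int(np.ceil(radius_m / cell + 0.75))
    offs = np.arange(-h, h + 1) * cell
    ox, oy = np.meshgrid(offs, offs, indexing="xy")
    half = cell / 2.0
    disc = disc_polygon(0.0, 0.0, radius_m)
    boxes = shapely.box(ox - half, oy - half, ox + half, oy + half)
    w = shapely.area(shapely.intersection(boxes.ravel(), disc)).reshape(ox.shape)
    # trim all-zero border rows/cols so convolutions stay tight
    nz = np.nonzero(w.sum(axis=0))[0]
    w = w[:, nz.min(): nz.max() + 1]
    nz = np.nonzero(w.sum(axis=1))[0]
    w = w[nz.min(): nz.max() + 1, :]
    return DiscKernel(weights=w, radius_m=radius_m, cell=cell)
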