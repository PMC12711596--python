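"""Planar raster grid container and plain-text (ESRI ASCII grid) I/O.

A :class:`RasterGrid` is the spatial currency of the whole package: a single
band of float values on a regular planar grid, with NaN marking nodata. Row 0
is the northernmost row (the usual raster convention), x increases with column
index and y decreases with row index. Coordinates are in km unless the caller
says otherwise; nothing here assumes a geodetic datum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid", "GridError"]

_NODATA_OUT = -9999.0


class GridError(ValueError):
    """Invalid grid construction or incompatible grids."""


@dataclass
class RasterGrid:
    """Single-band georeferenced grid on a planar coordinate system.

    Parameters
    ----------
    values:
        2-D float array; ``NaN`` cells are nodata.
    x_min, y_max:
        Coordinates of the top-left corner of the top-left cell.
    cell_size:
        Side length of a (square) cell, same units as the coordinates.
    """

    values: np.ndarray
    x_min: float
    y_max: float
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise GridError("grid values must be a non-empty 2-D array")
        if not self.cell_size > 0:
            raise GridError(f"cell_size must be positive, got {self.cell_size}")

    # -- geometry ----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_min(self) -> float:
        return self.y_max - self.n_rows * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max)."""
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return np.isfinite(self.values)

    def x_centres(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centres(self) -> np.ndarray:
        """Row-centre y coordinates, northernmost first."""
        return self.y_max - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def centre_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Full (X, Y) cell-centre coordinate arrays, shape == values.shape."""
        return np.meshgrid(self.x_centres(), self.y_centres())

    def index_of(self, x, y):
        """Map coordinates to (row, col); entries are -1 where off-grid.

        Accepts scalars or arrays. Membership is half-open: a point on the
        shared edge of two cells belongs to the cell with the larger index in
        x and the smaller in y (matching ``floor``).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_min) / self.cell_size).astype(int)
        row = np.floor((self.y_max - y) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def centre_of(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x_min + (col + 0.5) * self.cell_size
        y = self.y_max - (row + 0.5) * self.cell_size
        return x, y

    # -- construction helpers ---------------------------------------------
    def with_values(self, values: np.ndarray) -> "RasterGrid":
        """New grid on the same transform with different values."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise GridError(f"shape mismatch: {values.shape} vs {self.shape}")
        return RasterGrid(values.copy(), self.x_min, self.y_max, self.cell_size)

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_min - other.x_min) <= tol
            and abs(self.y_max - other.y_max) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def values_at(self, x, y) -> np.ndarray:
        """Values at point locations; NaN where off-grid."""
        row, col = self.index_of(x, y)
        out = np.full(np.shape(row), np.nan, dtype=float)
        ok = (np.asarray(row) >= 0)
        r = np.asarray(row)[ok]
        c = np.asarray(col)[ok]
        out[ok] = self.values[r, c]
        return out


def write_ascii_grid(grid: RasterGrid, path) -> None:
    """Write an ESRI ASCII grid (.asc), NODATA_value -9999."""
    vals = np.where(grid.mask, grid.values, _NODATA_OUT)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_min!r}\n"
        f"yllcorner {grid.y_min!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {_NODATA_OUT!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or any
    conforming .asc with an ``xllcorner``/``yllcorner`` header)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.strip().partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # header shorter than six lines; rewind
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", _NODATA_OUT)
    values = np.where(values == nodata, np.nan, values)
    cell = header["cellsize"]
    y_max = header["yllcorner"] + header["nrows"] * cell
    grid = RasterGrid(values, header["xllcorner"], y_max, cell)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise GridError(f"header/body shape mismatch in {path}")
    return grid
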