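"""Planar kilometre grids and the plain-text raster interchange format.

Every gridded layer in this package lives on a regular planar grid with
square cells. Arrays are row-major with rows ordered north to south, so
``layer[0, 0]`` is the north-west corner cell. Coordinates are kilometres;
``(x0, y0)`` is the lower-left (south-west) corner of the grid and cell
*centres* are offset half a cell inward.

Layers are exchanged on disk as ESRI ASCII grids: a six-line header
(ncols, nrows, xllcorner, yllcorner, cellsize, nodata_value) followed by
whitespace-separated rows, north to south. NaN cells are written as the
nodata value and read back as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular planar grid (km units, square cells)."""

    nx: int
    ny: int
    cell_size_km: float = 1.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell in each direction")
        if self.cell_size_km <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    @property
    def width_km(self) -> float:
        return self.nx * self.cell_size_km

    @property
    def height_km(self) -> float:
        return self.ny * self.cell_size_km

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell_size_km

    @property
    def y_centers(self) -> np.ndarray:
        """Cell-centre y coordinates in storage (north-to-south) row order."""
        return self.y0 + (self.ny - np.arange(self.ny) - 0.5) * self.cell_size_km

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing planar points; -1 outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size_km).astype(int)
        row_s = np.floor((y - self.y0) / self.cell_size_km).astype(int)
        row = self.ny - 1 - row_s
        bad = (col < 0) | (col >= self.nx) | (row < 0) | (row >= self.ny)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.cell_size_km
        y = self.y0 + (self.ny - row - 0.5) * self.cell_size_km
        return x, y


def write_ascii_grid(path: str | Path, layer: np.ndarray, grid: GridSpec, nodata: float = -9999.0) -> None:
    layer = np.asarray(layer, dtype=float)
    if layer.shape != grid.shape:
        raise ValueError(f"layer shape {layer.shape} does not match grid {grid.shape}")
    out = np.where(np.isfinite(layer), layer, nodata)
    header = (
        f"ncols {grid.nx}\n"
        f"nrows {grid.ny}\n"
        f"xllcorner {grid.x0!r}\n"
        f"yllcorner {grid.y0!r}\n"
        f"cellsize {grid.cell_size_km!r}\n"
        f"nodata_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    nx, ny = int(header["ncols"]), int(header["nrows"])
    data = np.atleast_2d(data).reshape(ny, nx)
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    grid = GridSpec(
        nx=nx,
        ny=ny,
        cell_size_km=header["cellsize"],
        x0=header.get("xllcorner", 0.0),
        y0=header.get("yllcorner", 0.0),
    )
    return data, grid
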