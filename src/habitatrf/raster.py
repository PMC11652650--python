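"""Gridded-layer containers.

A :class:`RasterGrid` is one 2-D georeferenced layer: a value array, an
affine-style geotransform (top-left origin, positive cell sizes) and a
nodata sentinel. An :class:`EnvironmentalStack` is an ordered, named set
of such layers, optionally harmonized to a single common grid.

The coordinate convention follows the usual GIS raster model: row 0 is
the northernmost row, cell (row, col) = (0, 0) sits at the top-left, and
the centre of cell (i, j) is at ``(x0 + (j + 0.5) dx, y0 - (i + 0.5) dy)``.
Point-to-cell lookups use half-open cell intervals, so a point on a
shared edge belongs to exactly one cell.

Layers are read and written in the ESRI ASCII grid format (plain text,
square cells), which any desktop GIS ingests directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

DEFAULT_NODATA = -9999.0

__all__ = [
    "DEFAULT_NODATA",
    "GridGeometry",
    "RasterGrid",
    "EnvironmentalStack",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass(frozen=True)
class GridGeometry:
    """Shape plus geotransform of a raster grid.

    Parameters
    ----------
    x0, y0:
        Coordinates of the *outer top-left corner* of cell (0, 0).
    dx, dy:
        Cell width and height in map units; both strictly positive
        (``dy`` is the magnitude of the north-to-south step).
    nrows, ncols:
        Grid shape.
    """

    x0: float
    y0: float
    dx: float
    dy: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError(f"cell sizes must be positive, got dx={self.dx}, dy={self.dy}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError(f"grid must be non-empty, got {self.nrows}x{self.ncols}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) outer bounds."""
        return (
            self.x0,
            self.y0 - self.nrows * self.dy,
            self.x0 + self.ncols * self.dx,
            self.y0,
        )

    @classmethod
    def from_extent(
        cls, xmin: float, ymin: float, xmax: float, ymax: float, cellsize: float
    ) -> "GridGeometry":
        """Cover ``[xmin, xmax] x [ymin, ymax]`` with square cells.

        The number of rows/columns is the floor of extent / cellsize, so
        the grid never spills over the requested window; a window smaller
        than one cell is rejected.
        """
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("degenerate extent: xmax<=xmin or ymax<=ymin")
        ncols = int(np.floor((xmax - xmin) / cellsize + 1e-9))
        nrows = int(np.floor((ymax - ymin) / cellsize + 1e-9))
        if ncols < 1 or nrows < 1:
            raise ValueError(
                f"extent ({xmax - xmin} x {ymax - ymin}) smaller than one cell of size {cellsize}"
            )
        return cls(x0=xmin, y0=ymax, dx=cellsize, dy=cellsize, nrows=nrows, ncols=ncols)

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        """Map-space centre coordinates of cell (row, col)."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 - (np.asarray(row) + 0.5) * self.dy
        return x, y

    def cell_index(self, x: np.ndarray | float, y: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (half-open cells).

        Raises ``ValueError`` listing offending points if any fall
        outside the grid bounds.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        col = np.floor((x - self.x0) / self.dx).astype(int)
        row = np.floor((self.y0 - y) / self.dy).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        if np.any(bad):
            pts = list(zip(x[bad][:5], y[bad][:5]))
            raise ValueError(f"{int(bad.sum())} point(s) outside grid extent, e.g. {pts}")
        return row, col

    def row_center_latitudes(self) -> np.ndarray:
        """y coordinate of each row's cell centres (used for area weights)."""
        return self.y0 - (np.arange(self.nrows) + 0.5) * self.dy


@dataclass
class RasterGrid:
    """One 2-D layer: values + geometry + nodata sentinel + name."""

    values: np.ndarray
    geometry: GridGeometry
    nodata: float = DEFAULT_NODATA
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("values must be a non-empty 2-D array")
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return (self.values != self.nodata) & np.isfinite(self.values)

    @property
    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        return RasterGrid(
            values=values,
            geometry=self.geometry,
            nodata=self.nodata,
            name=self.name if name is None else name,
        )

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Cell value under each point (nodata propagated)."""
        row, col = self.geometry.cell_index(x, y)
        return self.values[row, col]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        g = self.geometry
        return f"RasterGrid({self.name!r}, {g.nrows}x{g.ncols}, dx={g.dx:g})"


class EnvironmentalStack:
    """Ordered, named set of predictor layers.

    The stack is *harmonized* when every layer shares one
    :class:`GridGeometry`; model fitting and clustering require this.
    """

    def __init__(self, layers: Mapping[str, RasterGrid] | None = None):
        self._layers: dict[str, RasterGrid] = {}
        if layers:
            for name, grid in layers.items():
                self.add(name, grid)

    def add(self, name: str, grid: RasterGrid) -> None:
        if name in self._layers:
            raise ValueError(f"duplicate layer name {name!r}")
        self._layers[name] = replace(grid, name=name)

    # -- mapping-ish surface -------------------------------------------------
    def __getitem__(self, name: str) -> RasterGrid:
        try:
            return self._layers[name]
        except KeyError:
            raise KeyError(f"stack has no layer {name!r}; layers: {self.names}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self) -> Iterator[str]:
        return iter(self._layers)

    def __len__(self) -> int:
        return len(self._layers)

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    def items(self) -> Iterator[tuple[str, RasterGrid]]:
        return iter(self._layers.items())

    # -- harmonization state -------------------------------------------------
    @property
    def harmonized(self) -> bool:
        geoms = {g.geometry for g in self._layers.values()}
        return len(geoms) == 1

    @property
    def geometry(self) -> GridGeometry:
        if not self._layers:
            raise ValueError("empty stack has no geometry")
        if not self.harmonized:
            raise ValueError("stack is not harmonized to one grid")
        return next(iter(self._layers.values())).geometry

    def require_harmonized(self) -> GridGeometry:
        return self.geometry

    def valid_mask(self) -> np.ndarray:
        """Cells valid in *every* layer (harmonized stacks only)."""
        geom = self.require_harmonized()
        mask = np.ones(geom.shape, dtype=bool)
        for grid in self._layers.values():
            mask &= grid.valid_mask
        return mask

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid_cells x n_layers matrix, flat indices of those cells)."""
        mask = self.valid_mask()
        idx = np.flatnonzero(mask.ravel())
        cols = [g.values.ravel()[idx] for g in self._layers.values()]
        return np.column_stack(cols), idx

    def subset(self, names: list[str]) -> "EnvironmentalStack":
        missing = [n for n in names if n not in self._layers]
        if missing:
            raise KeyError(f"stack missing layer(s): {missing}")
        return EnvironmentalStack({n: self._layers[n] for n in names})


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: RasterGrid, path: str | Path) -> Path:
    """Write a layer as an ESRI ASCII grid (requires square cells)."""
    g = grid.geometry
    if not np.isclose(g.dx, g.dy):
        raise ValueError("ASCII grid format requires square cells")
    path = Path(path)
    yll = g.y0 - g.nrows * g.dy
    header = (
        f"ncols {g.ncols}\n"
        f"nrows {g.nrows}\n"
        f"xllcorner {g.x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {g.dx!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    vals = np.where(grid.valid_mask, grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")
    return path


def read_ascii_grid(path: str | Path, name: str = "") -> RasterGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    geom = GridGeometry(
        x0=header["xllcorner"],
        y0=header["yllcorner"] + nrows * cell,
        dx=cell,
        dy=cell,
        nrows=nrows,
        ncols=ncols,
    )
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    return RasterGrid(values=values, geometry=geom, nodata=nodata, name=name or path.stem)
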