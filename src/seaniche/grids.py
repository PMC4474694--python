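"""Planar raster grid containers shared by every stage of the analysis.

All spatial fields (depth, slope, distance to shore, SST statistics, habitat
suitability) live on one rectangular grid of square cells with a boolean
land/sea mask.  Coordinates are planar metres; row 0 is the northernmost row,
and the centre of cell (row, col) sits at

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y - (row + 0.5) * cell_size

where (origin_x, origin_y) is the outer corner of the top-left cell.
Rasters are exchanged as single-band ESRI ASCII grids (plain text).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry and validity mask of a raster grid.

    ``mask`` is True on marine (valid) cells and False on land/NoData cells.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    mask: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        mask = self.mask
        if mask is None:
            mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != (self.n_rows, self.n_cols):
                raise ValueError("mask shape does not match grid dimensions")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all cell centres, shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map planar coordinates to (row, col); out-of-grid points get -1."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - y) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
        )

    def with_mask(self, mask: np.ndarray) -> "GridSpec":
        return replace(self, mask=np.asarray(mask, dtype=bool))


@dataclass
class Raster:
    """A single named layer on a :class:`GridSpec`.

    Values must be finite on masked-true cells; masked-false cells hold NaN.
    """

    grid: GridSpec
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float).copy()
        if vals.shape != self.grid.shape:
            raise ValueError(
                f"raster {self.name!r}: values shape {vals.shape} "
                f"does not match grid {self.grid.shape}"
            )
        vals[~self.grid.mask] = np.nan
        if not np.all(np.isfinite(vals[self.grid.mask])):
            raise ValueError(f"raster {self.name!r}: non-finite values on valid cells")
        self.values = vals

    def valid_values(self) -> np.ndarray:
        """1-D array of values on valid cells (row-major order)."""
        return self.values[self.grid.mask]

    def masked_like(self, mask: np.ndarray) -> "Raster":
        """Restrict this raster to the intersection of its mask and ``mask``."""
        new_mask = self.grid.mask & np.asarray(mask, dtype=bool)
        return Raster(self.grid.with_mask(new_mask), self.values, self.name, self.units)


class EnvStack:
    """An ordered, name-addressable collection of co-registered rasters.

    All layers share one GridSpec geometry and one mask (the intersection of
    the individual layer masks), so a per-cell covariate vector is well
    defined on every valid cell.
    """

    def __init__(self, layers: list[Raster], season: str | None = None):
        if not layers:
            raise ValueError("EnvStack needs at least one layer")
        names = [r.name for r in layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        base = layers[0].grid
        for r in layers[1:]:
            if not r.grid.same_geometry(base):
                raise ValueError(f"layer {r.name!r} is on a different grid geometry")
        common = np.logical_and.reduce([r.grid.mask for r in layers])
        self.grid = base.with_mask(common)
        self.layers = [r.masked_like(common) for r in layers]
        self.season = season

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.layers]

    def __getitem__(self, name: str) -> Raster:
        for r in self.layers:
            if r.name == name:
                return r
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.layers)

    def covariate_matrix(self) -> np.ndarray:
        """(n_valid, n_layers) matrix of covariates over valid cells."""
        return np.column_stack([r.valid_values() for r in self.layers])

    def covariates_at(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(n_points, n_layers) covariate matrix at the given cells."""
        return np.column_stack([r.values[rows, cols] for r in self.layers])


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.6f") -> None:
    """Write a raster as an ESRI ASCII grid with a tagged NoData value."""
    g = raster.grid
    path = Path(path)
    vals = np.where(g.mask, raster.values, NODATA)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.origin_x:.6f}\n"
        f"yllcorner {g.origin_y - g.n_rows * g.cell_size:.6f}\n"
        f"cellsize {g.cell_size:.6f}\n"
        f"NODATA_value {NODATA:.1f}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)


def read_ascii_grid(path: str | Path, name: str = "", units: str = "") -> Raster:
    """Read an ESRI ASCII grid; NoData cells become masked-out cells."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        vals = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {vals.shape} does not match header")
    nodata = header.get("nodata_value", NODATA)
    cell = header["cellsize"]
    mask = vals != nodata
    grid = GridSpec(
        n_rows, n_cols, cell,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        mask=mask,
    )
    vals = np.where(mask, vals, np.nan)
    return Raster(grid, vals, name=name or path.stem, units=units)
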