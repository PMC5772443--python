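"""Analysis lattice: grid geometry, raster containers, region partitions, raster I/O.

All coordinates are WGS84 decimal degrees and every distance in the package is
Euclidean in degree space — the convention the rest of the pipeline (IDW radii,
KDE bandwidths, hull buffers) inherits. Cells are half-open intervals
``[west, west + cell_size) x [south, south + cell_size)`` with a lower-left
origin; row index increases northward.

Rasters are read and written in the ESRI ASCII grid dialect
(``ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`` header); nodata is
-9999. ESRI ASCII stores the top row first, so rows are flipped on the way in
and out to keep the in-memory south-up orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0

#: Sentinel returned by :func:`point_to_cell` for points off the grid.
OUT_OF_BOUNDS = None


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lattice of square cells in decimal degrees."""

    west: float
    south: float
    cell_size: float = 0.5
    n_cols: int = 60
    n_rows: int = 60

    def __post_init__(self) -> None:
        if not (self.cell_size > 0):
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def east(self) -> float:
        return self.west + self.cell_size * self.n_cols

    @property
    def north(self) -> float:
        return self.south + self.cell_size * self.n_rows

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


def point_to_cell(lon, lat, grid: GridSpec):
    """Map a point to its (row, col) cell, or ``None`` when off the grid.

    The lower/western edge owns the boundary (half-open intervals), so a point
    exactly on ``west + k*cell_size`` belongs to column ``k``.
    """
    lon = float(lon)
    lat = float(lat)
    if not (np.isfinite(lon) and np.isfinite(lat)):
        raise ValueError("coordinates must be finite")
    col = int(np.floor((lon - grid.west) / grid.cell_size))
    row = int(np.floor((lat - grid.south) / grid.cell_size))
    if col < 0 or col >= grid.n_cols or row < 0 or row >= grid.n_rows:
        return OUT_OF_BOUNDS
    return (row, col)


def points_to_cells(lon: np.ndarray, lat: np.ndarray, grid: GridSpec):
    """Vectorised :func:`point_to_cell`; rows/cols are -1 for out-of-bounds."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    col = np.floor((lon - grid.west) / grid.cell_size).astype(int)
    row = np.floor((lat - grid.south) / grid.cell_size).astype(int)
    bad = (
        ~np.isfinite(lon)
        | ~np.isfinite(lat)
        | (col < 0)
        | (col >= grid.n_cols)
        | (row < 0)
        | (row >= grid.n_rows)
    )
    row = np.where(bad, -1, row)
    col = np.where(bad, -1, col)
    return row, col


def cell_center(cell: tuple[int, int], grid: GridSpec) -> tuple[float, float]:
    """Midpoint (lon, lat) of a cell; inverse of :func:`point_to_cell`."""
    row, col = cell
    if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
        raise IndexError(f"cell {cell} outside {grid.n_rows}x{grid.n_cols} grid")
    lon = grid.west + (col + 0.5) * grid.cell_size
    lat = grid.south + (row + 0.5) * grid.cell_size
    return (lon, lat)


def cell_centers(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """(lon, lat) arrays of shape (n_rows, n_cols) with every cell midpoint."""
    lon = grid.west + (np.arange(grid.n_cols) + 0.5) * grid.cell_size
    lat = grid.south + (np.arange(grid.n_rows) + 0.5) * grid.cell_size
    return np.meshgrid(lon, lat)


@dataclass
class RasterLayer:
    """Per-cell values on a :class:`GridSpec` with a validity mask.

    ``values`` has shape (n_rows, n_cols), row 0 southernmost. Invalid cells
    (outside the study region, non-forest, nodata) are excluded from every
    downstream statistic.
    """

    grid: GridSpec
    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise ValueError("valid mask shape mismatch")

    def copy(self) -> "RasterLayer":
        return RasterLayer(self.grid, self.values.copy(), self.valid.copy())

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


@dataclass
class RegionPartition:
    """Integer labelling of valid cells into the six Amazonian regions."""

    grid: GridSpec
    region_id: np.ndarray  # int, 0 = no region / invalid

    N_REGIONS = 6

    def __post_init__(self) -> None:
        self.region_id = np.asarray(self.region_id, dtype=int)
        if self.region_id.shape != self.grid.shape:
            raise ValueError("region raster shape mismatch")
        labels = np.unique(self.region_id[self.region_id > 0])
        if labels.size and (labels.min() < 1 or labels.max() > self.N_REGIONS):
            raise ValueError("region labels must lie in 1..6")

    def regions_of_points(self, lon, lat) -> np.ndarray:
        """Region label per point; 0 for off-grid or unlabelled cells."""
        row, col = points_to_cells(np.asarray(lon), np.asarray(lat), self.grid)
        out = np.zeros(row.shape, dtype=int)
        ok = row >= 0
        out[ok] = self.region_id[row[ok], col[ok]]
        return out


def write_raster(layer: RasterLayer, path) -> None:
    """Write an ESRI ASCII grid; invalid cells become the nodata value."""
    g = layer.grid
    vals = np.where(layer.valid, layer.values, NODATA)
    header = (
        f"ncols {g.n_cols}\n"
        f"nrows {g.n_rows}\n"
        f"xllcorner {g.west!r}\n"
        f"yllcorner {g.south!r}\n"
        f"cellsize {g.cell_size!r}\n"
        f"NODATA_value {NODATA:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI ASCII is north-up: top row first
        for row in vals[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_raster(path, grid: GridSpec | None = None) -> RasterLayer:
    """Read an ESRI ASCII grid.

    When ``grid`` is given, the file's georeferencing must match it exactly;
    a mismatch raises ``ValueError`` naming the offending header field.
    """
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"malformed raster header: missing '{req}' in {path}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    file_grid = GridSpec(
        west=header["xllcorner"],
        south=header["yllcorner"],
        cell_size=header["cellsize"],
        n_cols=n_cols,
        n_rows=n_rows,
    )
    if grid is not None:
        for fld in ("west", "south", "cell_size", "n_cols", "n_rows"):
            got, want = getattr(file_grid, fld), getattr(grid, fld)
            if not np.isclose(got, want, rtol=0, atol=1e-9):
                raise ValueError(
                    f"raster {fld} = {got} does not match configured {fld} = {want}"
                )
        file_grid = grid
    vals = np.array(rows, dtype=float)
    if vals.shape != (n_rows, n_cols):
        raise ValueError(
            f"raster body shape {vals.shape} does not match header "
            f"({n_rows}, {n_cols})"
        )
    vals = vals[::-1]  # back to south-up
    nodata = header.get("nodata_value", NODATA)
    valid = ~np.isclose(vals, nodata, rtol=0, atol=1e-6)
    vals = np.where(valid, vals, np.nan)
    return RasterLayer(file_grid, vals, valid)


def write_region_raster(part: RegionPartition, path) -> None:
    layer = RasterLayer(part.grid, part.region_id.astype(float),
                        part.region_id > 0)
    write_raster(layer, path)


def read_region_raster(path, grid: GridSpec | None = None) -> RegionPartition:
    layer = read_raster(path, grid)
    ids = np.where(layer.valid, np.rint(layer.values), 0).astype(int)
    return RegionPartition(layer.grid, ids)
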