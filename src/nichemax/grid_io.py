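"""Grids, environmental raster stacks and occurrence records.

The analysis grid is a regular raster indexed row-major from the north-west
corner.  Cells are half-open, ``[x, x + dx) × (y − dy, y]``, so every point
maps to exactly one cell and occurrence deduplication is deterministic.
Rasters are read and written as ESRI ASCII grids (plain-text ``.asc``),
which round-trip exactly and keep fixtures human-readable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: Recognised coordinate-reference families.  ``geographic-WGS84`` grids are
#: in decimal degrees; ``equal-area-EPSG3035`` and ``synthetic-planar`` grids
#: are planar with cell sizes in metres (areas constant per cell).
CRS_TAGS = ("geographic-WGS84", "equal-area-EPSG3035", "synthetic-planar")

#: Default study extent (degrees): western Mediterranean up to southern
#: Scandinavia, the window the occurrence compilation covers.
STUDY_EXTENT = {"lat_min": 30.92, "lat_max": 59.26, "lon_min": -10.61, "lon_max": 42.16}


class GridMismatchError(ValueError):
    """Raised when layers or maps do not share the same grid geometry."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular analysis grid.

    ``origin_x``/``origin_y`` locate the north-west corner; cell ``(0, 0)``
    is the NW cell and indexing is row-major southwards.
    """

    n_rows: int
    n_cols: int
    origin_x: float
    origin_y: float
    cell_size_x: float
    cell_size_y: float
    crs_tag: str = "synthetic-planar"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size_x <= 0 or self.cell_size_y <= 0:
            raise ValueError("cell sizes must be positive")
        if self.crs_tag not in CRS_TAGS:
            raise ValueError(f"unknown crs_tag {self.crs_tag!r}; expected one of {CRS_TAGS}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_x, other.origin_x, abs_tol=1e-9)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=1e-9)
            and math.isclose(self.cell_size_x, other.cell_size_x, rel_tol=1e-12)
            and math.isclose(self.cell_size_y, other.cell_size_y, rel_tol=1e-12)
        )

    def cell_of(self, x: float | np.ndarray, y: float | np.ndarray):
        """Map point coordinates to (row, col); out-of-grid points give -1.

        Cells are half-open: ``[x, x+dx)`` horizontally and ``(y−dy, y]``
        vertically, measured from each cell's NW corner.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size_x).astype(int)
        # cell top edge inclusive, bottom edge exclusive
        row = np.floor((self.origin_y - y) / self.cell_size_y).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        row = np.where(inside, row, -1)
        col = np.where(inside, col, -1)
        return row, col

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.origin_x + (col + 0.5) * self.cell_size_x
        y = self.origin_y - (row + 0.5) * self.cell_size_y
        return x, y


@dataclass
class EnvStack:
    """Named environmental layers sharing one grid, plus a nodata mask."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    scenario: str = "current"
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.grid.shape:
                raise GridMismatchError(
                    f"layer {name!r} has shape {arr.shape}, expected {self.grid.shape}"
                )
            self.layers[name] = arr
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.grid.shape:
                raise GridMismatchError("nodata_mask shape does not match grid")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    def unmasked_cells(self) -> np.ndarray:
        """(k, 2) array of (row, col) indices of usable cells, row-major order."""
        rows, cols = np.nonzero(~self.nodata_mask)
        return np.column_stack([rows, cols])

    def values_at(self, cells: np.ndarray, layers: Sequence[str] | None = None) -> pd.DataFrame:
        """Extract layer values at (row, col) cell indices as a DataFrame."""
        cells = np.asarray(cells)
        names = list(layers) if layers is not None else self.layer_names
        data = {name: self.layers[name][cells[:, 0], cells[:, 1]] for name in names}
        return pd.DataFrame(data)

    def table(self, layers: Sequence[str] | None = None) -> pd.DataFrame:
        """All unmasked cells as a DataFrame (row-major order)."""
        return self.values_at(self.unmasked_cells(), layers)

    def with_scenario(self, scenario: str) -> "EnvStack":
        return EnvStack(self.grid, dict(self.layers), scenario, self.nodata_mask.copy())


@dataclass
class OccurrenceSet:
    """Presence-only records in WGS84 decimal degrees (or planar analogues).

    ``cell_row``/``cell_col`` are filled by :func:`dedup_to_grid`.
    """

    records: pd.DataFrame  # columns: longitude, latitude, optional source
    cell_row: np.ndarray | None = None
    cell_col: np.ndarray | None = None
    crs_tag: str = "geographic-WGS84"  # planar tags carry planar coordinates

    def __post_init__(self) -> None:
        df = self.records
        for col in ("longitude", "latitude"):
            if col not in df.columns:
                raise ValueError(f"occurrence table lacks column {col!r}")
        if self.crs_tag == "geographic-WGS84":
            lon = df["longitude"].to_numpy(dtype=float)
            lat = df["latitude"].to_numpy(dtype=float)
            if np.any((lon < -180) | (lon > 180)) or np.any((lat < -90) | (lat > 90)):
                raise ValueError("occurrence coordinates outside valid lon/lat ranges")

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_csv(cls, path: str | Path, crs_tag: str = "geographic-WGS84") -> "OccurrenceSet":
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        return cls(df, crs_tag=crs_tag)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    def cells(self) -> np.ndarray:
        if self.cell_row is None:
            raise ValueError("occurrences not yet assigned to a grid; run dedup_to_grid")
        return np.column_stack([self.cell_row, self.cell_col])


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def read_ascii_grid(path: str | Path, crs_tag: str = "synthetic-planar"):
    """Read one ESRI ASCII grid.  Returns ``(GridSpec, values, nodata_mask)``."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise OSError(f"cannot read raster file {path}: {exc}") from exc
    lines = text.splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII-grid header field {key!r}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    values = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data block shape {values.shape} != header ({n_rows}, {n_cols})")
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        cell_size_x=cell,
        cell_size_y=cell,
        crs_tag=crs_tag,
    )
    mask = np.isclose(values, nodata) | ~np.isfinite(values)
    values = np.where(mask, np.nan, values)
    return grid, values, mask


def write_ascii_grid(path: str | Path, grid: GridSpec, values: np.ndarray,
                     nodata: float = -9999.0) -> None:
    """Write one layer as an ESRI ASCII grid (requires square cells)."""
    if not math.isclose(grid.cell_size_x, grid.cell_size_y, rel_tol=1e-12):
        raise ValueError("ESRI ASCII grids require square cells")
    values = np.asarray(values, dtype=float)
    out = np.where(np.isfinite(values), values, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y - grid.n_rows * grid.cell_size_y!r}\n"
        f"cellsize {grid.cell_size_x!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")


def read_env_stack(paths: Sequence[str | Path], scenario: str,
                   crs_tag: str = "synthetic-planar",
                   names: Sequence[str] | None = None) -> EnvStack:
    """Read several single-layer rasters into one stack.

    Layer names default to file stems.  All files must share the grid
    geometry exactly; per-file nodata masks are unioned.
    """
    if not paths:
        raise ValueError("no raster paths given")
    if names is not None and len(names) != len(paths):
        raise ValueError("names and paths length mismatch")
    grid = None
    layers: dict[str, np.ndarray] = {}
    mask = None
    for k, p in enumerate(paths):
        name = names[k] if names is not None else Path(p).stem
        g, vals, m = read_ascii_grid(p, crs_tag=crs_tag)
        if grid is None:
            grid, mask = g, m
        else:
            if not grid.same_geometry(g):
                raise GridMismatchError(f"grid mismatch in layer {name!r} ({p})")
            mask = mask | m
        if name in layers:
            raise ValueError(f"duplicate layer name {name!r}")
        layers[name] = vals
    return EnvStack(grid, layers, scenario, mask)


def write_env_stack(stack: EnvStack, directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, vals in stack.layers.items():
        out = np.where(stack.nodata_mask, np.nan, vals)
        p = directory / f"{name}.asc"
        write_ascii_grid(p, stack.grid, out)
        written.append(p)
    return written


# ---------------------------------------------------------------------------
# Occurrence handling


def dedup_to_grid(occ: OccurrenceSet, grid: GridSpec,
                  nodata_mask: np.ndarray | None = None) -> OccurrenceSet:
    """Reduce occurrences to at most one per grid cell.

    The first record (input order) in each occupied cell is retained, which
    attenuates spatial autocorrelation from densely sampled localities.
    Records outside the grid, or on masked cells, are dropped; the counts
    are logged.  Idempotent.
    """
    df = occ.records.reset_index(drop=True)
    if len(df) == 0:
        return OccurrenceSet(df.copy(), np.array([], dtype=int), np.array([], dtype=int),
                             occ.crs_tag)
    row, col = grid.cell_of(df["longitude"].to_numpy(), df["latitude"].to_numpy())
    inside = row >= 0
    n_outside = int((~inside).sum())
    if nodata_mask is not None:
        on_land = inside.copy()
        on_land[inside] = ~nodata_mask[row[inside], col[inside]]
        n_masked = int(inside.sum() - on_land.sum())
        inside = on_land
    else:
        n_masked = 0
    keep_idx = np.flatnonzero(inside)
    cell_id = row[keep_idx] * grid.n_cols + col[keep_idx]
    _, first = np.unique(cell_id, return_index=True)
    keep_idx = keep_idx[np.sort(first)]
    if n_outside or n_masked:
        logger.info("dedup_to_grid: dropped %d outside grid, %d on masked cells",
                    n_outside, n_masked)
    logger.info("dedup_to_grid: %d records -> %d unique cells", len(df), len(keep_idx))
    out = df.iloc[keep_idx].reset_index(drop=True)
    return OccurrenceSet(out, row[keep_idx], col[keep_idx], occ.crs_tag)


# ---------------------------------------------------------------------------
# Terrain and area


def compute_slope(elevation: np.ndarray, grid: GridSpec, z_scale: float = 1.0) -> np.ndarray:
    """Slope in degrees from an elevation layer, Horn 3×3 finite differences.

    Border cells use edge replication.  ``z_scale`` converts elevation units
    to the grid's horizontal units (e.g. 1.0 for metres on a metre grid).
    """
    elevation = np.asarray(elevation, dtype=float)
    if elevation.shape != grid.shape:
        raise GridMismatchError("elevation shape does not match grid")
    if grid.n_rows < 2 or grid.n_cols < 2:
        raise ValueError("grid too small for slope")
    z = np.pad(elevation * z_scale, 1, mode="edge")
    # Horn kernel weights over the 3x3 neighbourhood
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * grid.cell_size_x)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * grid.cell_size_y)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


def cell_areas(grid: GridSpec) -> np.ndarray:
    """Per-cell area in km².

    Planar grids (equal-area or synthetic) have constant cell area
    ``dx·dy`` converted from m² to km².  Geographic grids use the spherical
    approximation ``R²·Δλ·Δφ·cos(φ_center)`` with R = 6371 km, adequate at
    kilometre scales.
    """
    if grid.crs_tag in ("equal-area-EPSG3035", "synthetic-planar"):
        area = grid.cell_size_x * grid.cell_size_y / 1e6
        return np.full(grid.shape, area)
    if grid.crs_tag == "geographic-WGS84":
        dlam = math.radians(grid.cell_size_x)
        dphi = math.radians(grid.cell_size_y)
        rows = np.arange(grid.n_rows)
        lat_center = grid.origin_y - (rows + 0.5) * grid.cell_size_y
        row_area = EARTH_RADIUS_KM ** 2 * dlam * dphi * np.cos(np.radians(lat_center))
        return np.repeat(row_area[:, None], grid.n_cols, axis=1)
    raise ValueError(f"unknown crs_tag {grid.crs_tag!r}")  # pragma: no cover


def resample_bilinear(stack: EnvStack, target: GridSpec) -> EnvStack:
    """Resample a (typically coarser) stack onto a target grid.

    Layer values are bilinearly interpolated at the target cell centers;
    the nodata mask is transferred by nearest neighbour.  Used to bring
    coarse palaeoclimate layers onto the analysis grid.
    """
    tr, tc = np.meshgrid(np.arange(target.n_rows), np.arange(target.n_cols), indexing="ij")
    x, y = target.cell_center(tr, tc)
    src = stack.grid
    # fractional source indices of the target cell centers
    fc = (x - src.origin_x) / src.cell_size_x - 0.5
    fr = (src.origin_y - y) / src.cell_size_y - 0.5
    coords = np.stack([fr.ravel(), fc.ravel()])
    layers = {}
    for name, vals in stack.layers.items():
        filled = np.where(stack.nodata_mask, np.nan, vals)
        # fill nodata with layer mean so interpolation near coasts stays finite;
        # masked-out cells are re-masked below
        fill = np.nanmean(filled)
        filled = np.where(np.isnan(filled), fill, filled)
        out = ndimage.map_coordinates(filled, coords, order=1, mode="nearest")
        layers[name] = out.reshape(target.shape)
    mask = ndimage.map_coordinates(stack.nodata_mask.astype(float), coords, order=0,
                                   mode="nearest").reshape(target.shape) > 0.5
    return EnvStack(target, layers, stack.scenario, mask)
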