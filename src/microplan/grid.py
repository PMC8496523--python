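"""Gridded population data model, Esri ASCII I/O, and zonal extraction.

A :class:`PopulationGrid` is a rectangular raster of non-negative integer
person counts per cell, stratified by age band and sex (the WorldPop-style
convention). Row 0 is the northernmost row, matching Esri ASCII grid order.
The total layer is always recomputed as the sum over strata, never trusted
from disk.

Two zonal inclusion rules are provided. The ``center`` rule credits a cell's
full count to a polygon iff the cell center lies inside it (boundary counts
as inside); it is integer-exact and partitions the grid, so covered plus
uncovered population always equals the grid total. The ``fraction`` rule
area-weights partially covered cells and converges to the center rule as
polygon edges approach cell boundaries.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import shapely
from shapely.geometry import box
from shapely.validation import explain_validity

from .errors import FormatError, GeometryError, ValidationError


class StratumKey(NamedTuple):
    """One age-band x sex slice of the population."""

    age_band: str
    sex: str


#: WorldPop-convention age bands: under-1, 1-4, then 5-year bands to 80+.
DEFAULT_AGE_BANDS = ("0", "1-4") + tuple(
    f"{lo}-{lo + 4}" for lo in range(5, 80, 5)
) + ("80+",)
SEXES = ("f", "m")


@dataclass
class PopulationGrid:
    """Raster of per-cell person counts, stratified by age band and sex."""

    ncols: int
    nrows: int
    xll: float
    yll: float
    cell_size_m: float
    strata: dict  # StratumKey -> (nrows, ncols) int64 array
    nodata_value: int = -9999

    def __post_init__(self):
        if self.ncols < 1 or self.nrows < 1:
            raise ValidationError("grid must have at least one row and column")
        if self.cell_size_m <= 0:
            raise ValidationError("cell_size_m must be positive")
        if not self.strata:
            raise ValidationError("grid needs at least one stratum")
        for key, arr in self.strata.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.shape != (self.nrows, self.ncols):
                raise ValidationError(f"stratum {key}: shape {arr.shape} != ({self.nrows}, {self.ncols})")
            if (arr < 0).any():
                raise ValidationError(f"stratum {key}: negative counts")
            self.strata[key] = arr

    @property
    def total(self) -> np.ndarray:
        """Per-cell total, recomputed as the sum over strata."""
        return sum(self.strata.values())

    @property
    def population(self) -> int:
        return int(self.total.sum())

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.xll, self.yll,
                self.xll + self.ncols * self.cell_size_m,
                self.yll + self.nrows * self.cell_size_m)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) center coordinate arrays of shape (nrows, ncols); row 0 is north."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.xll + (cols + 0.5) * self.cell_size_m
        y = self.yll + (self.nrows - rows - 0.5) * self.cell_size_m
        return np.meshgrid(x, y)


@dataclass
class ZonalResult:
    """Population aggregated over one polygon zone."""

    population_total: float
    population_by_stratum: dict
    n_cells: int
    rule: str


def _check_polygon(polygon):
    if polygon.is_empty:
        return
    if not polygon.is_valid:
        raise GeometryError(f"invalid polygon: {explain_validity(polygon)}")


def center_mask(grid: PopulationGrid, polygon) -> np.ndarray:
    """Boolean (nrows, ncols) mask of cells whose centers fall in the polygon.

    A center exactly on the boundary counts as inside.
    """
    _check_polygon(polygon)
    mask = np.zeros((grid.nrows, grid.ncols), dtype=bool)
    if polygon.is_empty:
        return mask
    X, Y = grid.cell_centers()
    minx, miny, maxx, maxy = polygon.bounds
    cand = (X >= minx) & (X <= maxx) & (Y >= miny) & (Y <= maxy)
    if cand.any():
        # intersects == inside-or-on-boundary for points
        mask[cand] = shapely.intersects_xy(polygon, X[cand], Y[cand])
    return mask


def zonal_population(grid: PopulationGrid, polygon, rule: str = "center") -> ZonalResult:
    """Population of the grid inside a polygon, under the chosen rule."""
    if rule == "center":
        mask = center_mask(grid, polygon)
        by = {k: int(arr[mask].sum()) for k, arr in grid.strata.items()}
        return ZonalResult(population_total=sum(by.values()),
                           population_by_stratum=by, n_cells=int(mask.sum()), rule=rule)
    if rule == "fraction":
        _check_polygon(polygon)
        weights = _fraction_weights(grid, polygon)
        by = {k: float((arr * weights).sum()) for k, arr in grid.strata.items()}
        return ZonalResult(population_total=float(sum(by.values())),
                           population_by_stratum=by,
                           n_cells=int((weights > 0).sum()), rule=rule)
    raise ValidationError(f"unknown zonal rule {rule!r} (expected 'center' or 'fraction')")


def _fraction_weights(grid: PopulationGrid, polygon) -> np.ndarray:
    """Per-cell fraction of cell area intersecting the polygon."""
    w = np.zeros((grid.nrows, grid.ncols), dtype=float)
    if polygon.is_empty:
        return w
    cs = grid.cell_size_m
    minx, miny, maxx, maxy = polygon.bounds
    c0 = max(0, math.floor((minx - grid.xll) / cs))
    c1 = min(grid.ncols, math.ceil((maxx - grid.xll) / cs))
    r0 = max(0, math.floor((grid.yll + grid.nrows * cs - maxy) / cs))
    r1 = min(grid.nrows, math.ceil((grid.yll + grid.nrows * cs - miny) / cs))
    area = cs * cs
    for r in range(r0, r1):
        ytop = grid.yll + (grid.nrows - r) * cs
        for c in range(c0, c1):
            cell = box(grid.xll + c * cs, ytop - cs, grid.xll + (c + 1) * cs, ytop)
            w[r, c] = cell.intersection(polygon).area / area
    return w


def uncovered_cells(grid: PopulationGrid, polygons) -> tuple[np.ndarray, int, dict]:
    """Cells whose centers fall in no polygon, and their population.

    Returns ``(mask, underserved_total, underserved_by_stratum)``. Under the
    center rule this partitions the grid exactly: covered + underserved
    equals the grid total as integers.
    """
    covered = np.zeros((grid.nrows, grid.ncols), dtype=bool)
    for poly in polygons:
        covered |= center_mask(grid, poly)
    mask = ~covered
    by = {k: int(arr[mask].sum()) for k, arr in grid.strata.items()}
    return mask, sum(by.values()), by


# ---------------------------------------------------------------------------
# Esri ASCII grid + manifest I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def read_asc(path) -> tuple[dict, np.ndarray]:
    """Read one Esri ASCII grid; returns (header dict, int array, north-first)."""
    header = {}
    data_start = 0
    lines = Path(path).read_text().splitlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            key = parts[0].lower()
            header[key] = float(parts[1])
            data_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing header key {key!r}")
    header.setdefault("nodata_value", -9999.0)
    vals = np.array(" ".join(lines[data_start:]).split(), dtype=np.int64)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if vals.size != nrows * ncols:
        raise FormatError(f"{path}: expected {nrows * ncols} values, found {vals.size}")
    return header, vals.reshape(nrows, ncols)


def write_asc(path, header: dict, data: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {int(header['ncols'])}\n")
        fh.write(f"nrows {int(header['nrows'])}\n")
        fh.write(f"xllcorner {header['xllcorner']:.6f}\n")
        fh.write(f"yllcorner {header['yllcorner']:.6f}\n")
        fh.write(f"cellsize {header['cellsize']:.6f}\n")
        fh.write(f"NODATA_value {int(header.get('nodata_value', -9999))}\n")
        for row in np.asarray(data, dtype=np.int64):
            fh.write(" ".join(str(v) for v in row) + "\n")


def read_grid(manifest_path) -> PopulationGrid:
    """Load a stratified grid from a ``manifest.csv`` of per-stratum rasters.

    Manifest columns: ``file,age_band,sex``; paths are resolved relative to
    the manifest. All rasters must agree on shape, origin and cell size.
    """
    manifest_path = Path(manifest_path)
    strata = {}
    ref_header = None
    with open(manifest_path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise FormatError(f"{manifest_path}: empty manifest")
    for row in rows:
        f = manifest_path.parent / row["file"]
        if not f.exists():
            raise FileNotFoundError(f"manifest references missing raster: {f}")
        header, data = read_asc(f)
        if ref_header is None:
            ref_header = header
        else:
            for key in _HEADER_KEYS[:5]:
                if not math.isclose(header[key], ref_header[key], rel_tol=0, abs_tol=1e-9):
                    raise FormatError(
                        f"{f}: header {key}={header[key]} disagrees with {ref_header[key]}")
        nodata = int(header["nodata_value"])
        data = np.where(data == nodata, 0, data)
        if (data < 0).any():
            raise ValidationError(f"{f}: negative population counts")
        key = StratumKey(row["age_band"], row["sex"])
        if key in strata:
            raise FormatError(f"{manifest_path}: duplicate stratum {key}")
        strata[key] = data
    return PopulationGrid(
        ncols=int(ref_header["ncols"]), nrows=int(ref_header["nrows"]),
        xll=ref_header["xllcorner"], yll=ref_header["yllcorner"],
        cell_size_m=ref_header["cellsize"], strata=strata,
        nodata_value=int(ref_header["nodata_value"]))


def write_grid(grid: PopulationGrid, out_dir) -> Path:
    """Write one .asc per stratum plus ``manifest.csv``; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = {"ncols": grid.ncols, "nrows": grid.nrows, "xllcorner": grid.xll,
              "yllcorner": grid.yll, "cellsize": grid.cell_size_m,
              "nodata_value": grid.nodata_value}
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["file", "age_band", "sex"])
        for key in sorted(grid.strata):
            fname = f"pop_{key.age_band.replace('-', '_').replace('+', 'plus')}_{key.sex}.asc"
            write_asc(out_dir / fname, header, grid.strata[key])
            w.writerow([fname, key.age_band, key.sex])
    return manifest


def write_mask_asc(path, grid: PopulationGrid, mask: np.ndarray) -> None:
    """Export a boolean cell mask as a 0/1 Esri ASCII grid."""
    header = {"ncols": grid.ncols, "nrows": grid.nrows, "xllcorner": grid.xll,
              "yllcorner": grid.yll, "cellsize": grid.cell_size_m, "nodata_value": -9999}
    write_asc(path, header, mask.astype(np.int64))
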