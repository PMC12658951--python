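"""Shared grid geometry, layer types, and raster/vector I/O.

All spatial layers in this package are views on a single raster grid
(:class:`SeascapeGrid`). Cells are indexed row-major from the top-left
corner; a flat cell id is ``r * n_cols + c``. Land cells are impassable
and carry no habitat, so every quantity of interest lives on water cells.

Rasters are read and written as single-band ESRI ASCII grids (``.asc``),
a plain-text format understood by every GIS. MPA polygons travel as
GeoJSON ``FeatureCollection`` files with an IUCN-category property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

__all__ = [
    "SeascapeGrid",
    "HabitatLayer",
    "DisturbanceLayer",
    "MPAStatusLayer",
    "SpeciesProfile",
    "Protection",
    "MPAPolygon",
    "STRICT_CATEGORIES",
    "DEFAULT_ALPHA",
    "read_raster_layer",
    "write_raster_layer",
    "rasterize_mpas",
    "read_mpas",
    "write_mpas",
]

#: IUCN categories treated as strict protection.
STRICT_CATEGORIES = frozenset({"Ia", "Ib", "II"})

#: Default dispersal-kernel steepness (moderately steep decline:
#: the kernel falls to exp(-1/0.3) ~ 0.036 of its origin value at d_max).
DEFAULT_ALPHA = 0.3

_HABITAT_CLASSES = (0.0, 0.5, 1.0)


class Protection(IntEnum):
    """Per-cell protection status; ordering encodes strictness."""

    UNPROTECTED = 0
    NONSTRICT = 1
    STRICT = 2


@dataclass(frozen=True)
class SeascapeGrid:
    """Raster geometry plus the land/water mask shared by all layers.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; at least 1 each.
    resolution
        Cell edge length in metres (projected planar coordinates).
    origin
        ``(x, y)`` of the grid's upper-left corner.
    water_mask
        Boolean ``(n_rows, n_cols)`` array, ``True`` on water.
    """

    n_rows: int
    n_cols: int
    resolution: float
    origin: tuple[float, float]
    water_mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")
        mask = np.asarray(self.water_mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"water_mask shape {mask.shape} does not match grid "
                f"({self.n_rows}, {self.n_cols})"
            )
        object.__setattr__(self, "water_mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_water(self) -> int:
        return int(self.water_mask.sum())

    def cell_center(self, r: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Planar coordinates of cell centers for row/col index arrays."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(c) + 0.5) * self.resolution
        y = y0 - (np.asarray(r) + 0.5) * self.resolution
        return x, y

    def same_geometry(self, other: "SeascapeGrid") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and self.resolution == other.resolution
            and self.origin == other.origin
        )

    def geometry_str(self) -> str:
        return (
            f"{self.n_rows}x{self.n_cols} @ {self.resolution} m, "
            f"origin {self.origin}"
        )


def _check_grid(grid: SeascapeGrid, values: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.shape != grid.shape:
        raise ValueError(
            f"{name} shape {arr.shape} does not match grid {grid.shape}"
        )
    return arr


@dataclass
class HabitatLayer:
    """Three-class habitat suitability s_i per cell (0.0 / 0.5 / 1.0).

    Positive suitability may occur only on water cells. The dispersal
    kernel accepts continuous qualities in [0, 1], but the habitat
    classifier used here emits exactly the three classes.
    """

    grid: SeascapeGrid
    quality: np.ndarray

    def __post_init__(self) -> None:
        q = _check_grid(self.grid, self.quality, "habitat quality").astype(float)
        bad = sorted(set(np.unique(q)) - set(_HABITAT_CLASSES))
        if bad:
            raise ValueError(f"habitat quality outside {{0.0, 0.5, 1.0}}: {bad}")
        if np.any((q > 0) & ~self.grid.water_mask):
            raise ValueError("positive habitat quality on land cells")
        self.quality = q

    @property
    def habitat_cells(self) -> np.ndarray:
        """Flat ids of cells with positive suitability, ascending."""
        return np.flatnonzero(self.quality.ravel() > 0)


@dataclass
class DisturbanceLayer:
    """Anthropogenic-disturbance zones 0-5 per cell (0 = undisturbed)."""

    grid: SeascapeGrid
    zone: np.ndarray

    def __post_init__(self) -> None:
        z = _check_grid(self.grid, self.zone, "disturbance zone")
        if not np.issubdtype(z.dtype, np.integer):
            zf = np.asarray(z, dtype=float)
            if not np.all(zf == np.round(zf)):
                raise ValueError("disturbance zones must be integers")
            z = zf.astype(np.int64)
        bad = sorted(set(np.unique(z)) - set(range(6)))
        if bad:
            raise ValueError(f"disturbance zones outside 0-5: {bad}")
        self.zone = z.astype(np.int64)


@dataclass
class MPAStatusLayer:
    """Per-cell protection status (unprotected / non-strict / strict)."""

    grid: SeascapeGrid
    status: np.ndarray

    def __post_init__(self) -> None:
        s = _check_grid(self.grid, self.status, "MPA status")
        s = np.asarray(s, dtype=np.int64)
        bad = sorted(set(np.unique(s)) - {int(p) for p in Protection})
        if bad:
            raise ValueError(f"invalid protection status values: {bad}")
        self.status = s

    def counted_mask(self, network: str) -> np.ndarray:
        """Cells counted as protected under the ``full`` or ``strict`` network."""
        if network == "full":
            return self.status >= Protection.NONSTRICT
        if network == "strict":
            return self.status == Protection.STRICT
        raise ValueError(f"unknown network {network!r} (use 'full' or 'strict')")


@dataclass
class SpeciesProfile:
    """A species' habitat map plus its dispersal parameters.

    ``d_max`` is the maximum dispersal distance in metres; beyond it the
    kernel is exactly zero. ``alpha`` sets the steepness of the
    negative-exponential decay (default 0.3).
    """

    name: str
    habitat: HabitatLayer
    d_max: float
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not self.d_max > 0:
            raise ValueError(f"{self.name}: d_max must be positive")
        if not self.alpha > 0:
            raise ValueError(f"{self.name}: alpha must be positive")


@dataclass(frozen=True)
class MPAPolygon:
    """One MPA polygon with its (possibly missing) IUCN category."""

    geometry: shapely.Geometry
    category: str | None = None

    @property
    def is_strict(self) -> bool:
        return self.category in STRICT_CATEGORIES


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

_NODATA = -9999


def _write_asc(path: Path, grid: SeascapeGrid, values: np.ndarray,
               fmt: str, nodata_mask: np.ndarray | None = None) -> None:
    x0, y0 = grid.origin
    lines = [
        f"ncols {grid.n_cols}",
        f"nrows {grid.n_rows}",
        f"xllcorner {x0!r}",
        f"yllcorner {y0 - grid.n_rows * grid.resolution!r}",
        f"cellsize {grid.resolution!r}",
        f"NODATA_value {_NODATA}",
    ]
    vals = values.astype(object)
    if nodata_mask is not None:
        vals = np.where(nodata_mask, _NODATA, vals)
    for row in vals:
        lines.append(" ".join(str(_NODATA) if v == _NODATA else fmt.format(v)
                              for v in row))
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")


def _read_asc(path: Path) -> tuple[dict, np.ndarray]:
    text = Path(path).read_text().split("\n")
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(text):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            break
    body = " ".join(text[i:])
    data = np.array(body.split(), dtype=float)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.size != n_rows * n_cols:
        raise ValueError(
            f"{path}: expected {n_rows * n_cols} cells, found {data.size}"
        )
    return header, data.reshape(n_rows, n_cols)


def _grid_from_header(header: dict, water_mask: np.ndarray) -> SeascapeGrid:
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    res = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * res)
    return SeascapeGrid(n_rows, n_cols, res, origin, water_mask)


def write_raster_layer(path: str | Path, layer) -> None:
    """Write a layer (or a grid's water mask) as an ESRI ASCII grid.

    Habitat and feature values are written as full-precision floats so a
    read-back reproduces them bit-exactly; zones and statuses as integers.
    Land cells of the mask raster are written as NODATA.
    """
    path = Path(path)
    if isinstance(layer, SeascapeGrid):
        _write_asc(path, layer, layer.water_mask.astype(int), "{:d}",
                   nodata_mask=~layer.water_mask)
    elif isinstance(layer, HabitatLayer):
        _write_asc(path, layer.grid, layer.quality, "{!r}")
    elif isinstance(layer, DisturbanceLayer):
        _write_asc(path, layer.grid, layer.zone, "{:d}")
    elif isinstance(layer, MPAStatusLayer):
        _write_asc(path, layer.grid, layer.status, "{:d}")
    else:  # generic float layer, e.g. a FeatureLayer amount grid
        grid, values = layer.grid, np.asarray(layer.amount, dtype=float)
        _write_asc(path, grid, values, "{!r}")


def read_raster_layer(path: str | Path, kind: str,
                      grid: SeascapeGrid | None = None):
    """Read a single-band ASCII raster as a typed layer.

    Parameters
    ----------
    kind
        ``"mask"`` returns a :class:`SeascapeGrid` (NODATA pixels become
        land); ``"habitat"`` / ``"disturbance"`` / ``"status"`` return the
        corresponding layer bound to ``grid`` (NODATA maps to 0).
    grid
        Required for every kind except ``"mask"``; the raster geometry
        must match it exactly.
    """
    header, data = _read_asc(path)
    nodata = header.get("nodata_value", _NODATA)
    if kind == "mask":
        water = (data != nodata) & (data > 0)
        return _grid_from_header(header, water)
    if grid is None:
        raise ValueError(f"kind={kind!r} requires a reference grid")
    file_grid = _grid_from_header(header, np.ones(data.shape, dtype=bool))
    if not grid.same_geometry(file_grid):
        raise ValueError(
            f"{path}: raster geometry ({file_grid.geometry_str()}) does not "
            f"match reference grid ({grid.geometry_str()})"
        )
    values = np.where(data == nodata, 0.0, data)
    if kind == "habitat":
        return HabitatLayer(grid, values)
    if kind == "disturbance":
        return DisturbanceLayer(grid, values)
    if kind == "status":
        return MPAStatusLayer(grid, values)
    if kind == "feature":
        return values
    raise ValueError(f"unknown raster kind {kind!r}")


# ---------------------------------------------------------------------------
# MPA polygons (GeoJSON) and rasterization
# ---------------------------------------------------------------------------

def write_mpas(path: str | Path, mpas: Sequence[MPAPolygon],
               category_field: str = "iucn_cat") -> None:
    features = []
    for m in mpas:
        props = {} if m.category is None else {category_field: m.category}
        features.append({
            "type": "Feature",
            "properties": props,
            "geometry": geom_mapping(m.geometry),
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}, indent=1))


def read_mpas(path: str | Path, category_field: str = "iucn_cat"
              ) -> list[MPAPolygon]:
    doc = json.loads(Path(path).read_text())
    mpas = []
    for feat in doc.get("features", []):
        cat = (feat.get("properties") or {}).get(category_field)
        mpas.append(MPAPolygon(geom_shape(feat["geometry"]), cat))
    return mpas


def rasterize_mpas(mpas: Iterable[MPAPolygon], grid: SeascapeGrid
                   ) -> MPAStatusLayer:
    """Rasterize MPA polygons to a per-cell protection status.

    A cell is protected when its center lies inside at least one polygon.
    IUCN categories Ia, Ib and II count as strict; any other category, or
    a missing one, as non-strict. Overlaps resolve to the strictest
    designation present, so the result is independent of polygon order.
    """
    status = np.zeros(grid.shape, dtype=np.int64)
    res = grid.resolution
    x0, y0 = grid.origin
    for m in mpas:
        if m.geometry.is_empty:
            continue
        if not m.geometry.is_valid:
            raise ValueError(f"invalid MPA geometry: {m.category!r}")
        minx, miny, maxx, maxy = m.geometry.bounds
        c_lo = max(int(np.floor((minx - x0) / res - 0.5)), 0)
        c_hi = min(int(np.ceil((maxx - x0) / res - 0.5)), grid.n_cols - 1)
        r_lo = max(int(np.floor((y0 - maxy) / res - 0.5)), 0)
        r_hi = min(int(np.ceil((y0 - miny) / res - 0.5)), grid.n_rows - 1)
        if c_lo > c_hi or r_lo > r_hi:
            continue
        rr, cc = np.meshgrid(np.arange(r_lo, r_hi + 1),
                             np.arange(c_lo, c_hi + 1), indexing="ij")
        x, y = grid.cell_center(rr.ravel(), cc.ravel())
        inside = shapely.contains_xy(m.geometry, x, y)
        level = Protection.STRICT if m.is_strict else Protection.NONSTRICT
        block = status[r_lo:r_hi + 1, c_lo:c_hi + 1]
        np.maximum(block, np.where(inside.reshape(rr.shape), int(level), 0),
                   out=block)
    return MPAStatusLayer(grid, status)
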