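"""Raster/vector/table I/O and grid-alignment contracts.

Every raster in a pipeline run lives on one shared north-up grid in a
projected, metre-unit CRS.  A :class:`Grid` carries the array, the affine
georeferencing (GDAL-style 6-tuple), a square cell size in metres, a nodata
sentinel and a CRS identifier; :func:`align_stack` brings heterogeneous
inputs (e.g. a 30 m DEM and a 300 m land-cover product) onto the reference
grid before any analysis.

GeoTIFF support is a deliberately small subset written directly with
``tifffile``: single band, north-up, ModelPixelScale + ModelTiepoint +
GDAL_NODATA tags, CRS identifier stored as JSON in ImageDescription.
Rotated/sheared rasters and geographic (degree-unit) CRSes are rejected.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
from scipy.ndimage import map_coordinates
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

__all__ = [
    "Grid",
    "VectorLayer",
    "read_grid",
    "write_grid",
    "align_stack",
    "rasterize",
    "read_geojson",
    "write_geojson",
    "read_roster",
    "read_facilities",
]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_MODEL_TRANSFORMATION = 34264
_GDAL_NODATA = 42113
_IMAGE_DESCRIPTION = 270

DEFAULT_CRS = "EPSG:32738"  # UTM zone 38S; any projected metre CRS id is accepted


@dataclass
class Grid:
    """A single-band north-up raster in a projected metre CRS.

    ``transform`` is the GDAL 6-tuple ``(x0, dx, 0, y0, 0, -dy)`` mapping
    (col,row) pixel corners to map coordinates; row 0 / col 0 is the
    north-west corner and a cell's value refers to the whole cell.
    """

    values: np.ndarray
    transform: tuple[float, float, float, float, float, float]
    cell_size: float
    nodata: float = float("nan")
    crs_id: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be a 2-D array")
        x0, dx, rot1, y0, rot2, dy = self.transform
        if rot1 != 0 or rot2 != 0:
            raise ValueError("non-north-up raster: rotated/sheared transform")
        if dx <= 0 or dy >= 0:
            raise ValueError("Grid must be north-up with positive cell size")
        if not math.isclose(dx, -dy):
            raise ValueError("Grid cells must be square")
        if not math.isclose(dx, self.cell_size):
            raise ValueError("cell_size inconsistent with transform")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def x0(self) -> float:
        return self.transform[0]

    @property
    def y0(self) -> float:
        return self.transform[3]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        rows, cols = self.shape
        return (
            self.x0,
            self.y0 - rows * self.cell_size,
            self.x0 + cols * self.cell_size,
            self.y0,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell center, each shaped like values."""
        rows, cols = self.shape
        xs = self.x0 + (np.arange(cols) + 0.5) * self.cell_size
        ys = self.y0 - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; raises if outside."""
        col = int(math.floor((x - self.x0) / self.cell_size))
        row = int(math.floor((self.y0 - y) / self.cell_size))
        rows, cols = self.shape
        if not (0 <= row < rows and 0 <= col < cols):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x0 + (col + 0.5) * self.cell_size,
            self.y0 - (row + 0.5) * self.cell_size,
        )

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and all(
                math.isclose(a, b, abs_tol=1e-6)
                for a, b in zip(self.transform, other.transform)
            )
            and self.crs_id == other.crs_id
        )

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """New Grid sharing this grid's geometry."""
        nd = self.nodata if nodata is None else nodata
        return Grid(np.asarray(values), self.transform, self.cell_size, nd, self.crs_id)


def make_grid(
    values: np.ndarray,
    cell_size: float,
    x0: float = 0.0,
    y0: float | None = None,
    nodata: float = float("nan"),
    crs_id: str = DEFAULT_CRS,
) -> Grid:
    """Convenience constructor; default origin puts (xmin, ymin) at (0, 0)."""
    values = np.asarray(values)
    if y0 is None:
        y0 = values.shape[0] * cell_size
    transform = (x0, cell_size, 0.0, y0, 0.0, -cell_size)
    return Grid(values, transform, cell_size, nodata, crs_id)


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_grid(path: str | Path, grid: Grid) -> None:
    """Write a Grid as a single-band GeoTIFF (lossless round-trip)."""
    desc = json.dumps({"crs_id": grid.crs_id, "units": "m"}, sort_keys=True)
    nodata_str = "nan" if isinstance(grid.nodata, float) and math.isnan(grid.nodata) else repr(grid.nodata)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0)),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x0, grid.y0, 0.0)),
        (_GDAL_NODATA, "s", 0, nodata_str),
    ]
    tifffile.imwrite(
        str(path),
        grid.values,
        description=desc,
        extratags=extratags,
        photometric="minisblack",
    )


def read_grid(path: str | Path, expected_cell_size: float | None = None) -> Grid:
    """Read a single-band projected GeoTIFF into a Grid.

    Raises on rotated/sheared georeferencing and on geographic (degree-unit)
    CRS metadata — inputs must be reprojected to a metre CRS beforehand.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        if _MODEL_TRANSFORMATION in tags:
            m = np.asarray(tags[_MODEL_TRANSFORMATION].value, dtype=float).reshape(4, 4)
            if m[0, 1] != 0 or m[1, 0] != 0:
                raise ValueError("non-north-up raster: rotated/sheared transform")
            dx, dy = m[0, 0], m[1, 1]
            x0, y0 = m[0, 3], m[1, 3]
        elif _MODEL_PIXEL_SCALE in tags and _MODEL_TIEPOINT in tags:
            scale = tags[_MODEL_PIXEL_SCALE].value
            tie = tags[_MODEL_TIEPOINT].value
            dx, dy = float(scale[0]), -float(scale[1])
            # tiepoint: raster (i,j,k) -> model (x,y,z)
            x0 = float(tie[3]) - float(tie[0]) * dx
            y0 = float(tie[4]) - float(tie[1]) * dy
        else:
            raise ValueError(f"{path}: no GeoTIFF georeferencing tags found")

        crs_id = DEFAULT_CRS
        if _IMAGE_DESCRIPTION in tags:
            try:
                meta = json.loads(tags[_IMAGE_DESCRIPTION].value)
                crs_id = meta.get("crs_id", crs_id)
                if meta.get("units", "m") not in ("m", "meter", "metre"):
                    raise ValueError(
                        f"{path}: geographic (degree-unit) CRS; reproject to a metre CRS first"
                    )
            except json.JSONDecodeError:
                pass
        if crs_id.upper() in ("EPSG:4326", "CRS84", "OGC:CRS84"):
            raise ValueError(
                f"{path}: geographic (degree-unit) CRS; reproject to a metre CRS first"
            )

        nodata: float = float("nan")
        if _GDAL_NODATA in tags:
            s = str(tags[_GDAL_NODATA].value).strip().strip("\x00")
            nodata = float("nan") if s.lower() == "nan" else float(s)

    cell = dx
    if expected_cell_size is not None and not math.isclose(cell, expected_cell_size):
        raise ValueError(
            f"{path}: cell size {cell} m, expected {expected_cell_size} m"
        )
    return Grid(values, (x0, dx, 0.0, y0, 0.0, dy), cell, nodata, crs_id)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

Resampling = Literal["nearest", "bilinear"]


def align_stack(
    grids: Sequence[Grid],
    reference: Grid,
    resampling: Sequence[Resampling] | None = None,
) -> list[Grid]:
    """Resample each grid onto the reference geometry.

    Categorical layers should use ``nearest``; continuous layers default to
    ``bilinear``.  Each output grid shares the reference transform, shape and
    CRS id.  Raises if a grid's extent does not overlap the reference.
    """
    if resampling is None:
        resampling = ["bilinear"] * len(grids)
    if len(resampling) != len(grids):
        raise ValueError("one resampling mode per grid required")

    ref_x, ref_y = reference.cell_centers()
    out: list[Grid] = []
    for grid, mode in zip(grids, resampling):
        if grid.crs_id != reference.crs_id:
            raise ValueError(
                f"CRS mismatch: {grid.crs_id} vs reference {reference.crs_id}"
            )
        gxmin, gymin, gxmax, gymax = grid.bounds
        rxmin, rymin, rxmax, rymax = reference.bounds
        if gxmax <= rxmin or gxmin >= rxmax or gymax <= rymin or gymin >= rymax:
            raise ValueError("grid extent is disjoint from reference extent")
        if grid.same_geometry(reference):
            out.append(grid.with_values(grid.values.copy()))
            continue
        # fractional (row, col) of reference centers in the source grid
        col_f = (ref_x - grid.x0) / grid.cell_size - 0.5
        row_f = (grid.y0 - ref_y) / grid.cell_size - 0.5
        order = 0 if mode == "nearest" else 1
        vals = map_coordinates(
            np.asarray(grid.values, dtype=float),
            [row_f, col_f],
            order=order,
            mode="nearest",
        )
        if mode == "nearest" and np.issubdtype(grid.values.dtype, np.integer):
            vals = vals.astype(grid.values.dtype)
        out.append(
            Grid(vals, reference.transform, reference.cell_size, grid.nodata, reference.crs_id)
        )
    return out


# ---------------------------------------------------------------------------
# Vector layers
# ---------------------------------------------------------------------------

@dataclass
class VectorLayer:
    """Features (shapely geometry + attribute dict) in one projected CRS."""

    features: list[tuple[shapely.Geometry, dict]] = field(default_factory=list)
    crs_id: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        for geom, _ in self.features:
            if geom.geom_type in ("Polygon", "MultiPolygon") and not geom.is_valid:
                raise ValueError("invalid polygon geometry (self-intersection?)")

    def __len__(self) -> int:
        return len(self.features)

    def geometries(self) -> list[shapely.Geometry]:
        return [g for g, _ in self.features]

    def attribute(self, key: str) -> list:
        return [a.get(key) for _, a in self.features]


def read_geojson(path: str | Path, crs_id: str = DEFAULT_CRS) -> VectorLayer:
    with open(path) as fh:
        data = json.load(fh)
    if "crs_id" in data:
        crs_id = data["crs_id"]
    feats = [
        (geom_shape(f["geometry"]), dict(f.get("properties") or {}))
        for f in data["features"]
    ]
    return VectorLayer(feats, crs_id)


def write_geojson(path: str | Path, layer: VectorLayer) -> None:
    data = {
        "type": "FeatureCollection",
        "crs_id": layer.crs_id,
        "features": [
            {"type": "Feature", "geometry": geom_mapping(g), "properties": a}
            for g, a in layer.features
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def rasterize(
    layer: VectorLayer,
    reference: Grid,
    burn_value_field: str | None = None,
    burn_value: float = 1.0,
    nodata: float = 0.0,
) -> Grid:
    """Burn vector features onto the reference grid.

    Polygons burn cells whose *center* is covered; polylines burn every cell
    whose center lies within half a cell size of the line (a supercover-like
    rule that keeps roads 8-connected on the cost graph); points burn their
    containing cell.  Later features overwrite earlier ones.
    """
    if layer.crs_id != reference.crs_id:
        raise ValueError("layer CRS does not match reference grid CRS")
    out = np.full(reference.shape, nodata, dtype=float)
    if len(layer) == 0:
        warnings.warn("rasterize: empty layer, returning all-nodata grid")
        return reference.with_values(out, nodata=nodata)

    cx, cy = reference.cell_centers()
    pts = None  # built lazily: shapely point array of all cell centers
    half = reference.cell_size / 2.0

    for geom, attrs in layer.features:
        val = float(attrs[burn_value_field]) if burn_value_field else burn_value
        gtype = geom.geom_type
        if gtype in ("Polygon", "MultiPolygon"):
            minx, miny, maxx, maxy = geom.bounds
            win = (cx >= minx - half) & (cx <= maxx + half) & (cy >= miny - half) & (cy <= maxy + half)
            rows, cols = np.nonzero(win)
            if rows.size == 0:
                continue
            inside = shapely.contains_xy(geom, cx[rows, cols], cy[rows, cols])
            out[rows[inside], cols[inside]] = val
        elif gtype in ("LineString", "MultiLineString"):
            minx, miny, maxx, maxy = geom.bounds
            pad = half * 1.5
            win = (cx >= minx - pad) & (cx <= maxx + pad) & (cy >= miny - pad) & (cy <= maxy + pad)
            rows, cols = np.nonzero(win)
            if rows.size == 0:
                continue
            if pts is None:
                pts = shapely.points(np.column_stack([cx.ravel(), cy.ravel()])).reshape(cx.shape)
            d = shapely.distance(geom, pts[rows, cols])
            near = d <= half
            out[rows[near], cols[near]] = val
        elif gtype in ("Point", "MultiPoint"):
            geoms = geom.geoms if gtype == "MultiPoint" else [geom]
            for p in geoms:
                try:
                    r, c = reference.index_of(p.x, p.y)
                except ValueError:
                    continue
                out[r, c] = val
        else:
            raise ValueError(f"unsupported geometry type {gtype}")
    return reference.with_values(out, nodata=nodata)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

ROSTER_COLUMNS = ["fokontany_id", "n_acs", "assigned_csb_id", "assigned_pa_id"]
FACILITY_COLUMNS = ["facility_id", "kind", "x", "y", "eligible"]


def read_roster(path: str | Path) -> pd.DataFrame:
    """Read the per-fokontany worker roster.

    Required columns: fokontany_id, n_acs, assigned_csb_id, assigned_pa_id
    (assigned_pa_id may be empty where the commune has no supply point).
    """
    df = pd.read_csv(path, dtype={"fokontany_id": str, "assigned_csb_id": str, "assigned_pa_id": str})
    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"roster missing columns: {missing}")
    if df["fokontany_id"].duplicated().any():
        raise ValueError("roster fokontany_id values must be unique")
    if (df["n_acs"] < 0).any():
        raise ValueError("n_acs must be >= 0")
    return df


def read_facilities(path: str | Path) -> pd.DataFrame:
    """Read the facility table (health centers and supply points).

    Required columns: facility_id, kind (CSB|PA), x, y; optional eligible flag
    (facilities without any assigned workers are ineligible for reassignment).
    """
    df = pd.read_csv(path, dtype={"facility_id": str, "kind": str})
    missing = [c for c in ("facility_id", "kind", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"facility table missing columns: {missing}")
    bad = set(df["kind"]) - {"CSB", "PA"}
    if bad:
        raise ValueError(f"unknown facility kinds: {sorted(bad)}")
    if "eligible" not in df.columns:
        df["eligible"] = True
    df["eligible"] = df["eligible"].astype(bool)
    return df


def validate_roster_against_facilities(roster: pd.DataFrame, facilities: pd.DataFrame) -> pd.DataFrame:
    """Flag roster rows whose assigned facility ids do not resolve."""
    known = set(facilities["facility_id"])
    roster = roster.copy()
    roster["csb_missing"] = ~roster["assigned_csb_id"].isin(known) & roster["assigned_csb_id"].notna()
    roster["pa_missing"] = ~roster["assigned_pa_id"].isin(known) & roster["assigned_pa_id"].notna()
    return roster
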