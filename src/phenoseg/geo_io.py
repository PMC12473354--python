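"""Raster and vector IO on a shared scene grid.

Rasters are single- or multi-band float32 GeoTIFFs read and written through
tifffile, carrying the standard GeoTIFF georeferencing tags (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory with the EPSG code).  Vector parcels are
GeoJSON FeatureCollections handled with shapely.  All pixel arithmetic uses
0-based indices, half-open windows, row 0 at the top (north); polygon
coordinates are in projected CRS units (metres).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from scipy import ndimage
from shapely.geometry import Polygon, box, mapping, shape
from shapely.ops import unary_union

logger = logging.getLogger(__name__)

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735

# 4-connectivity structuring element for component labelling
FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SceneGrid:
    """Regular raster grid in a projected CRS.

    ``origin`` is the (x, y) of the *top-left corner* of pixel (0, 0); y
    decreases with increasing row (north-up).
    """

    width: int
    height: int
    pixel_size: float = 3.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs_id: str = "EPSG:32633"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def pixel_centres(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Projected (x, y) coordinates of pixel centres."""
        ox, oy = self.origin
        x = ox + (np.asarray(cols, dtype=float) + 0.5) * self.pixel_size
        y = oy - (np.asarray(rows, dtype=float) + 0.5) * self.pixel_size
        return x, y

    def corner_xy(self, row: float, col: float) -> tuple[float, float]:
        """Projected coordinates of the pixel-corner lattice point (row, col)."""
        ox, oy = self.origin
        return ox + col * self.pixel_size, oy - row * self.pixel_size


@dataclass
class NDVIStack:
    """Per-pixel NDVI time series on a shared grid.

    ``values`` has shape (T, H, W); ``dates`` are ordinal days, strictly
    increasing; ``valid_mask`` flags per-pixel-per-date validity.
    """

    values: np.ndarray
    dates: np.ndarray
    valid_mask: np.ndarray
    grid: SceneGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        self.dates = np.asarray(self.dates, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        if self.values.shape[0] != self.dates.shape[0]:
            raise ValueError("time axis length does not match dates")
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError("raster shape does not match grid")
        if np.any(np.diff(self.dates) <= 0):
            raise ValueError("dates must be strictly increasing")
        finite = self.valid_mask & np.isfinite(self.values)
        vals = self.values[finite]
        if vals.size and (vals.min() < -1.0 - 1e-6 or vals.max() > 1.0 + 1e-6):
            raise ValueError("valid NDVI values must lie in [-1, 1]")


@dataclass
class ParcelSet:
    """Collection of simple parcel polygons with unique integer ids."""

    polygons: list[Polygon]
    ids: np.ndarray
    crs_id: str = "EPSG:32633"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        if len(self.polygons) != len(self.ids):
            raise ValueError("polygons and ids length mismatch")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("parcel ids must be unique")

    def __len__(self) -> int:
        return len(self.polygons)

    @property
    def areas(self) -> np.ndarray:
        return np.array([p.area for p in self.polygons], dtype=float)

    def subset(self, indices: Iterable[int]) -> "ParcelSet":
        idx = list(indices)
        return ParcelSet([self.polygons[i] for i in idx], self.ids[idx], self.crs_id)

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"id": int(pid), "area_m2": poly.area},
                "geometry": mapping(poly),
            }
            for poly, pid in zip(self.polygons, self.ids)
        ]
        doc = {
            "type": "FeatureCollection",
            "crs": {"type": "name", "properties": {"name": self.crs_id}},
            "features": features,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_geojson(cls, path: str | Path) -> "ParcelSet":
        doc = json.loads(Path(path).read_text())
        crs = doc.get("crs", {}).get("properties", {}).get("name", "EPSG:32633")
        polys, ids = [], []
        for i, feat in enumerate(doc["features"]):
            geom = shape(feat["geometry"])
            geom = repair_polygon(geom)
            if geom.is_empty:
                continue
            polys.append(geom)
            ids.append(feat.get("properties", {}).get("id", i + 1))
        return cls(polys, np.asarray(ids), crs)


def repair_polygon(geom):
    """Repair an invalid polygon with make_valid, keeping the largest part."""
    if not geom.is_valid:
        geom = shapely.make_valid(geom)
    if geom.geom_type == "MultiPolygon":
        geom = max(geom.geoms, key=lambda g: g.area)
    elif geom.geom_type == "GeometryCollection":
        parts = [g for g in geom.geoms if g.geom_type == "Polygon"]
        geom = max(parts, key=lambda g: g.area) if parts else Polygon()
    return geom


# ---------------------------------------------------------------------------
# NDVI and raster IO
# ---------------------------------------------------------------------------

def compute_ndvi(nir: np.ndarray, red: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """NDVI = (NIR - RED) / (NIR + RED) with a validity mask.

    Pixels where NIR + RED == 0 (or either band is non-finite) are marked
    invalid rather than raising.
    Returns ``(ndvi, valid)``.
    """
    nir = np.asarray(nir, dtype=np.float64)
    red = np.asarray(red, dtype=np.float64)
    if nir.shape != red.shape:
        raise ValueError("NIR and RED grids must share a shape")
    denom = nir + red
    valid = np.isfinite(denom) & (denom != 0)
    ndvi = np.full(nir.shape, np.nan, dtype=np.float64)
    np.divide(nir - red, denom, out=ndvi, where=valid)
    return ndvi.astype(np.float32), valid


def write_geotiff(path: str | Path, data: np.ndarray, grid: SceneGrid) -> None:
    """Write a float32 (H, W) or (H, W, B) GeoTIFF with georeferencing tags."""
    data = np.asarray(data, dtype=np.float32)
    epsg = int(grid.crs_id.split(":")[-1]) if ":" in grid.crs_id else 32633
    ox, oy = grid.origin
    # minimal GeoKeyDirectory: projected CRS by EPSG code
    geokeys = (1, 1, 0, 2, 1024, 0, 1, 1, 3072, 0, 1, epsg)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.pixel_size, grid.pixel_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, ox, oy, 0.0)),
        (_TAG_GEOKEYS, "H", len(geokeys), geokeys),
    ]
    photometric = "minisblack" if data.ndim == 2 else "rgb"
    tifffile.imwrite(path, data, photometric=photometric, extratags=extratags)


def read_geotiff(path: str | Path) -> tuple[np.ndarray, SceneGrid]:
    """Read a GeoTIFF written by :func:`write_geotiff` (or compatible)."""
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = tif.asarray()
            tags = page.tags
            px = 1.0
            origin = (0.0, 0.0)
            crs = "EPSG:32633"
            if _TAG_PIXEL_SCALE in tags:
                px = float(tags[_TAG_PIXEL_SCALE].value[0])
            if _TAG_TIEPOINT in tags:
                tp = tags[_TAG_TIEPOINT].value
                origin = (float(tp[3]), float(tp[4]))
            if _TAG_GEOKEYS in tags:
                gk = tags[_TAG_GEOKEYS].value
                for i in range(4, len(gk) - 3, 4):
                    if gk[i] == 3072:
                        crs = f"EPSG:{gk[i + 3]}"
    except (tifffile.TiffFileError, OSError) as exc:
        raise IOError(f"unreadable raster: {path}: {exc}") from exc
    h, w = data.shape[:2]
    return data, SceneGrid(width=w, height=h, pixel_size=px, origin=origin, crs_id=crs)


def read_stack(
    scene_paths: Sequence[str | Path],
    dates: Sequence[float],
    nir_band: int | None = None,
    red_band: int | None = None,
) -> NDVIStack:
    """Stack per-date NDVI rasters into an :class:`NDVIStack`.

    Single-band scenes are taken as NDVI directly; multiband scenes require
    1-based ``nir_band`` and ``red_band`` indices (band roles are sensor
    configuration, e.g. nir_band=8, red_band=6 for SuperDove).  Scenes must
    share grid and CRS; dates are sorted ascending and slices reordered
    consistently.
    """
    if len(scene_paths) != len(dates):
        raise ValueError("number of scenes must equal number of dates")
    if len(scene_paths) == 0:
        raise ValueError("at least one scene is required")
    order = np.argsort(np.asarray(dates, dtype=float), kind="stable")
    ref_grid: SceneGrid | None = None
    slices: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for i in order:
        path = scene_paths[i]
        data, grid = read_geotiff(path)
        if ref_grid is None:
            ref_grid = grid
        elif grid != ref_grid:
            raise ValueError(f"scene grid mismatch: {path} differs from {scene_paths[order[0]]}")
        if data.ndim == 2:
            ndvi = data.astype(np.float32)
            valid = np.isfinite(ndvi)
        else:
            if nir_band is None or red_band is None:
                raise ValueError(f"multiband scene {path} requires nir_band and red_band")
            ndvi, valid = compute_ndvi(data[..., nir_band - 1], data[..., red_band - 1])
        slices.append(ndvi)
        masks.append(valid)
    assert ref_grid is not None
    return NDVIStack(
        values=np.stack(slices),
        dates=np.asarray(dates, dtype=float)[order],
        valid_mask=np.stack(masks),
        grid=ref_grid,
    )


# ---------------------------------------------------------------------------
# Rasterization and polygonization
# ---------------------------------------------------------------------------

def rasterize_parcels(
    parcels: ParcelSet, grid: SceneGrid, binary: bool = False
) -> np.ndarray:
    """Burn parcels onto the grid using the pixel-centre rule.

    A pixel is assigned a parcel id iff its centre lies inside the polygon;
    background is 0.  In ``binary`` mode overlapping polygons burn the union
    (all burnt pixels get 1).  In label mode later parcels overwrite earlier
    ones where they overlap (ground truth is assumed non-overlapping).
    """
    labels = np.zeros(grid.shape, dtype=np.int32)
    ox, oy = grid.origin
    px = grid.pixel_size
    for poly, pid in zip(parcels.polygons, parcels.ids):
        if poly.is_empty:
            continue
        minx, miny, maxx, maxy = poly.bounds
        c0 = max(int(np.floor((minx - ox) / px - 0.5)), 0)
        c1 = min(int(np.ceil((maxx - ox) / px + 0.5)), grid.width)
        r0 = max(int(np.floor((oy - maxy) / px - 0.5)), 0)
        r1 = min(int(np.ceil((oy - miny) / px + 0.5)), grid.height)
        if c0 >= c1 or r0 >= r1:
            continue
        rows, cols = np.mgrid[r0:r1, c0:c1]
        xs, ys = grid.pixel_centres(rows.ravel(), cols.ravel())
        inside = shapely.contains_xy(poly, xs, ys).reshape(rows.shape)
        value = 1 if binary else int(pid)
        labels[r0:r1, c0:c1][inside] = value
    return labels


def _runs_to_boxes(mask: np.ndarray, grid: SceneGrid) -> list[Polygon]:
    """Row run-length encode a boolean mask into pixel-edge rectangles."""
    boxes: list[Polygon] = []
    px = grid.pixel_size
    for r in range(mask.shape[0]):
        row = mask[r]
        if not row.any():
            continue
        diff = np.diff(np.concatenate(([0], row.view(np.int8), [0])))
        starts = np.flatnonzero(diff == 1)
        stops = np.flatnonzero(diff == -1)
        y_top = grid.origin[1] - r * px
        y_bot = y_top - px
        for c0, c1 in zip(starts, stops):
            x0 = grid.origin[0] + c0 * px
            x1 = grid.origin[0] + c1 * px
            boxes.append(box(x0, y_bot, x1, y_top))
    return boxes


def mask_to_polygons(mask: np.ndarray, grid: SceneGrid) -> list[Polygon]:
    """Exact pixel-edge polygons of the 4-connected components of a mask.

    Holes are preserved as interior rings; no filling, no morphology, no
    smoothing.  A component that only self-touches at a pixel corner cannot
    be a single simple polygon and is returned as multiple parts.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    comp, n = ndimage.label(mask, structure=FOUR_CONNECTED)
    out: list[Polygon] = []
    for obj_idx, sl in enumerate(ndimage.find_objects(comp), start=1):
        sub = comp[sl] == obj_idx
        subgrid = SceneGrid(
            width=sub.shape[1],
            height=sub.shape[0],
            pixel_size=grid.pixel_size,
            origin=grid.corner_xy(sl[0].start, sl[1].start),
            crs_id=grid.crs_id,
        )
        merged = unary_union(_runs_to_boxes(sub, subgrid))
        if merged.geom_type == "Polygon":
            out.append(merged)
        else:
            out.extend(g for g in merged.geoms if g.geom_type == "Polygon")
    return out


def polygonize_labels(labels: np.ndarray, grid: SceneGrid) -> ParcelSet:
    """Vectorize a label grid: one polygon per 4-connected component per label."""
    labels = np.asarray(labels)
    if labels.shape != grid.shape:
        raise ValueError("label grid shape does not match grid")
    polys: list[Polygon] = []
    values: list[int] = []
    multi = False
    for value in np.unique(labels):
        if value == 0:
            continue
        parts = mask_to_polygons(labels == value, grid)
        if len(parts) != 1:
            multi = True
        polys.extend(parts)
        values.extend([int(value)] * len(parts))
    # keep the source label as the id when the mapping is one-to-one
    ids = np.arange(1, len(polys) + 1) if multi else np.asarray(values, dtype=np.int64)
    return ParcelSet(polys, ids, grid.crs_id)
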