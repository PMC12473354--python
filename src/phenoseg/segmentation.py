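"""Tiled mask proposal on recoloured composites, NMS merging and filtering.

The composite is processed in overlapping 512 px tiles; a pluggable backend
proposes masks per tile (any callable ``backend(window_rgb, cfg) -> MaskSet``
can be used — e.g. an adapter around a zero-shot segmenter).  The built-in
backend quantizes the three colour channels into equal-width bins and emits
the 4-connected components of identical bin triples, which is deterministic
and needs no model weights.  Per-tile masks are merged with greedy IoU-based
non-maximum suppression, polygonized, and filtered by minimum area and by
best-IoU preselection against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from shapely import STRtree

from phenoseg.geo_io import (
    FOUR_CONNECTED,
    ParcelSet,
    SceneGrid,
    mask_to_polygons,
)
from phenoseg.recolouring import RecolouredComposite

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BackendConfig:
    """Mask-generation parameter surface (mirrors the zero-shot segmenter's)."""

    points_per_side: int = 32
    pred_iou_thresh: float = 0.75
    stability_score_thresh: float = 0.80
    crop_n_layers: int = 2
    crop_overlap_ratio: float = 0.35
    crop_n_points_downscale_factor: int = 1
    tile_size: int = 512
    # built-in quantization backend knobs
    n_bins: int = 12
    min_region_px: int = 4

    def __post_init__(self) -> None:
        for name in ("pred_iou_thresh", "stability_score_thresh", "crop_overlap_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")


@dataclass
class Mask:
    """Binary mask in scene pixel coordinates with a proposal score."""

    pixels: np.ndarray          # bool (h, w) within bbox
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    score: float = 1.0

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def to_scene(self, shape: tuple[int, int]) -> np.ndarray:
        full = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        full[r0:r1, c0:c1] = self.pixels
        return full


@dataclass
class MaskSet:
    masks: list[Mask] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.masks)


Window = tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
Backend = Callable[[np.ndarray, BackendConfig], MaskSet]


def tile_grid(grid: SceneGrid, tile_size: int = 512, overlap_ratio: float = 0.35) -> list[Window]:
    """Half-open pixel windows covering the scene with the requested overlap.

    Adjacent windows overlap by round(tile_size * overlap_ratio) pixels;
    scene-edge windows are clipped, not padded.
    """
    overlap = int(round(tile_size * overlap_ratio))
    stride = max(tile_size - overlap, 1)

    def starts(extent: int) -> list[int]:
        if extent <= tile_size:
            return [0]
        s = list(range(0, extent - tile_size, stride))
        s.append(extent - tile_size)
        return sorted(set(s))

    windows = []
    for r0 in starts(grid.height):
        for c0 in starts(grid.width):
            windows.append((r0, c0, min(r0 + tile_size, grid.height), min(c0 + tile_size, grid.width)))
    return windows


def quantize_region_backend(window_rgb: np.ndarray, cfg: BackendConfig) -> MaskSet:
    """Deterministic built-in backend: colour quantization + components.

    Each channel is quantized into ``cfg.n_bins`` equal-width bins over
    [0, 1]; 4-connected components of identical bin triples with at least
    ``cfg.min_region_px`` pixels become masks with score 1.0.  Pure-black
    pixels (nodata rendering) propose nothing.
    """
    rgb = np.asarray(window_rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("backend expects an (H, W, 3) window")
    nb = cfg.n_bins
    bins = np.minimum((np.clip(rgb, 0.0, 1.0) * nb).astype(np.int32), nb - 1)
    combined = (bins[..., 0] * nb + bins[..., 1]) * nb + bins[..., 2] + 1
    combined[np.all(rgb == 0.0, axis=-1)] = 0  # nodata
    out = MaskSet()
    for value in np.unique(combined):
        if value == 0:
            continue
        comp, n = ndimage.label(combined == value, structure=FOUR_CONNECTED)
        for idx, sl in enumerate(ndimage.find_objects(comp), start=1):
            sub = comp[sl] == idx
            if sub.sum() < cfg.min_region_px:
                continue
            out.masks.append(
                Mask(
                    pixels=sub,
                    bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
                    score=1.0,
                )
            )
    return out


def propose_masks(
    backend: Backend,
    composite: RecolouredComposite,
    window: Window,
    cfg: BackendConfig,
) -> MaskSet:
    """Run a backend on one window, returning masks in scene coordinates.

    A backend failure skips the window with a logged warning instead of
    aborting the scene.
    """
    r0, c0, r1, c1 = window
    if not (0 <= r0 < r1 <= composite.grid.height and 0 <= c0 < c1 <= composite.grid.width):
        raise ValueError(f"window {window} outside scene")
    try:
        local = backend(composite.rgb[r0:r1, c0:c1], cfg)
    except Exception as exc:  # noqa: BLE001 - backend contract: skip + warn
        logger.warning("backend failed on window %s: %s", window, exc)
        return MaskSet()
    shifted = MaskSet()
    for m in local.masks:
        lr0, lc0, lr1, lc1 = m.bbox
        shifted.masks.append(
            Mask(pixels=m.pixels, bbox=(lr0 + r0, lc0 + c0, lr1 + r0, lc1 + c0), score=m.score)
        )
    return shifted


def _bbox_iou_possible(a: Mask, b: Mask) -> bool:
    return not (
        a.bbox[2] <= b.bbox[0] or b.bbox[2] <= a.bbox[0]
        or a.bbox[3] <= b.bbox[1] or b.bbox[3] <= a.bbox[1]
    )


def mask_iou(a: Mask, b: Mask) -> float:
    """IoU of two masks via their bbox intersection window."""
    if not _bbox_iou_possible(a, b):
        return 0.0
    r0 = min(a.bbox[0], b.bbox[0])
    c0 = min(a.bbox[1], b.bbox[1])
    r1 = max(a.bbox[2], b.bbox[2])
    c1 = max(a.bbox[3], b.bbox[3])
    fa = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    fb = np.zeros_like(fa)
    fa[a.bbox[0] - r0:a.bbox[2] - r0, a.bbox[1] - c0:a.bbox[3] - c0] = a.pixels
    fb[b.bbox[0] - r0:b.bbox[2] - r0, b.bbox[1] - c0:b.bbox[3] - c0] = b.pixels
    inter = np.logical_and(fa, fb).sum()
    union = np.logical_or(fa, fb).sum()
    return float(inter) / float(union) if union else 0.0


def merge_masks(masksets: Sequence[MaskSet], nms_iou: float = 0.70) -> MaskSet:
    """Greedy NMS across tiles: keep by descending score, drop IoU > nms_iou.

    Ties are broken by larger pixel area, then lower mask index, so merging
    is fully deterministic.  Surviving masks are unmodified.
    """
    pool: list[Mask] = [m for ms in masksets for m in ms.masks]
    order = sorted(range(len(pool)), key=lambda i: (-pool[i].score, -pool[i].area_px, i))
    kept: list[Mask] = []
    for i in order:
        cand = pool[i]
        if any(mask_iou(cand, k) > nms_iou for k in kept):
            continue
        kept.append(cand)
    return MaskSet(kept)


def masks_to_parcels(maskset: MaskSet, grid: SceneGrid) -> ParcelSet:
    """Polygonize surviving masks; one ParcelSet entry per mask polygon part."""
    polys = []
    for m in maskset.masks:
        r0, c0, _, _ = m.bbox
        subgrid = SceneGrid(
            width=m.pixels.shape[1], height=m.pixels.shape[0],
            pixel_size=grid.pixel_size, origin=grid.corner_xy(r0, c0),
            crs_id=grid.crs_id,
        )
        polys.extend(mask_to_polygons(m.pixels, subgrid))
    return ParcelSet(polys, np.arange(1, len(polys) + 1), grid.crs_id)


def filter_min_area(parcels: ParcelSet, min_area: float = 30.0) -> ParcelSet:
    """Drop polygons with area strictly less than ``min_area`` m^2."""
    keep = [i for i, p in enumerate(parcels.polygons) if p.area >= min_area]
    return parcels.subset(keep)


def preselect_by_iou(preds: ParcelSet, gt: ParcelSet, thresh: float = 0.50) -> ParcelSet:
    """Keep predictions whose best IoU against any ground-truth parcel is > thresh."""
    if len(gt) == 0:
        logger.warning("empty ground truth: preselection drops every prediction")
        return preds.subset([])
    tree = STRtree(gt.polygons)
    keep = []
    for i, pred in enumerate(preds.polygons):
        best = 0.0
        for j in tree.query(pred):
            g = gt.polygons[int(j)]
            inter = pred.intersection(g).area
            if inter == 0:
                continue
            union = pred.area + g.area - inter
            best = max(best, inter / union)
        if best > thresh:
            keep.append(i)
    return preds.subset(keep)


def segment_composite(
    composite: RecolouredComposite,
    backend: Backend | None = None,
    cfg: BackendConfig | None = None,
    nms_iou: float = 0.70,
) -> ParcelSet:
    """Full proposal path: tile, propose, NMS-merge, polygonize."""
    cfg = cfg or BackendConfig()
    backend = backend or quantize_region_backend
    windows = tile_grid(composite.grid, cfg.tile_size, cfg.crop_overlap_ratio)
    per_tile = [propose_masks(backend, composite, w, cfg) for w in windows]
    merged = merge_masks(per_tile, nms_iou=nms_iou)
    return masks_to_parcels(merged, composite.grid)
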