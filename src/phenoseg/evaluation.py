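"""Object-wise and pixel-wise delineation accuracy metrics.

Matching is ground-truth anchored and one-to-one: iterating over ground
truth polygons in input order, the unused prediction with the highest IoU is
taken and registered as a match iff IoU >= 0.50.  TP/FP/FN counts feed

    Precision = TP/(TP+FP),  Recall = TP/(TP+FN),  F1 = 2PR/(P+R),
    IoU = TP/(TP+FP+FN).

Object metrics are stratified by ground-truth parcel area (< 5000 m^2,
5000-20000 m^2, > 20000 m^2).  Fragmentation is the number of predictions
associated (by largest intersection) with a stratum's ground-truth parcels
per ground-truth parcel.  Per-prediction over-/under-classification errors

    OC = 1 - |S∩O|/|O|,  UC = 1 - |S∩O|/|S|,  TC = sqrt((OC^2+UC^2)/2),

with O the ground-truth parcel of largest intersection, are aggregated to
global errors by prediction-area weights.  Seam analysis compares pixel
metrics inside a buffered zone around interior tile boundaries against the
rest of the scene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely import STRtree
from shapely.geometry import Polygon

from phenoseg.geo_io import ParcelSet, SceneGrid

logger = logging.getLogger(__name__)

#: default area strata bounds in m^2: [0, 5000), [5000, 20000], (20000, inf)
STRATA_BOUNDS = (5000.0, 20000.0)
STRATA_NAMES = ("small", "medium", "large")


@dataclass
class MatchResult:
    """One-to-one ground-truth/prediction pairing."""

    pairs: list[tuple[int, int, float]]  # (gt_id, pred_id, iou)
    unmatched_gt_ids: list[int]
    unmatched_pred_ids: list[int]

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fn(self) -> int:
        return len(self.unmatched_gt_ids)

    @property
    def fp(self) -> int:
        return len(self.unmatched_pred_ids)


@dataclass
class MetricsReport:
    precision: float
    recall: float
    f1: float
    miou: float | None = None
    stratum: str = "all"
    mode: str = "object"
    defined: bool = True


@dataclass
class ClassErrorReport:
    goc: float
    guc: float
    gtc: float
    oc: np.ndarray
    uc: np.ndarray
    tc: np.ndarray
    weights: np.ndarray
    n_excluded: int = 0
    defined: bool = True


@dataclass
class SeamReport:
    seam: MetricsReport
    interior: MetricsReport
    deltas: dict = field(default_factory=dict)
    defined: bool = True


# ---------------------------------------------------------------------------
# Geometry metrics
# ---------------------------------------------------------------------------

def pair_iou(a: Polygon, b: Polygon) -> float:
    """Vector IoU = area(a∩b)/area(a∪b); 0 when both are empty."""
    inter = a.intersection(b).area
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def greedy_match(gt: ParcelSet, preds: ParcelSet, thresh: float = 0.50) -> MatchResult:
    """Sequential ground-truth anchored matching.

    For each ground-truth parcel in input order, bbox-intersecting unused
    predictions are queried from a spatial index; the unused candidate with
    the highest IoU is selected and registered iff IoU >= thresh.
    """
    used = np.zeros(len(preds), dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    unmatched_gt: list[int] = []
    tree = STRtree(preds.polygons) if len(preds) else None
    for gi, gpoly in enumerate(gt.polygons):
        best_iou, best_j = 0.0, -1
        if tree is not None:
            for j in sorted(int(v) for v in tree.query(gpoly)):
                if used[j]:
                    continue
                iou = pair_iou(gpoly, preds.polygons[j])
                if iou > best_iou:
                    best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= thresh:
            used[best_j] = True
            pairs.append((int(gt.ids[gi]), int(preds.ids[best_j]), best_iou))
        else:
            unmatched_gt.append(int(gt.ids[gi]))
    unmatched_pred = [int(preds.ids[j]) for j in range(len(preds)) if not used[j]]
    return MatchResult(pairs, unmatched_gt, unmatched_pred)


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from counts; undefined denominators give 0."""
    p = tp / (tp + fp) if tp + fp > 0 else 0.0
    r = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def f1_from_pr(p: float, r: float) -> float:
    """F1 = 2PR/(P+R); 0 when P = R = 0."""
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def iou_from_pr(p: float, r: float) -> float:
    """IoU = PR/(P+R-PR), the TP/(TP+FP+FN) identity in P, R form."""
    denom = p + r - p * r
    return p * r / denom if denom > 0 else 0.0


def object_metrics(match: MatchResult, stratum: str = "all") -> MetricsReport:
    """Object-wise precision/recall/F1 and mean IoU over matched pairs."""
    p, r, f1 = prf(match.tp, match.fp, match.fn)
    miou = float(np.mean([iou for *_, iou in match.pairs])) if match.pairs else None
    return MetricsReport(p, r, f1, miou, stratum=stratum, mode="object")


def pixel_metrics(gt_mask: np.ndarray, pred_mask: np.ndarray) -> MetricsReport:
    """Pixel-wise metrics on binary masks; TN is not counted."""
    gt_mask = np.asarray(gt_mask, dtype=bool)
    pred_mask = np.asarray(pred_mask, dtype=bool)
    if gt_mask.shape != pred_mask.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.logical_and(gt_mask, pred_mask).sum())
    fp = int(np.logical_and(~gt_mask, pred_mask).sum())
    fn = int(np.logical_and(gt_mask, ~pred_mask).sum())
    p, r, f1 = prf(tp, fp, fn)
    iou = tp / (tp + fp + fn) if tp + fp + fn > 0 else 0.0
    defined = (tp + fp + fn) > 0
    return MetricsReport(p, r, f1, iou, mode="pixel", defined=defined)


# ---------------------------------------------------------------------------
# Stratification, fragmentation, classification errors
# ---------------------------------------------------------------------------

def stratify_by_area(
    gt: ParcelSet, bounds: tuple[float, float] = STRATA_BOUNDS
) -> dict[str, ParcelSet]:
    """Split parcels into [0, lo), [lo, hi], (hi, inf) area strata."""
    lo, hi = bounds
    areas = gt.areas
    idx = {
        "small": np.flatnonzero(areas < lo),
        "medium": np.flatnonzero((areas >= lo) & (areas <= hi)),
        "large": np.flatnonzero(areas > hi),
    }
    return {name: gt.subset(list(ix)) for name, ix in idx.items()}


def associate_predictions(preds: ParcelSet, gt: ParcelSet) -> np.ndarray:
    """Index into gt of the largest-intersection parcel per prediction (-1 if none)."""
    assoc = np.full(len(preds), -1, dtype=int)
    if len(gt) == 0:
        return assoc
    tree = STRtree(gt.polygons)
    for i, pred in enumerate(preds.polygons):
        best_area, best_j = 0.0, -1
        for j in sorted(int(v) for v in tree.query(pred)):
            inter = pred.intersection(gt.polygons[j]).area
            if inter > best_area:
                best_area, best_j = inter, j
        assoc[i] = best_j
    return assoc


def fragmentation_ratio(
    gt_stratum: ParcelSet, preds: ParcelSet, assoc_gt: ParcelSet | None = None
) -> tuple[float | None, int, int]:
    """Fragmentation = associated predictions / ground-truth parcels in a stratum.

    Association assigns each retained prediction to the full ground-truth
    set's largest-intersection parcel (``assoc_gt``, defaulting to the
    stratum itself); the ratio counts predictions whose associated parcel
    lies in the stratum.  Returns (ratio or None, n_gt, n_associated).
    """
    n_gt = len(gt_stratum)
    if n_gt == 0:
        logger.warning("fragmentation undefined: empty stratum")
        return None, 0, 0
    base = assoc_gt if assoc_gt is not None else gt_stratum
    assoc = associate_predictions(preds, base)
    stratum_ids = set(int(i) for i in gt_stratum.ids)
    n_assoc = sum(1 for j in assoc if j >= 0 and int(base.ids[j]) in stratum_ids)
    return n_assoc / n_gt, n_gt, n_assoc


def oc_uc_tc(S: Polygon, gts: ParcelSet) -> tuple[float, float, float] | None:
    """Per-prediction over-, under- and total classification error.

    O is the ground-truth parcel with the largest intersection with S;
    OC = 1 - |S∩O|/|O|, UC = 1 - |S∩O|/|S|, TC = sqrt((OC^2+UC^2)/2).
    Returns None when S intersects no ground truth.
    """
    best_area, best = 0.0, None
    for g in gts.polygons:
        inter = S.intersection(g).area
        if inter > best_area:
            best_area, best = inter, g
    if best is None:
        return None
    oc = 1.0 - best_area / best.area
    uc = 1.0 - best_area / S.area
    tc = float(np.sqrt((oc**2 + uc**2) / 2.0))
    return oc, uc, tc


def global_errors(preds: ParcelSet, gts: ParcelSet) -> ClassErrorReport:
    """Area-weighted global OC/UC/TC across predictions.

    Predictions intersecting no ground truth are excluded from the sums (and
    counted); weights w_i = area(S_i)/sum(area(S_k)) over included
    predictions.
    """
    ocs, ucs, tcs, areas = [], [], [], []
    n_excluded = 0
    for poly in preds.polygons:
        res = oc_uc_tc(poly, gts)
        if res is None:
            n_excluded += 1
            continue
        ocs.append(res[0])
        ucs.append(res[1])
        tcs.append(res[2])
        areas.append(poly.area)
    if n_excluded:
        logger.info("%d predictions intersect no ground truth; excluded", n_excluded)
    if not areas:
        return ClassErrorReport(
            np.nan, np.nan, np.nan, np.array([]), np.array([]), np.array([]),
            np.array([]), n_excluded, defined=False,
        )
    w = np.asarray(areas) / np.sum(areas)
    oc = np.asarray(ocs)
    uc = np.asarray(ucs)
    tc = np.asarray(tcs)
    return ClassErrorReport(
        goc=float(w @ oc), guc=float(w @ uc), gtc=float(w @ tc),
        oc=oc, uc=uc, tc=tc, weights=w, n_excluded=n_excluded,
    )


def parcel_scores(
    gt: ParcelSet, preds: ParcelSet, match: MatchResult | None = None,
    thresh: float = 0.50,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ground-truth-parcel IoU and F1 score vectors (0 when unmatched).

    The IoU is the matched pair's vector IoU; the F1 score is the pairwise
    F1 of the matched pair computed from intersection and areas (for two
    regions, pixel precision |S∩O|/|S| and recall |S∩O|/|O| reduce to the
    area ratios, so F1 = 2|S∩O|/(|S|+|O|), the Dice coefficient).
    Zero-filling unmatched parcels keeps the repeated-measures design
    balanced.
    """
    if match is None:
        match = greedy_match(gt, preds, thresh=thresh)
    pred_by_id = {int(pid): poly for pid, poly in zip(preds.ids, preds.polygons)}
    pair_by_gt = {g: (p, iou) for g, p, iou in match.pairs}
    ious = np.zeros(len(gt))
    f1s = np.zeros(len(gt))
    for i, gid in enumerate(gt.ids):
        hit = pair_by_gt.get(int(gid))
        if hit is None:
            continue
        pred_id, iou = hit
        ious[i] = iou
        g = gt.polygons[i]
        s = pred_by_id[pred_id]
        inter = g.intersection(s).area
        denom = g.area + s.area
        f1s[i] = 2.0 * inter / denom if denom > 0 else 0.0
    return ious, f1s


# ---------------------------------------------------------------------------
# Seam analysis
# ---------------------------------------------------------------------------

def seam_zone_mask(
    grid: SceneGrid, windows: list[tuple[int, int, int, int]], buffer_px: int = 16
) -> np.ndarray | None:
    """Pixels within ``buffer_px`` of any interior tile boundary line.

    Boundary lines are window edges that do not coincide with the scene
    border; distance is Euclidean from pixel to the nearest boundary-line
    pixel.  Returns None for a single-tile scene (no seams).
    """
    lines = np.zeros(grid.shape, dtype=bool)
    any_interior = False
    for r0, c0, r1, c1 in windows:
        if r0 > 0:
            lines[r0, c0:c1] = True
            any_interior = True
        if r1 < grid.height:
            lines[r1 - 1, c0:c1] = True
            any_interior = True
        if c0 > 0:
            lines[r0:r1, c0] = True
            any_interior = True
        if c1 < grid.width:
            lines[r0:r1, c1 - 1] = True
            any_interior = True
    if not any_interior:
        return None
    dist = ndimage.distance_transform_edt(~lines)
    return dist <= buffer_px


def seam_analysis(
    gt_mask: np.ndarray,
    pred_mask: np.ndarray,
    windows: list[tuple[int, int, int, int]],
    grid: SceneGrid,
    buffer_px: int = 16,
) -> SeamReport:
    """Pixel metrics computed separately in seam and interior zones."""
    zone = seam_zone_mask(grid, windows, buffer_px)
    if zone is None:
        logger.warning("single-tile scene: seam analysis undefined")
        empty = MetricsReport(0, 0, 0, 0, mode="pixel", defined=False)
        return SeamReport(empty, empty, {}, defined=False)
    gt_mask = np.asarray(gt_mask, dtype=bool)
    pred_mask = np.asarray(pred_mask, dtype=bool)
    seam = pixel_metrics(gt_mask & zone, pred_mask & zone)
    interior = pixel_metrics(gt_mask & ~zone, pred_mask & ~zone)
    seam.stratum = interior.stratum = "all"
    deltas = {
        "iou": (interior.miou or 0.0) - (seam.miou or 0.0),
        "precision": interior.precision - seam.precision,
        "recall": interior.recall - seam.recall,
        "f1": interior.f1 - seam.f1,
    }
    return SeamReport(seam, interior, deltas)
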