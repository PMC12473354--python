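"""End-to-end orchestration: fit, recolour, segment and evaluate variants.

A *variant* is a (colour space, time encoding) combination; running all six
on one scene yields the parcel-level score matrix the repeated-measures
statistics need.  This module is the library surface behind the CLI and is
equally usable programmatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from phenoseg import evaluation as ev
from phenoseg import stats_tests as st
from phenoseg.geo_io import NDVIStack, ParcelSet, rasterize_parcels
from phenoseg.harmonics import TimeEncoding, fit_stack
from phenoseg.recolouring import COLOUR_SPACES, render_composite
from phenoseg.segmentation import (
    BackendConfig,
    filter_min_area,
    preselect_by_iou,
    segment_composite,
    tile_grid,
)

logger = logging.getLogger(__name__)

ALL_VARIANTS = tuple(
    (space, enc) for enc in (TimeEncoding.ORDINAL_DAY, TimeEncoding.ANNUAL_RADIAN)
    for space in COLOUR_SPACES
)


def variant_name(space: str, encoding: TimeEncoding) -> str:
    suffix = "" if TimeEncoding(encoding) is TimeEncoding.ORDINAL_DAY else "—annual radians"
    return f"{space}{suffix}"


@dataclass
class VariantResult:
    """Predictions and metric families for one colour-space/encoding variant."""

    space: str
    encoding: TimeEncoding
    predictions: ParcelSet          # area-filtered + IoU-preselected
    match: ev.MatchResult
    object_overall: ev.MetricsReport
    object_by_stratum: dict[str, ev.MetricsReport]
    pixel: ev.MetricsReport
    fragmentation: dict[str, tuple[float | None, int, int]]
    class_errors: dict[str, ev.ClassErrorReport]
    seam: ev.SeamReport
    parcel_iou: np.ndarray
    parcel_f1: np.ndarray


def evaluate_predictions(
    preds: ParcelSet,
    gt: ParcelSet,
    grid,
    min_area: float = 30.0,
    preselect_iou: float | None = 0.50,
    match_iou: float = 0.50,
    strata_bounds: tuple[float, float] = ev.STRATA_BOUNDS,
    seam_buffer_px: int = 16,
    tile_size: int = 512,
    overlap_ratio: float = 0.35,
    space: str = "",
    encoding: TimeEncoding = TimeEncoding.ORDINAL_DAY,
) -> VariantResult:
    """Apply the filter/preselect/match/metrics protocol to one prediction set.

    ``preselect_iou=None`` skips the best-IoU preselection entirely.
    """
    preds = filter_min_area(preds, min_area)
    if preselect_iou is not None:
        preds = preselect_by_iou(preds, gt, preselect_iou)
    match = ev.greedy_match(gt, preds, thresh=match_iou)
    overall = ev.object_metrics(match)

    strata = ev.stratify_by_area(gt, strata_bounds)
    by_stratum: dict[str, ev.MetricsReport] = {}
    frag: dict[str, tuple[float | None, int, int]] = {}
    cls: dict[str, ev.ClassErrorReport] = {}
    assoc = ev.associate_predictions(preds, gt)
    pred_stratum_of_gt = {}
    areas = gt.areas
    lo, hi = strata_bounds
    for i, gid in enumerate(gt.ids):
        a = areas[i]
        pred_stratum_of_gt[int(gid)] = (
            "small" if a < lo else ("medium" if a <= hi else "large")
        )
    for name, sub in strata.items():
        sub_ids = set(int(i) for i in sub.ids)
        tp = sum(1 for g, _, _ in match.pairs if g in sub_ids)
        fn = len(sub) - tp
        # FPs per stratum: unmatched predictions associated to this stratum
        fp = 0
        for j, gt_idx in enumerate(assoc):
            if int(preds.ids[j]) in {p for _, p, _ in match.pairs}:
                continue
            if gt_idx >= 0 and pred_stratum_of_gt[int(gt.ids[gt_idx])] == name:
                fp += 1
        p, r, f1 = ev.prf(tp, fp, fn)
        pair_ious = [iou for g, _, iou in match.pairs if g in sub_ids]
        miou = float(np.mean(pair_ious)) if pair_ious else None
        by_stratum[name] = ev.MetricsReport(p, r, f1, miou, stratum=name, mode="object")

        n_assoc = sum(
            1 for gt_idx in assoc
            if gt_idx >= 0 and int(gt.ids[gt_idx]) in sub_ids
        )
        frag[name] = (n_assoc / len(sub) if len(sub) else None, len(sub), n_assoc)

        stratum_pred_idx = [
            j for j, gt_idx in enumerate(assoc)
            if gt_idx >= 0 and int(gt.ids[gt_idx]) in sub_ids
        ]
        cls[name] = ev.global_errors(preds.subset(stratum_pred_idx), sub)

    gt_mask = rasterize_parcels(gt, grid, binary=True) > 0
    pred_mask = rasterize_parcels(preds, grid, binary=True) > 0
    pixel = ev.pixel_metrics(gt_mask, pred_mask)

    windows = tile_grid(grid, tile_size, overlap_ratio)
    seam = ev.seam_analysis(gt_mask, pred_mask, windows, grid, seam_buffer_px)

    parcel_iou, parcel_f1 = ev.parcel_scores(gt, preds, match)
    return VariantResult(
        space=space, encoding=TimeEncoding(encoding), predictions=preds,
        match=match, object_overall=overall, object_by_stratum=by_stratum,
        pixel=pixel, fragmentation=frag, class_errors=cls, seam=seam,
        parcel_iou=parcel_iou, parcel_f1=parcel_f1,
    )


def run_variants(
    stack: NDVIStack,
    gt: ParcelSet,
    variants=ALL_VARIANTS,
    backend=None,
    cfg: BackendConfig | None = None,
    min_area: float = 30.0,
    preselect_iou: float = 0.50,
    match_iou: float = 0.50,
    seam_buffer_px: int = 16,
    nms_iou: float = 0.70,
) -> dict[str, VariantResult]:
    """Fit, recolour, segment and evaluate every requested variant."""
    cfg = cfg or BackendConfig()
    results: dict[str, VariantResult] = {}
    fits: dict[TimeEncoding, object] = {}
    for space, enc in variants:
        enc = TimeEncoding(enc)
        if enc not in fits:
            fits[enc] = fit_stack(stack, encoding=enc)
        composite = render_composite(fits[enc], space)
        preds = segment_composite(composite, backend=backend, cfg=cfg, nms_iou=nms_iou)
        name = variant_name(space, enc)
        logger.info("variant %s: %d raw predictions", name, len(preds))
        results[name] = evaluate_predictions(
            preds, gt, stack.grid,
            min_area=min_area, preselect_iou=preselect_iou, match_iou=match_iou,
            seam_buffer_px=seam_buffer_px, tile_size=cfg.tile_size,
            overlap_ratio=cfg.crop_overlap_ratio, space=space, encoding=enc,
        )
    return results


def stats_by_stratum(
    results: dict[str, VariantResult],
    gt: ParcelSet,
    strata_bounds: tuple[float, float] = ev.STRATA_BOUNDS,
) -> dict[str, dict]:
    """Friedman omnibus + pairwise Wilcoxon/Holm per size stratum.

    Scores are per-parcel IoU and F1 vectors aligned over variants; the
    analysis runs separately within each stratum, for each score kind.
    """
    names = list(results)
    areas = gt.areas
    lo, hi = strata_bounds
    masks = {
        "small": areas < lo,
        "medium": (areas >= lo) & (areas <= hi),
        "large": areas > hi,
    }
    out: dict[str, dict] = {}
    for stratum, mask in masks.items():
        entry: dict = {"n_parcels": int(mask.sum())}
        if mask.sum() < 2:
            entry["defined"] = False
            out[stratum] = entry
            continue
        for kind in ("iou", "f1"):
            attr = "parcel_iou" if kind == "iou" else "parcel_f1"
            X = np.column_stack([getattr(results[n], attr)[mask] for n in names])
            fr = st.friedman(X)
            entry[kind] = {
                "friedman_Q": fr.statistic,
                "friedman_p": fr.p_value,
                "pairwise": st.pairwise_tests(X, names),
            }
        entry["defined"] = True
        out[stratum] = entry
    return out


# ---------------------------------------------------------------------------
# Structured-text reports (one file per table family)
# ---------------------------------------------------------------------------

def _fmt(x, nd=3):
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return "undefined"
    return f"{x:.{nd}f}"


def format_reports(results: dict[str, VariantResult]) -> dict[str, str]:
    """Render the metric families as aligned TSV-style text tables."""
    out: dict[str, str] = {}
    lines = ["Colour\tPrecision\tRecall\tF1"]
    for name, r in results.items():
        o = r.object_overall
        lines.append(f"{name}\t{_fmt(o.precision)}\t{_fmt(o.recall)}\t{_fmt(o.f1)}")
    out["object_wise"] = "\n".join(lines) + "\n"

    for stratum in ev.STRATA_NAMES:
        lines = ["Colour\tPrecision\tRecall\tF1\tmIoU"]
        for name, r in results.items():
            m = r.object_by_stratum[stratum]
            lines.append(
                f"{name}\t{_fmt(m.precision)}\t{_fmt(m.recall)}\t{_fmt(m.f1)}\t{_fmt(m.miou)}"
            )
        out[f"object_wise_{stratum}"] = "\n".join(lines) + "\n"

    lines = ["Colour\tPrecision\tRecall\tF1\tIoU"]
    for name, r in results.items():
        m = r.pixel
        lines.append(
            f"{name}\t{_fmt(m.precision)}\t{_fmt(m.recall)}\t{_fmt(m.f1)}\t{_fmt(m.miou)}"
        )
    out["pixel_wise"] = "\n".join(lines) + "\n"

    lines = ["Colour\tdIoU\tdPrecision\tdRecall\tdF1"]
    for name, r in results.items():
        d = r.seam.deltas
        if r.seam.defined:
            lines.append(
                f"{name}\t{_fmt(d['iou'])}\t{_fmt(d['precision'])}"
                f"\t{_fmt(d['recall'])}\t{_fmt(d['f1'])}"
            )
        else:
            lines.append(f"{name}\tundefined\tundefined\tundefined\tundefined")
    out["seam"] = "\n".join(lines) + "\n"

    for stratum in ev.STRATA_NAMES:
        lines = ["Colour\tGT parcels\tPredicted polygons\tRatio"]
        for name, r in results.items():
            ratio, n_gt, n_assoc = r.fragmentation[stratum]
            lines.append(f"{name}\t{n_gt}\t{n_assoc}\t{_fmt(ratio, 2)}")
        out[f"fragmentation_{stratum}"] = "\n".join(lines) + "\n"

    for stratum in ev.STRATA_NAMES:
        lines = ["Colour\tGOC\tGUC\tGTC"]
        for name, r in results.items():
            c = r.class_errors[stratum]
            if c.defined:
                lines.append(f"{name}\t{_fmt(c.goc)}\t{_fmt(c.guc)}\t{_fmt(c.gtc)}")
            else:
                lines.append(f"{name}\tundefined\tundefined\tundefined")
        out[f"class_errors_{stratum}"] = "\n".join(lines) + "\n"
    return out


def format_stats_report(stats: dict[str, dict]) -> str:
    lines = ["# Friedman omnibus per stratum", "Stratum\tScore\tN\tQ\tp"]
    for stratum, entry in stats.items():
        if not entry.get("defined"):
            lines.append(f"{stratum}\t-\t{entry['n_parcels']}\tundefined\tundefined")
            continue
        for kind in ("iou", "f1"):
            e = entry[kind]
            lines.append(
                f"{stratum}\t{kind}\t{entry['n_parcels']}"
                f"\t{e['friedman_Q']:.3f}\t{e['friedman_p']:.3e}"
            )
    lines.append("")
    lines.append("# Pairwise Wilcoxon signed-rank (Holm-adjusted)")
    lines.append("Stratum\tScore\tA\tB\tMedianDiff\tCIlow\tCIhigh\tpHolm")
    for stratum, entry in stats.items():
        if not entry.get("defined"):
            continue
        for kind in ("iou", "f1"):
            for row in entry[kind]["pairwise"]:
                lines.append(
                    f"{stratum}\t{kind}\t{row['a']}\t{row['b']}"
                    f"\t{row['median_diff']:+.4f}\t{row['ci_low']:+.4f}"
                    f"\t{row['ci_high']:+.4f}\t{row['p_holm']:.3e}"
                )
    return "\n".join(lines) + "\n"
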