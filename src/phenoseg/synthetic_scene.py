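"""Seeded synthetic parcel mosaics with per-parcel seasonal NDVI dynamics.

The generator emulates the scene statistics of a fragmented agricultural
landscape observed by a ~3 m cubesat constellation: a rectangular extent is
recursively guillotine-split into elongated strip parcels (median ~0.6 ha,
most below 1 ha), each parcel gets a phenology (seasonal peak day, NDVI
amplitude, mean NDVI, small linear trend), and a multitemporal NDVI stack is
rendered from

    y(t) = b + m*t + mean_offset + amp * cos(tau(t) - tau*) + eps,

with tau the annual angle of the acquisition day and eps i.i.d. Gaussian
noise, clipped to [-1, 1].  Non-field classes break the mosaic up the way
real scenes do: forest (high mean, low amplitude), water and urban (low,
flat).  Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon, box

from phenoseg.geo_io import NDVIStack, ParcelSet, SceneGrid, rasterize_parcels, repair_polygon
from phenoseg.harmonics import DAYS_PER_YEAR, to_annual_radians

#: class mix by area fraction
CLASS_MIX = {"field": 0.80, "forest": 0.10, "water": 0.05, "urban": 0.05}


@dataclass
class PhenologyParams:
    """True seasonal parameters of one parcel."""

    peak_doy: float
    amplitude: float
    mean_ndvi: float
    trend_slope: float = 0.0
    class_tag: str = "field"

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not -1.0 <= self.mean_ndvi <= 1.0:
            raise ValueError("mean_ndvi must be in [-1, 1]")

    @property
    def peak_tau(self) -> float:
        """Annual angle of the seasonal peak."""
        return float(to_annual_radians(self.peak_doy))


@dataclass
class SyntheticScene:
    """A rendered scene: NDVI stack, field ground truth, and true parameters."""

    stack: NDVIStack
    truth: ParcelSet           # field-class parcels only
    all_parcels: ParcelSet     # every parcel incl. non-field classes
    params: dict[int, PhenologyParams]  # by parcel id
    seed: int


# ---------------------------------------------------------------------------
# Parcel mosaic
# ---------------------------------------------------------------------------

def generate_parcels(
    extent: tuple[float, float] = (5000.0, 5000.0),
    min_area: float = 200.0,
    split_stop: float = 12000.0,
    stop_prob: float = 0.85,
    early_stop_prob: float = 0.03,
    cut_range: tuple[float, float] = (0.30, 0.70),
    axis_bias: float = 0.65,
    seed: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
    crs_id: str = "EPSG:32633",
) -> ParcelSet:
    """Recursive guillotine partition of a rectangle into strip parcels.

    Cells larger than ``split_stop`` m^2 are split (except for a small
    ``early_stop_prob`` chance that leaves an occasional large field); once
    below ``split_stop`` a cell stops with probability ``stop_prob`` per
    decision.  Cuts go across the longer side with probability ``axis_bias``
    at a position uniform in ``cut_range``; a cut producing a child below
    ``min_area`` is rejected.  Parcels tile the extent exactly.
    """
    w, h = extent
    if w * h < min_area:
        raise ValueError("extent smaller than min_area: infeasible")
    if split_stop < min_area:
        raise ValueError("split_stop below min_area: infeasible")
    rng = np.random.default_rng(seed)
    ox, oy = origin
    # rectangles as (x0, y0, x1, y1) with y decreasing southwards from oy
    done: list[tuple[float, float, float, float]] = []
    todo = [(ox, oy - h, ox + w, oy)]
    while todo:
        x0, y0, x1, y1 = todo.pop()
        area = (x1 - x0) * (y1 - y0)
        if area <= split_stop and rng.random() < stop_prob:
            done.append((x0, y0, x1, y1))
            continue
        if area > split_stop and rng.random() < early_stop_prob:
            done.append((x0, y0, x1, y1))
            continue
        dx, dy = x1 - x0, y1 - y0
        long_is_x = dx >= dy
        cut_x = long_is_x if rng.random() < axis_bias else not long_is_x
        frac = rng.uniform(*cut_range)
        if cut_x:
            cut = x0 + frac * dx
            children = [(x0, y0, cut, y1), (cut, y0, x1, y1)]
        else:
            cut = y0 + frac * dy
            children = [(x0, y0, x1, cut), (x0, cut, x1, y1)]
        if any((cx1 - cx0) * (cy1 - cy0) < min_area for cx0, cy0, cx1, cy1 in children):
            done.append((x0, y0, x1, y1))
            continue
        todo.extend(children)
    polys = [box(*r) for r in done]
    return ParcelSet(polys, np.arange(1, len(polys) + 1), crs_id)


def sample_dates(
    n: int = 22,
    start_ordinal: float = 738535.0,   # mid-January of the first season
    span_days: float = 567.0,
    jitter_days: float = 4.0,
    seed: int = 0,
) -> np.ndarray:
    """Strictly increasing ordinal acquisition days.

    Mean spacing is ``span_days / (n - 1)`` (defaults give ~27 days over two
    crop cycles); each interior date is jittered by a uniform offset.
    """
    if n < 2:
        raise ValueError("need at least 2 dates")
    rng = np.random.default_rng(seed)
    base = start_ordinal + np.linspace(0.0, span_days, n)
    if jitter_days > 0:
        jit = rng.uniform(-jitter_days, jitter_days, size=n)
        jit[0] = jit[-1] = 0.0
        base = base + jit
        base = np.maximum.accumulate(base + np.arange(n) * 1e-6)  # keep strict order
    return np.round(base, 6)


# ---------------------------------------------------------------------------
# Phenology assignment
# ---------------------------------------------------------------------------

def _easy_field_params(hue_bin: int, mean_bin: int, n_bins: int) -> PhenologyParams:
    # Discrete menu centred on the quantization bins of the built-in backend:
    # hue, saturation and value land mid-bin, so an "easy" scene tests the
    # pipeline rather than bin-edge dithering.
    phi = (hue_bin + 0.5) / n_bins * 2.0 * math.pi - math.pi   # target fitted phase
    peak_doy = (phi % (2.0 * math.pi)) / (2.0 * math.pi) * DAYS_PER_YEAR
    mean = (mean_bin + 0.5) / n_bins * 2.0 - 1.0
    return PhenologyParams(float(peak_doy), 0.35, float(mean), 0.0, "field")


#: easy-menu mean-NDVI bins (value-channel bins of a 12-bin backend)
_EASY_MEAN_BINS = (4, 6, 7)


def _field_params(rng: np.random.Generator, easy: bool, n_bins: int) -> PhenologyParams:
    if easy:
        hue_bin = int(rng.integers(0, n_bins))
        mean_bin = int(rng.choice(_EASY_MEAN_BINS))
        return _easy_field_params(hue_bin, mean_bin, n_bins)
    peak_doy = rng.uniform(90.0, 300.0)
    amp = rng.uniform(0.20, 0.45)
    # keep mean +/- amp inside [-1, 1] so the rendered series never clips
    mean = rng.uniform(0.30, min(0.70, 1.0 - amp - 0.02))
    trend = rng.normal(0.0, 2e-5)
    return PhenologyParams(float(peak_doy), float(amp), float(mean), float(trend), "field")


def assign_phenology(
    parcels: ParcelSet,
    seed: int = 0,
    class_mix: dict[str, float] | None = None,
    easy: bool = False,
    n_bins: int = 12,
) -> dict[int, PhenologyParams]:
    """Assign a class and phenology to every parcel.

    Non-field classes are drawn until their area quota (``class_mix``, by
    area) is filled; the rest are fields.  The ``easy`` preset draws field
    parameters from a discrete, well-separated mid-bin menu and additionally
    guarantees that *touching* parcels never share a (hue, mean) combo, so
    phases are well separated exactly where separation matters.
    """
    mix = class_mix or CLASS_MIX
    rng = np.random.default_rng(seed)
    areas = parcels.areas
    total = areas.sum()
    order = rng.permutation(len(parcels))
    quotas = {c: mix.get(c, 0.0) * total for c in ("forest", "water", "urban")}
    classes = ["field"] * len(parcels)
    filled = {c: 0.0 for c in quotas}
    for i in order:
        for c in ("forest", "water", "urban"):
            if filled[c] + areas[i] <= quotas[c]:
                classes[i] = c
                filled[c] += areas[i]
                break
    easy_combo: dict[int, tuple[int, int]] = {}
    if easy:
        # greedy colouring of the parcel adjacency graph over the menu
        from shapely import STRtree

        tree = STRtree(parcels.polygons)
        combos = [(h, m) for h in range(n_bins) for m in _EASY_MEAN_BINS]
        for i in range(len(parcels)):
            if classes[i] != "field":
                continue
            taken = set()
            for j in tree.query(parcels.polygons[i]):
                j = int(j)
                if j != i and j in easy_combo and \
                        parcels.polygons[i].intersects(parcels.polygons[j]):
                    taken.add(easy_combo[j])
            free = [c for c in combos if c not in taken]
            easy_combo[i] = free[int(rng.integers(0, len(free)))] if free \
                else combos[int(rng.integers(0, len(combos)))]
    params: dict[int, PhenologyParams] = {}
    for i, pid in enumerate(parcels.ids):
        c = classes[i]
        if c == "field":
            if easy:
                h, mb = easy_combo[i]
                params[int(pid)] = _easy_field_params(h, mb, n_bins)
            else:
                params[int(pid)] = _field_params(rng, easy, n_bins)
        elif c == "forest":
            params[int(pid)] = PhenologyParams(
                rng.uniform(140, 200), rng.uniform(0.03, 0.08),
                rng.uniform(0.70, 0.85), 0.0, "forest")
        elif c == "water":
            params[int(pid)] = PhenologyParams(
                0.0, rng.uniform(0.0, 0.02), rng.uniform(-0.30, -0.05), 0.0, "water")
        else:
            params[int(pid)] = PhenologyParams(
                0.0, rng.uniform(0.0, 0.03), rng.uniform(0.05, 0.20), 0.0, "urban")
    return params


# ---------------------------------------------------------------------------
# Stack rendering
# ---------------------------------------------------------------------------

def render_stack(
    parcels: ParcelSet,
    params: dict[int, PhenologyParams],
    dates: np.ndarray,
    grid: SceneGrid,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> SyntheticScene:
    """Render the multitemporal NDVI stack of a parcel mosaic.

    Every pixel takes its parcel's series ``mean + trend*(t - t_mid) +
    amp*cos(tau(t) - tau*)`` plus independent Gaussian noise, clipped to
    [-1, 1].  Pixels outside every parcel (possible after rasterization of
    sliver geometry) are invalid.  ``truth`` contains field parcels only.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    missing = [int(i) for i in parcels.ids if int(i) not in params]
    if missing:
        raise ValueError(f"parcels without phenology params: {missing[:5]}")
    dates = np.asarray(dates, dtype=float)
    rng = np.random.default_rng(seed)
    labels = rasterize_parcels(parcels, grid)
    tau = to_annual_radians(np.mod(dates, DAYS_PER_YEAR))
    t_mid = dates.mean()
    T = dates.size
    values = np.zeros((T, grid.height, grid.width), dtype=np.float32)
    valid = labels > 0
    for pid, p in params.items():
        mask = labels == pid
        if not mask.any():
            continue
        series = (
            p.mean_ndvi
            + p.trend_slope * (dates - t_mid)
            + p.amplitude * np.cos(tau - p.peak_tau)
        )
        values[:, mask] = series[:, None].astype(np.float32)
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape).astype(np.float32)
    values = np.clip(values, -1.0, 1.0)
    values[:, ~valid] = np.nan
    stack = NDVIStack(
        values=values,
        dates=dates,
        valid_mask=np.broadcast_to(valid, values.shape).copy(),
        grid=grid,
    )
    field_idx = [i for i, pid in enumerate(parcels.ids) if params[int(pid)].class_tag == "field"]
    truth = parcels.subset(field_idx)
    return SyntheticScene(stack=stack, truth=truth, all_parcels=parcels,
                          params=params, seed=seed)


def perturb_truth(truth: ParcelSet, boundary_sd: float, seed: int = 0) -> ParcelSet:
    """Synthetic second annotation: jitter polygon vertices, repair validity."""
    if boundary_sd < 0:
        raise ValueError("boundary_sd must be >= 0")
    if boundary_sd == 0:
        return ParcelSet(list(truth.polygons), truth.ids.copy(), truth.crs_id)
    rng = np.random.default_rng(seed)
    out = []
    for poly in truth.polygons:
        coords = np.asarray(poly.exterior.coords)
        jit = rng.normal(0.0, boundary_sd, size=(coords.shape[0] - 1, 2))
        new = coords.copy()
        new[:-1] += jit
        new[-1] = new[0]
        interiors = []
        for ring in poly.interiors:
            rc = np.asarray(ring.coords)
            rj = rng.normal(0.0, boundary_sd, size=(rc.shape[0] - 1, 2))
            rn = rc.copy()
            rn[:-1] += rj
            rn[-1] = rn[0]
            interiors.append(rn)
        cand = repair_polygon(Polygon(new, interiors))
        out.append(cand if not cand.is_empty else poly)
    return ParcelSet(out, truth.ids.copy(), truth.crs_id)


def simulate_scene(
    extent: tuple[float, float] = (5000.0, 5000.0),
    pixel_size: float = 3.0,
    n_dates: int = 22,
    noise_sd: float = 0.02,
    seed: int = 0,
    easy: bool = False,
    origin: tuple[float, float] = (500000.0, 5120000.0),
    **parcel_kwargs,
) -> SyntheticScene:
    """One-call scene synthesis: parcels + phenology + dates + stack."""
    parcels = generate_parcels(extent=extent, seed=seed, origin=origin, **parcel_kwargs)
    params = assign_phenology(parcels, seed=seed + 1, easy=easy)
    dates = sample_dates(n=n_dates, seed=seed + 2)
    grid = SceneGrid(
        width=int(round(extent[0] / pixel_size)),
        height=int(round(extent[1] / pixel_size)),
        pixel_size=pixel_size,
        origin=origin,
        crs_id=parcels.crs_id,
    )
    return render_stack(parcels, params, dates, grid, noise_sd=noise_sd, seed=seed + 3)
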