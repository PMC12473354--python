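"""Map harmonic parameters (amplitude, phase, NDVI mean) to sRGB composites.

Channel normalisation uses AOI-wide scalers so contrast is consistent across
tiles:

    A' = A / max(A)          in [0, 1]
    V' = (NDVI_mean + 1) / 2 in [0, 1]
    phi' = Phi + pi          in [0, 2*pi)

Three cylindrical colour spaces are rendered.  HSV: hue = phi'/2pi encodes
phenological timing, saturation = A' the seasonal range, value = V' the mean
greenness.  HWB: hue as in HSV, whiteness = V' (greener parcels desaturate
towards white), blackness = 1 - A' (strongly seasonal fields appear bright).
LCH(ab): lightness L = 100*V', hue angle h = phi' and chroma C proportional
to A', with a single global chroma scale found by geometric search so that
at most a small fraction of pixels falls outside the sRGB gamut; the scale
touches only C, so hue and lightness relationships are preserved exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from phenoseg.geo_io import SceneGrid, write_geotiff
from phenoseg.harmonics import HarmonicFitGrid, TimeEncoding

COLOUR_SPACES = ("HSV", "HWB", "LCH")

#: reference chroma for the LCH rendering (before global gamut scaling)
CHROMA_REF = 100.0
#: geometric chroma search: shrink factor and tolerated out-of-gamut fraction
CHROMA_SHRINK = 0.95
CLIP_TOLERANCE = 1e-3

# sRGB primaries and D65 white point (IEC 61966-2-1 chromaticities).  The
# XYZ<->RGB matrix is derived from them rather than hard-coding rounded
# constants so that the neutral axis (a = b = 0) maps to exact grey.
_PRIMARIES = np.array([[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]])
_WHITE_XY = (0.3127, 0.3290)


def _derive_srgb_matrices() -> tuple[np.ndarray, np.ndarray]:
    xy = _PRIMARIES
    xyz = np.column_stack([xy[:, 0], xy[:, 1], 1.0 - xy.sum(axis=1)]).T  # 3x3, rows X,Y,Z
    xw, yw = _WHITE_XY
    white = np.array([xw / yw, 1.0, (1.0 - xw - yw) / yw])
    scale = np.linalg.solve(xyz, white)
    rgb_to_xyz = xyz * scale
    return rgb_to_xyz, np.linalg.inv(rgb_to_xyz)


_RGB_TO_XYZ, _XYZ_TO_RGB = _derive_srgb_matrices()
_D65 = tuple(_RGB_TO_XYZ @ np.ones(3))  # == white point; M @ (1,1,1)


@dataclass
class NormalizedChannels:
    """AOI-normalised channels: A' and V' in [0, 1], phi' in [0, 2*pi)."""

    A_prime: np.ndarray
    V_prime: np.ndarray
    phi_prime: np.ndarray


@dataclass
class RecolouredComposite:
    """3-band sRGB float composite in [0, 1] with scaling metadata."""

    rgb: np.ndarray
    space: str
    encoding: TimeEncoding
    grid: SceneGrid
    scale_meta: dict = field(default_factory=dict)

    def write(self, path: str | Path, sidecar: bool = True) -> None:
        write_geotiff(path, self.rgb.astype(np.float32), self.grid)
        if sidecar:
            meta = dict(self.scale_meta, space=self.space, encoding=self.encoding.value)
            Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


def normalize_channels(
    A: np.ndarray, Phi: np.ndarray, ndvi_mean: np.ndarray, maxA: float
) -> NormalizedChannels:
    """Normalise amplitude, phase and mean with AOI-wide scalers."""
    if not np.isfinite(maxA) or maxA <= 0:
        raise ValueError("maxA must be positive (degenerate scene)")
    A_prime = np.clip(np.asarray(A, dtype=float) / maxA, 0.0, 1.0)
    V_prime = np.clip((np.asarray(ndvi_mean, dtype=float) + 1.0) / 2.0, 0.0, 1.0)
    phi_prime = np.mod(np.asarray(Phi, dtype=float) + np.pi, 2.0 * np.pi)
    return NormalizedChannels(A_prime, V_prime, phi_prime)


# ---------------------------------------------------------------------------
# Colour space conversions (vectorised)
# ---------------------------------------------------------------------------

def hsv_to_rgb(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Standard HSV -> RGB sextant conversion; h, s, v in [0, 1]."""
    h = np.asarray(h, dtype=float)
    s = np.asarray(s, dtype=float)
    v = np.asarray(v, dtype=float)
    h6 = np.mod(h, 1.0) * 6.0
    i = np.floor(h6).astype(int) % 6
    f = h6 - np.floor(h6)
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.stack([r, g, b], axis=-1)


def hwb_to_rgb(h: np.ndarray, w: np.ndarray, bl: np.ndarray) -> np.ndarray:
    """Standard HWB -> RGB rule (CSS Color 4 semantics).

    If W + B >= 1 the colour is achromatic grey W/(W+B); otherwise it is the
    HSV colour with V = 1 - B and S = 1 - W/(1 - B).
    """
    h = np.asarray(h, dtype=float)
    w = np.asarray(w, dtype=float)
    bl = np.asarray(bl, dtype=float)
    tot = w + bl
    achrom = tot >= 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        grey = np.where(tot > 0, w / tot, 0.0)
        v = 1.0 - bl
        s = np.where(v > 0, 1.0 - w / v, 0.0)
    rgb = hsv_to_rgb(h, np.clip(s, 0.0, 1.0), np.clip(v, 0.0, 1.0))
    return np.where(achrom[..., None], grey[..., None], rgb)


def _finv(t: np.ndarray) -> np.ndarray:
    # inverse of the CIE L*a*b* companding function
    delta = 6.0 / 29.0
    return np.where(t > delta, t**3, 3.0 * delta**2 * (t - 4.0 / 29.0))


def lab_to_xyz(L: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    x = _D65[0] * _finv(fx)
    y = _D65[1] * _finv(fy)
    z = _D65[2] * _finv(fz)
    return np.stack([x, y, z], axis=-1)


def _srgb_compand(linear: np.ndarray) -> np.ndarray:
    # IEC 61966-2-1 forward companding
    a = 0.055
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        (1 + a) * np.sign(linear) * np.abs(linear) ** (1 / 2.4) - a,
    )


def lch_to_rgb(L: np.ndarray, C: np.ndarray, h_rad: np.ndarray) -> np.ndarray:
    """LCH(ab) -> LAB -> XYZ(D65) -> sRGB, without clipping.

    Out-of-gamut colours come back with components outside [0, 1]; the
    caller decides how to handle them (global chroma scaling + final clip).
    """
    a = C * np.cos(h_rad)
    b = C * np.sin(h_rad)
    xyz = lab_to_xyz(np.asarray(L, dtype=float), a, b)
    linear = xyz @ _XYZ_TO_RGB.T
    return _srgb_compand(linear)


def _out_of_gamut_fraction(rgb: np.ndarray, valid: np.ndarray) -> float:
    bad = np.any((rgb < -1e-9) | (rgb > 1.0 + 1e-9), axis=-1)
    n = int(valid.sum())
    return float(bad[valid].sum()) / n if n else 0.0


# ---------------------------------------------------------------------------
# Per-space mappings
# ---------------------------------------------------------------------------

def map_hsv(ch: NormalizedChannels) -> np.ndarray:
    """H = phi'/2pi, S = A', V = V'."""
    return hsv_to_rgb(ch.phi_prime / (2.0 * np.pi), ch.A_prime, ch.V_prime)


def map_hwb(ch: NormalizedChannels) -> np.ndarray:
    """H = phi'/2pi, W = V', B = 1 - A'."""
    return hwb_to_rgb(ch.phi_prime / (2.0 * np.pi), ch.V_prime, 1.0 - ch.A_prime)


def map_lch(
    ch: NormalizedChannels, valid: np.ndarray | None = None
) -> tuple[np.ndarray, dict]:
    """L = 100*V', h = phi', C = s*C_ref*A' with a single global scale s.

    s is the largest value in a geometric search (factor 0.95 from 1.0) such
    that the out-of-gamut pixel fraction is <= 0.1%; residual out-of-gamut
    values are clipped to [0, 1].  Scaling only C preserves hue and
    lightness relationships exactly.
    """
    if valid is None:
        valid = np.isfinite(ch.A_prime) & np.isfinite(ch.V_prime)
    L = 100.0 * ch.V_prime
    s = 1.0
    rgb = lch_to_rgb(L, s * CHROMA_REF * ch.A_prime, ch.phi_prime)
    while _out_of_gamut_fraction(rgb, valid) > CLIP_TOLERANCE and s > 1e-4:
        s *= CHROMA_SHRINK
        rgb = lch_to_rgb(L, s * CHROMA_REF * ch.A_prime, ch.phi_prime)
    clip_frac = _out_of_gamut_fraction(rgb, valid)
    return np.clip(rgb, 0.0, 1.0), {"chroma_scale": s, "clip_fraction": clip_frac}


# ---------------------------------------------------------------------------
# Composite assembly
# ---------------------------------------------------------------------------

def render_composite(
    fit: HarmonicFitGrid, space: str, maxA: float | None = None
) -> RecolouredComposite:
    """Normalise a fitted grid and render one colour-space composite.

    Unfittable pixels are rendered black; ``maxA`` defaults to the maximum
    amplitude over fittable pixels of the scene (the AOI-wide scaler).
    """
    space = space.upper()
    if space not in COLOUR_SPACES:
        raise ValueError(f"unknown colour space {space!r}; expected one of {COLOUR_SPACES}")
    valid = fit.fittable & np.isfinite(fit.amplitude)
    if not valid.any():
        raise ValueError("all pixels unfittable; nothing to render")
    if maxA is None:
        maxA = float(np.nanmax(fit.amplitude[valid]))
    A = np.where(valid, fit.amplitude, 0.0)
    Phi = np.where(valid, fit.phase, 0.0)
    mean = np.where(valid, fit.ndvi_mean, -1.0)
    ch = normalize_channels(A, Phi, mean, maxA)
    meta: dict = {"maxA": maxA}
    if space == "HSV":
        rgb = map_hsv(ch)
    elif space == "HWB":
        rgb = map_hwb(ch)
    else:
        rgb, lch_meta = map_lch(ch, valid)
        meta.update(lch_meta)
    rgb = np.where(valid[..., None], rgb, 0.0)
    return RecolouredComposite(
        rgb=np.clip(rgb, 0.0, 1.0), space=space, encoding=fit.encoding,
        grid=fit.grid, scale_meta=meta,
    )
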