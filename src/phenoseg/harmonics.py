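"""Per-pixel linear detrending and single-harmonic fitting of NDVI series.

Each pixel's NDVI series y(t) is first regressed on time with ordinary least
squares, y_lin = m*t + b, and the residuals r(t) = y - y_lin are modelled as
a single sinusoid with bias,

    r(x) = a0 + a1*cos(x) + b1*sin(x),

where x is either the annual angular time tau = 2*pi*DOY/365.25 (calendar-
interpretable phase) or the raw ordinal day t (implicit 2*pi-day period,
giving a relative phase offset).  Amplitude and phase follow as
A = sqrt(a1^2 + b1^2) and Phi = atan2(b1, a1) in (-pi, pi].

The model is linear in (a0, a1, b1); the iterative Levenberg-Marquardt route
is available per series and agrees with the closed form to numerical
precision, so full-stack fitting uses the vectorised normal equations.
"""

from __future__ import annotations

import enum
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from phenoseg.geo_io import NDVIStack, SceneGrid

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

#: minimum valid observations for a pixel to be fittable
MIN_VALID_OBS = 8


class TimeEncoding(str, enum.Enum):
    """Time axis encoding for the harmonic fit."""

    ORDINAL_DAY = "ordinal_day"
    ANNUAL_RADIAN = "annual_radian"


def to_annual_radians(doy: np.ndarray | float) -> np.ndarray | float:
    """Map day of year to the annual angle tau = 2*pi*DOY/365.25 in [0, 2*pi)."""
    tau = 2.0 * np.pi * (np.asarray(doy, dtype=float) / DAYS_PER_YEAR)
    tau = np.mod(tau, 2.0 * np.pi)
    if np.isscalar(doy):
        return float(tau)
    return tau


def encode_times(times: np.ndarray, encoding: TimeEncoding) -> np.ndarray:
    """Angular argument passed to sin/cos under the chosen encoding."""
    times = np.asarray(times, dtype=float)
    if TimeEncoding(encoding) is TimeEncoding.ANNUAL_RADIAN:
        return to_annual_radians(np.mod(times, DAYS_PER_YEAR))
    return times  # raw ordinal days straight into sin/cos


def detrend(series: np.ndarray, times: np.ndarray) -> tuple[float, float, np.ndarray]:
    """OLS linear fit y = m*t + b; returns (m, b, residuals)."""
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("detrending needs at least 2 distinct times")
    X = np.column_stack([t, np.ones_like(t)])
    (m, b), *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(m), float(b), y - (m * t + b)


def _design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), np.cos(x), np.sin(x)])


def fit_harmonic(
    residuals: np.ndarray,
    times: np.ndarray,
    encoding: TimeEncoding = TimeEncoding.ANNUAL_RADIAN,
    method: str = "lm",
) -> tuple[float, float, float]:
    """Least-squares fit of r = a0 + a1*cos(x) + b1*sin(x).

    ``method='lm'`` uses the unweighted, unbounded Levenberg-Marquardt solver
    with standard tolerances; on non-convergence (or ``method='linear'``) the
    linear-in-parameters normal equations are used — the two agree because
    the model is linear.
    """
    r = np.asarray(residuals, dtype=float)
    x = encode_times(times, encoding)
    if r.size < 4:
        raise ValueError("harmonic fit needs at least 4 observations")
    X = _design(x)
    if method == "lm":
        res = least_squares(lambda p: X @ p - r, x0=np.zeros(3), method="lm")
        if res.success:
            return tuple(float(v) for v in res.x)
        logger.warning("LM solver did not converge; falling back to linear solve")
    coef, *_ = np.linalg.lstsq(X, r, rcond=None)
    return tuple(float(v) for v in coef)


def derive_params(a1: float, b1: float) -> tuple[float, float]:
    """Amplitude and phase from harmonic coefficients.

    A = sqrt(a1^2 + b1^2); Phi = atan2(b1, a1) in (-pi, pi].  The degenerate
    a1 = b1 = 0 case yields A = 0 with the convention Phi = 0.
    """
    A = float(np.hypot(a1, b1))
    if A == 0.0:
        return 0.0, 0.0
    return A, float(np.arctan2(b1, a1))


@dataclass
class HarmonicFitGrid:
    """Per-pixel harmonic fit parameters over a scene.

    All arrays are (H, W); pixels failing the minimum-observation threshold
    are flagged unfittable and carry NaN.
    """

    m: np.ndarray
    b: np.ndarray
    a0: np.ndarray
    a1: np.ndarray
    b1: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    ndvi_mean: np.ndarray
    n_valid: np.ndarray
    fittable: np.ndarray
    encoding: TimeEncoding
    grid: SceneGrid

    _ARRAYS = ("m", "b", "a0", "a1", "b1", "amplitude", "phase",
               "ndvi_mean", "n_valid", "fittable")

    def save(self, path: str | Path, content_hash: str) -> None:
        np.savez_compressed(
            path,
            content_hash=np.array(content_hash),
            encoding=np.array(self.encoding.value),
            **{k: getattr(self, k) for k in self._ARRAYS},
        )

    @classmethod
    def load(cls, path: str | Path, grid: SceneGrid) -> tuple["HarmonicFitGrid", str]:
        with np.load(path) as z:
            arrays = {k: z[k] for k in cls._ARRAYS}
            enc = TimeEncoding(str(z["encoding"]))
            content_hash = str(z["content_hash"])
        fit = cls(**arrays, encoding=enc, grid=grid)
        return fit, content_hash


def _stack_hash(stack: NDVIStack, encoding: TimeEncoding, min_valid_obs: int) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(stack.dates).tobytes())
    h.update(repr(stack.grid).encode())
    h.update(encoding.value.encode())
    h.update(str(min_valid_obs).encode())
    h.update(np.ascontiguousarray(stack.values).tobytes())
    h.update(np.ascontiguousarray(stack.valid_mask).tobytes())
    return h.hexdigest()


def fit_stack(
    stack: NDVIStack,
    encoding: TimeEncoding = TimeEncoding.ANNUAL_RADIAN,
    min_valid_obs: int = MIN_VALID_OBS,
    cache_path: str | Path | None = None,
) -> HarmonicFitGrid:
    """Detrend + harmonic fit for every pixel of an NDVI stack.

    Pixels with fewer than ``min_valid_obs`` valid observations are flagged
    unfittable.  ``ndvi_mean`` is the empirical arithmetic mean of the
    pixel's valid NDVI values.  When ``cache_path`` is given, coefficients
    are cached and reloaded bit-identically; a cache whose content hash does
    not match the stack is ignored with a warning and the fit is redone.
    """
    encoding = TimeEncoding(encoding)
    content_hash = _stack_hash(stack, encoding, min_valid_obs)
    if cache_path is not None and Path(cache_path).exists():
        try:
            fit, cached_hash = HarmonicFitGrid.load(cache_path, stack.grid)
            if cached_hash == content_hash and fit.m.shape == stack.grid.shape:
                return fit
            logger.warning("harmonic cache %s stale or mismatched; refitting", cache_path)
        except Exception:  # noqa: BLE001 - any unreadable cache is refit
            logger.warning("harmonic cache %s unreadable; refitting", cache_path)

    T, H, W = stack.values.shape
    t = stack.dates
    x = encode_times(t, encoding)
    y = stack.values.reshape(T, -1).astype(np.float64)
    w = (stack.valid_mask.reshape(T, -1) & np.isfinite(y)).astype(np.float64)
    y = np.where(w > 0, y, 0.0)
    n_valid = w.sum(axis=0)
    fittable = n_valid >= min_valid_obs

    # --- batched OLS detrend: columns [t, 1] ---
    Xl = np.column_stack([t, np.ones_like(t)])           # (T, 2)
    # normal matrices per pixel: sum_j w_j x_j x_j^T  -> (N, 2, 2)
    G = np.einsum("tj,tk,tn->njk", Xl, Xl, w)
    rhs = np.einsum("tj,tn->nj", Xl, w * y)
    coef_lin = np.full((y.shape[1], 2), np.nan)
    if fittable.any():
        coef_lin[fittable] = np.linalg.solve(G[fittable], rhs[fittable, :, None])[..., 0]
    m_flat, b_flat = coef_lin[:, 0], coef_lin[:, 1]
    resid = y - (np.outer(t, m_flat) + b_flat[None, :])
    resid = np.where(w > 0, resid, 0.0)

    # --- batched harmonic fit: columns [1, cos x, sin x] ---
    Xh = _design(x)                                       # (T, 3)
    Gh = np.einsum("tj,tk,tn->njk", Xh, Xh, w)
    rh = np.einsum("tj,tn->nj", Xh, w * resid)
    coef_h = np.full((y.shape[1], 3), np.nan)
    if fittable.any():
        coef_h[fittable] = np.linalg.solve(Gh[fittable], rh[fittable, :, None])[..., 0]
    a0_flat, a1_flat, b1_flat = coef_h[:, 0], coef_h[:, 1], coef_h[:, 2]

    amp = np.hypot(a1_flat, b1_flat)
    phase = np.arctan2(b1_flat, a1_flat)
    phase = np.where(amp == 0, 0.0, phase)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_valid > 0, (w * y).sum(axis=0) / n_valid, np.nan)

    def grid_of(a: np.ndarray) -> np.ndarray:
        out = np.where(fittable, a, np.nan)
        return out.reshape(H, W)

    fit = HarmonicFitGrid(
        m=grid_of(m_flat),
        b=grid_of(b_flat),
        a0=grid_of(a0_flat),
        a1=grid_of(a1_flat),
        b1=grid_of(b1_flat),
        amplitude=grid_of(amp),
        phase=grid_of(phase),
        ndvi_mean=grid_of(mean),
        n_valid=n_valid.reshape(H, W),
        fittable=fittable.reshape(H, W),
        encoding=encoding,
        grid=stack.grid,
    )
    if cache_path is not None:
        fit.save(cache_path, content_hash)
    return fit
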