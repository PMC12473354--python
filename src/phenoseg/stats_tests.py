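"""Repeated-measures nonparametric comparison of delineation variants.

Each ground-truth parcel is scored under every method variant (e.g. six
colour-space/time-encoding combinations), giving a parcels x methods score
matrix.  The Friedman test is the omnibus check that at least one variant
differs in rank distribution; significant results are followed by pairwise
Wilcoxon signed-rank tests with Holm correction, and Hodges-Lehmann median
differences with signed-rank confidence intervals describe effect sizes.

All routines are self-contained implementations (average-rank ties, tie
corrections, exact enumeration for small samples) and are cross-checked
against scipy in the test-suite rather than delegating to it, so the exact
branch behaviour is under this module's control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm, rankdata

logger = logging.getLogger(__name__)

#: sample-size ceiling for the exact Wilcoxon null distribution
EXACT_N_MAX = 25


@dataclass
class FriedmanResult:
    statistic: float
    p_value: float
    df: int
    n: int
    k: int


@dataclass
class WilcoxonResult:
    statistic: float      # W+ (sum of positive ranks)
    p_value: float
    n_effective: int
    method: str           # "exact" | "normal" | "degenerate"
    degenerate: bool = False


@dataclass
class MedianDiffCI:
    median_diff: float
    ci_low: float
    ci_high: float
    level: float
    reliable: bool = True


def friedman(scores: np.ndarray) -> FriedmanResult:
    """Friedman rank test over a (n parcels, k methods) score matrix.

    Within-row average ranks with the standard tie correction; the statistic
    is referred to a chi-square distribution with k-1 degrees of freedom.
    Constant rows across all methods yield Q = 0, p = 1.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ValueError("score matrix must be 2-D (parcels x methods)")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 parcels and 2 methods")
    ranks = rankdata(X, axis=1)
    Rj = ranks.sum(axis=0)
    # tie correction: per row, sum of (t^3 - t) over tie groups
    srt = np.sort(X, axis=1)
    if not np.any(srt[:, 1:] == srt[:, :-1]):
        tie_sum = 0.0  # continuous data: no within-row ties
    else:
        tie_sum = 0.0
        for row in X:
            _, counts = np.unique(row, return_counts=True)
            tie_sum += float(np.sum(counts.astype(float) ** 3 - counts))
    denom = n * k * (k**2 - 1)
    correction = 1.0 - tie_sum / denom
    if correction <= 0:
        # every row fully tied: no evidence of any difference
        return FriedmanResult(0.0, 1.0, k - 1, n, k)
    Q = (12.0 / (n * k * (k + 1)) * np.sum(Rj**2) - 3.0 * n * (k + 1)) / correction
    p = float(chi2.sf(Q, k - 1))
    return FriedmanResult(float(Q), p, k - 1, n, k)


def _signed_rank_null_pmf(ranks2: np.ndarray) -> np.ndarray:
    """Exact null distribution of 2*W+ by dynamic programming.

    ``ranks2`` are doubled ranks (integers even with average-rank ties);
    returns P(2*W+ = s) for s = 0..sum(ranks2).
    """
    total = int(ranks2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = pmf.copy()
        nxt[r:] += pmf[: total + 1 - r]
        pmf = nxt / 2.0
    return pmf


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original rule); absolute
    differences are ranked with average ties.  The p-value is exact (full
    enumeration over sign assignments, via DP) for effective n <= 25, and a
    normal approximation with tie and continuity correction otherwise.
    All differences zero is degenerate: p = 1 with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have the same length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", degenerate=True)
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        ranks2 = np.round(2 * ranks).astype(int)
        pmf = _signed_rank_null_pmf(ranks2)
        s = int(round(2 * w_pos))
        mean2 = ranks2.sum() / 2.0  # null mean of 2*W+
        # two-sided: sum probabilities of outcomes at least as extreme
        dev = abs(s - mean2)
        support = np.arange(pmf.size)
        p = float(pmf[np.abs(support - mean2) >= dev - 1e-9].sum())
        return WilcoxonResult(w_pos, min(p, 1.0), n, "exact")
    mean = n * (n + 1) / 4.0
    # tie-corrected variance of W+
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(w_pos, 1.0, n, "degenerate", degenerate=True)
    # continuity correction towards the mean
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return WilcoxonResult(w_pos, min(p, 1.0), n, "normal")


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-D vector of p-values")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def _walsh_averages(d: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(d.size)
    return np.sort((d[i] + d[j]) / 2.0)


def _signed_rank_critical(n: int, alpha: float) -> int:
    """Largest integer c with P(W+ <= c) <= alpha/2 under the null (no ties)."""
    ranks2 = 2 * np.arange(1, n + 1)
    pmf = _signed_rank_null_pmf(ranks2)
    # W+ support is integers 0..n(n+1)/2 at even positions of the 2W pmf
    cdf = np.cumsum(pmf[::2])
    c = int(np.searchsorted(cdf, alpha / 2.0, side="right")) - 1
    return max(c, -1)


def median_diff_ci(
    x: np.ndarray, y: np.ndarray, level: float = 0.95
) -> MedianDiffCI:
    """Hodges-Lehmann pseudo-median of paired differences with signed-rank CI.

    The point estimate is the median of the Walsh averages of d = x - y; the
    confidence interval takes the (c+1)-th smallest and largest Walsh
    averages, with c the signed-rank critical value at the requested level.
    For n < 6 the exact interval cannot reach 95% coverage; the result is
    flagged unreliable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have the same length")
    d = x - y
    n = d.size
    if n == 0:
        raise ValueError("empty input")
    walsh = _walsh_averages(d)
    hl = float(np.median(walsh))
    reliable = n >= 6
    if n <= 200:
        c = _signed_rank_critical(n, 1.0 - level)
    else:
        # normal approximation to the signed-rank quantile
        mean = n * (n + 1) / 4.0
        sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
        c = int(np.floor(mean + norm.ppf((1.0 - level) / 2.0) * sd - 0.5))
    if c < 0:
        lo, hi = float(walsh[0]), float(walsh[-1])
        reliable = False
    else:
        lo, hi = float(walsh[c]), float(walsh[-(c + 1)])
    return MedianDiffCI(hl, lo, hi, level, reliable)


def score_matrix(per_variant_scores: dict[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """Stack per-variant parcel score vectors into a (n, k) matrix.

    Vectors must be aligned on the same parcel order and length; unmatched
    parcels are expected to be zero-filled upstream so the design stays
    balanced.
    """
    names = list(per_variant_scores)
    lengths = {len(v) for v in per_variant_scores.values()}
    if len(lengths) != 1:
        raise ValueError("variant score vectors differ in length")
    X = np.column_stack([np.asarray(per_variant_scores[k], dtype=float) for k in names])
    return X, names


def pairwise_tests(
    X: np.ndarray, names: list[str], level: float = 0.95
) -> list[dict]:
    """All pairwise Wilcoxon tests with Holm correction and HL median CIs."""
    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    raw = []
    rows = []
    for i, j in pairs:
        res = wilcoxon_signed_rank(X[:, i], X[:, j])
        ci = median_diff_ci(X[:, i], X[:, j], level=level)
        raw.append(res.p_value)
        rows.append(
            {
                "a": names[i],
                "b": names[j],
                "median_diff": ci.median_diff,
                "ci_low": ci.ci_low,
                "ci_high": ci.ci_high,
                "p_raw": res.p_value,
                "degenerate": res.degenerate,
            }
        )
    adj = holm_adjust(np.array(raw))
    for row, p in zip(rows, adj):
        row["p_holm"] = float(p)
    return rows
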