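"""Nonparametric statistics shared by every pipeline stage.

ECDFs, two- and one-sided Kolmogorov–Smirnov tests, the Wilcoxon rank-sum
test, Benjamini–Hochberg adjustment and Pearson correlation.  The KS
p-values are asymptotic (Kolmogorov series for the two-sided test, the
exponential bound ``exp(-2 D+^2 nm/(n+m))`` for the one-sided test): the
gene-set sizes this pipeline handles are tens to thousands, where the
asymptotic forms are accurate and the one-sided bound is conservative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import special

__all__ = [
    "Ecdf",
    "ecdf",
    "ks_two_sided",
    "ks_one_sided",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "pearson_r",
]


@dataclass(frozen=True)
class Ecdf:
    """Right-continuous empirical CDF: F(x) = #{v <= x} / n."""

    support: np.ndarray  # sorted unique support points
    heights: np.ndarray  # F evaluated at each support point

    def __call__(self, x) -> np.ndarray | float:
        xs = np.asarray(x, dtype=float)
        idx = np.searchsorted(self.support, xs, side="right")
        out = np.where(idx == 0, 0.0, self.heights[np.minimum(idx, len(self.heights)) - 1])
        return float(out) if np.isscalar(x) else out


def ecdf(values) -> Ecdf:
    """Empirical CDF of a finite sample (at least one finite value)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("ecdf requires at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("ecdf requires finite values")
    support, counts = np.unique(v, return_counts=True)
    heights = np.cumsum(counts) / v.size
    return Ecdf(support=support, heights=heights)


def _check_sample(name: str, v: np.ndarray, min_size: int) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.size < min_size:
        raise ValueError(f"{name} needs at least {min_size} values, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


def _ecdf_diffs(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F_a and F_b evaluated at the pooled breakpoints."""
    points = np.concatenate([a, b])
    fa = np.searchsorted(np.sort(a), points, side="right") / a.size
    fb = np.searchsorted(np.sort(b), points, side="right") / b.size
    return fa, fb


def ks_two_sided(a, b) -> tuple[float, float]:
    """Two-sided KS test: D = sup|F_a - F_b|, asymptotic Kolmogorov p.

    The p-value uses the Kolmogorov survival function evaluated at
    ``sqrt(nm/(n+m)) * D``.
    """
    a = _check_sample("a", a, 2)
    b = _check_sample("b", b, 2)
    fa, fb = _ecdf_diffs(a, b)
    d = float(np.max(np.abs(fa - fb)))
    en = a.size * b.size / (a.size + b.size)
    p = float(special.kolmogorov(np.sqrt(en) * d))
    return d, float(np.clip(p, np.finfo(float).tiny, 1.0))


def ks_one_sided(a_set, b_background) -> tuple[float, float]:
    """One-sided KS right-shift statistic of a set against a background.

    D+ = sup_x (F_background(x) - F_set(x)); positive when the set is
    shifted towards larger values.  p = exp(-2 D+^2 nm/(n+m)), clipped to
    (0, 1].
    """
    a = _check_sample("set", a_set, 2)
    b = _check_sample("background", b_background, 2)
    fa, fb = _ecdf_diffs(a, b)
    d_plus = float(max(np.max(fb - fa), 0.0))
    en = a.size * b.size / (a.size + b.size)
    p = float(np.exp(-2.0 * d_plus * d_plus * en))
    return d_plus, float(np.clip(p, np.finfo(float).tiny, 1.0))


def _mann_whitney_pmf(n: int, m: int) -> np.ndarray:
    """PMF of U over 0..n*m under the null, by dynamic programming.

    Counts interleavings via N(i, j, u) = N(i-1, j, u-j) + N(i, j-1, u):
    the largest pooled value is either an x (contributing j to U) or a y.
    """
    umax = n * m
    # table[j][u] = N(i, j, u) for the current i
    table = np.zeros((m + 1, umax + 1), dtype=float)
    table[:, 0] = 1.0  # i = 0: U is 0 however many y's there are
    for _ in range(1, n + 1):
        new = np.zeros_like(table)
        new[0, 0] = 1.0  # j = 0: U is 0
        for j in range(1, m + 1):
            new[j, :] = new[j - 1, :]
            new[j, j:] += table[j, : umax + 1 - j]
        table = new
    counts = table[m]
    return counts / counts.sum()


def wilcoxon_rank_sum(
    x, y, alternative: Literal["two-sided", "less", "greater"] = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney) test.

    Returns ``(U, p)`` with U the Mann–Whitney count for ``x`` (number of
    (x, y) pairs with x > y, ties counted half).  Exact enumeration when
    the pooled size is at most 20 and there are no ties; otherwise the
    normal approximation with tie and continuity corrections.

    ``alternative="less"`` tests whether x tends to be smaller than y.
    """
    x = _check_sample("x", x, 1)
    y = _check_sample("y", y, 1)
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    # U via midranks
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size)
    sorted_vals = pooled[order]
    # midranks for ties
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    rank_sum_x = float(ranks[:n].sum())
    u = rank_sum_x - n * (n + 1) / 2.0  # #{x > y} with ties half

    if n + m <= 20 and not has_ties:
        pmf = _mann_whitney_pmf(n, m)
        ui = int(round(u))
        p_greater = float(pmf[ui:].sum())
        p_less = float(pmf[: ui + 1].sum())
        if alternative == "greater":
            p = p_greater
        elif alternative == "less":
            p = p_less
        else:
            p = min(1.0, 2.0 * min(p_greater, p_less))
        return u, p

    mu = n * m / 2.0
    # tie-corrected variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var = n * m / 12.0 * ((n + m + 1) - tie_term / ((n + m) * (n + m - 1)))
    if var <= 0:
        return u, 1.0
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (u - mu - 0.5) / sd
        p = special.ndtr(-z)
    elif alternative == "less":
        z = (u - mu + 0.5) / sd
        p = special.ndtr(z)
    else:
        z = (abs(u - mu) - 0.5) / sd
        p = 2.0 * special.ndtr(-z)
    return u, float(np.clip(p, np.finfo(float).tiny, 1.0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def pearson_r(x, y) -> float:
    """Sample Pearson correlation; both vectors must be non-constant."""
    x = _check_sample("x", x, 3)
    y = _check_sample("y", y, 3)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson_r undefined for constant input")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
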