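"""Shared statistical primitives.

The paired Wilcoxon signed-rank test is implemented here rather than taken
from scipy because the genome-wide scan needs (a) a guaranteed exact-null
branch for small effective n and (b) a vectorized many-tests variant
(:func:`pairscan.cnscan.paired_bin_scan`) that shares its conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "signed_rank_exact_tail",
    "rank_sum_test",
    "bh_adjust",
    "spearman",
]

#: largest effective n routed to the exact null distribution
EXACT_N_MAX = 25


@dataclass
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int  # nonzero differences entering the test
    method: str  # "exact", "normal", or "degenerate"
    degenerate: bool = False


def _signed_rank_counts(ranks: np.ndarray) -> np.ndarray:
    """Null distribution of W+ = sum of a random subset of integer ranks.

    ``counts[w]`` = number of sign assignments with W+ == w. Equivalent to
    enumerating all 2^n sign patterns; computed by polynomial convolution.
    """
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks:
        r = int(r)
        counts[r:] += counts[: counts.size - r].copy()
    return counts


def signed_rank_exact_tail(n: int, w: float, alternative: str) -> float:
    """Exact p-value for W+ == w with distinct ranks 1..n."""
    ranks = np.arange(1, n + 1)
    counts = _signed_rank_counts(ranks)
    denom = 2.0**n
    w_int = int(round(w))
    p_ge = counts[w_int:].sum() / denom
    p_le = counts[: w_int + 1].sum() / denom
    if alternative == "greater":
        return min(1.0, p_ge)
    if alternative == "less":
        return min(1.0, p_le)
    return min(1.0, 2.0 * min(p_ge, p_le))


def wilcoxon_signed_rank(
    x,
    y=None,
    alternative: str = "two_sided",
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test on ``x - y`` (or on ``x`` directly).

    Zero differences are dropped; tied absolute differences receive
    mid-ranks. The exact null distribution (full sign enumeration) is used
    when the effective n is <= 25 and there are no ties; otherwise a normal
    approximation with tie and continuity corrections. ``alternative`` is
    one of ``greater`` (x > y), ``less``, ``two_sided``.

    All differences zero is reported as p = 1 with a degenerate flag, not an
    exception: the data carry no evidence either way.
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        d = x - y
    else:
        d = x
    if d.size == 0:
        raise ValueError("empty input")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(np.nan, 1.0, 0, "degenerate", degenerate=True)

    absd = np.abs(d)
    ranks = sps.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n

    if n <= EXACT_N_MAX and not has_ties:
        p = signed_rank_exact_tail(n, w_plus, alternative)
        return WilcoxonResult(w_plus, p, n, "exact")

    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    if has_ties:
        _, t = np.unique(absd, return_counts=True)
        var -= (t**3 - t).sum() / 48.0
    sd = np.sqrt(var)
    if sd == 0.0:
        return WilcoxonResult(w_plus, 1.0, n, "degenerate", degenerate=True)
    if alternative == "greater":
        p = sps.norm.sf((w_plus - mu - 0.5) / sd)
    elif alternative == "less":
        p = sps.norm.cdf((w_plus - mu + 0.5) / sd)
    else:
        z = (w_plus - mu - np.sign(w_plus - mu) * 0.5) / sd
        p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(w_plus, float(np.clip(p, np.nextafter(0, 1), 1.0)), n, "normal")


@dataclass
class RankSumResult:
    statistic: float
    p_value: float
    median_x: float
    median_y: float
    direction: str  # "x_higher", "y_higher", "tied"


def rank_sum_test(x, y, alternative: str = "two-sided") -> RankSumResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact for small tie-free samples, tie-corrected normal approximation
    otherwise (scipy's ``method='auto'``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="auto")
    mx, my = float(np.median(x)), float(np.median(y))
    direction = "x_higher" if mx > my else ("y_higher" if my > mx else "tied")
    return RankSumResult(float(res.statistic), float(res.pvalue), mx, my, direction)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    NaN entries (untested hypotheses) are ignored and returned as NaN; the
    adjustment is computed over the remaining m valid p-values.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    valid = np.isfinite(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[valid] = qv
    return q


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 2:
        return np.nan, np.nan
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)
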