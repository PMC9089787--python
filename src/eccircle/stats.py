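"""Nonparametric group comparisons with explicit tie handling.

The test statistics are computed here from first principles (mid-ranks,
tie-corrected variances, an exact rank-sum null distribution built by
dynamic programming); only the reference distributions (chi-square, normal)
come from scipy.  Two-sided tests throughout, significance at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2, norm

__all__ = [
    "GroupTestResult",
    "PairwiseResult",
    "midranks",
    "kruskal_wallis",
    "dunn_posthoc",
    "wilcoxon_rank_sum",
]


@dataclass
class PairwiseResult:
    group_i: int
    group_j: int
    z: float
    p_value: float
    p_adjusted: float


@dataclass
class GroupTestResult:
    method: str
    statistic: Optional[float]
    p_value: float
    group_sizes: List[int]
    pairwise: List[PairwiseResult] = field(default_factory=list)
    note: str = ""


def midranks(values: Sequence[float]) -> np.ndarray:
    """Mid-ranks (1-based, ties averaged) of a sample."""
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _tie_term(pooled: np.ndarray) -> float:
    """Sum of (t^3 - t) over tie groups."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """Kruskal-Wallis H test on mid-ranks with tie correction.

    H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1), divided by
    1 - sum(t^3 - t)/(N^3 - N); p from chi-square with k-1 df.  If every
    pooled value is identical the statistic is undefined and p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = [len(g) for g in groups]
    if any(n < 1 for n in sizes):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = len(pooled)
    if n_total < 3:
        raise ValueError("need at least three values in total")
    ranks = midranks(pooled)

    h = 0.0
    start = 0
    for n in sizes:
        r_sum = ranks[start : start + n].sum()
        h += r_sum**2 / n
        start += n
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)

    correction = 1.0 - _tie_term(pooled) / (n_total**3 - n_total)
    if correction <= 0.0:  # all values identical
        return GroupTestResult(
            method="kruskal_wallis",
            statistic=None,
            p_value=1.0,
            group_sizes=sizes,
            note="statistic undefined: all pooled values identical",
        )
    h_c = h / correction
    p = float(chi2.sf(h_c, df=len(groups) - 1))
    return GroupTestResult(
        method="kruskal_wallis", statistic=h_c, p_value=p, group_sizes=sizes
    )


def _adjust(pvals: List[float], correction: str) -> List[float]:
    m = len(pvals)
    if correction == "none":
        return list(pvals)
    if correction == "bonferroni":
        return [min(1.0, p * m) for p in pvals]
    if correction == "holm":
        order = sorted(range(m), key=lambda i: pvals[i])
        adjusted = [0.0] * m
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, min(1.0, (m - rank) * pvals[i]))
            adjusted[i] = running
        return adjusted
    raise ValueError(f"unknown correction {correction!r}")


def dunn_posthoc(
    groups: Sequence[Sequence[float]], correction: str = "holm"
) -> List[PairwiseResult]:
    """Dunn's multiple-comparison test on the pooled mid-ranks.

    z_ij = (mean rank_i - mean rank_j) /
           sqrt[(N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)]
    with T = sum(t^3 - t); two-sided normal p, adjusted per ``correction``
    (Holm by default).
    """
    if len(groups) < 3:
        raise ValueError("Dunn's test needs >= 3 groups (use rank-sum for 2)")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = len(pooled)
    ranks = midranks(pooled)
    mean_ranks = []
    start = 0
    for n in sizes:
        mean_ranks.append(ranks[start : start + n].mean())
        start += n
    var_term = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (
        12.0 * (n_total - 1)
    )

    raw: List[Tuple[int, int, float, float]] = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = math.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2.0 * float(norm.sf(abs(z)))
            raw.append((i, j, z, min(1.0, p)))

    adjusted = _adjust([r[3] for r in raw], correction)
    return [
        PairwiseResult(group_i=i, group_j=j, z=z, p_value=p, p_adjusted=pa)
        for (i, j, z, p), pa in zip(raw, adjusted)
    ]


def _exact_u_cdf(n_x: int, n_y: int) -> np.ndarray:
    """Null pmf of the Mann-Whitney U statistic (no ties) by dynamic
    programming over the Gaussian-binomial recurrence."""
    max_u = n_x * n_y
    # ways[u] = number of arrangements with U == u
    ways = np.zeros(max_u + 1, dtype=float)
    ways[0] = 1.0
    # polynomial product_{i=1..n_x} (1 - q^{n_y + i}) / (1 - q^i)
    for i in range(1, n_x + 1):
        # multiply by 1/(1 - q^i): prefix sums with stride i
        for u in range(i, max_u + 1):
            ways[u] += ways[u - i]
        # multiply by (1 - q^{n_y + i})
        k = n_y + i
        for u in range(max_u, k - 1, -1):
            ways[u] -= ways[u - k]
    return ways / ways.sum()


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> GroupTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when min(n_x, n_y) <= 8 and there are no ties;
    otherwise a normal approximation with tie-corrected variance and a
    0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples need at least one value")
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = midranks(pooled)
    r_x = ranks[:n_x].sum()
    u_x = r_x - n_x * (n_x + 1) / 2.0

    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(n_x, n_y) <= 8 and not has_ties:
        pmf = _exact_u_cdf(n_x, n_y)
        u = int(round(u_x))
        p_low = pmf[: u + 1].sum()
        p_high = pmf[u:].sum()
        p = min(1.0, 2.0 * min(p_low, p_high))
        return GroupTestResult(
            method="wilcoxon_rank_sum_exact",
            statistic=u_x,
            p_value=float(p),
            group_sizes=[n_x, n_y],
        )

    n = n_x + n_y
    mu = n_x * n_y / 2.0
    var = n_x * n_y / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    if var <= 0:
        return GroupTestResult(
            method="wilcoxon_rank_sum_normal",
            statistic=u_x,
            p_value=1.0,
            group_sizes=[n_x, n_y],
            note="zero variance: all pooled values identical",
        )
    diff = u_x - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return GroupTestResult(
        method="wilcoxon_rank_sum_normal",
        statistic=u_x,
        p_value=p,
        group_sizes=[n_x, n_y],
    )
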