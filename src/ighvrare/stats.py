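"""Rank-sum and co-occurrence statistics used by the carrier analysis.

The one-sided Mann-Whitney (Wilcoxon rank-sum) test contrasts carrier
read-frequency distributions against non-carrier backgrounds; the exact
null distribution of U is computed by the classical counting recurrence
when samples are small and untied, and a normal approximation with
continuity and tie correction is used otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = ["RankTestResult", "mann_whitney_one_sided", "hypergeom_tail_p"]

EXACT_MAX_N = 10  # exact U distribution when min(n_x, n_y) <= this, no ties


@dataclass
class RankTestResult:
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    n_x: int
    n_y: int
    degenerate: bool = False


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of arrangements of n x-ranks among n+m with each U value.

    c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u): the largest observation is
    either an x (contributing m to U) or a y.
    """
    if n == 0 or m == 0:
        return (1,)
    a = _u_counts(n - 1, m)
    b = _u_counts(n, m - 1)
    out = [0] * (n * m + 1)
    for u, c in enumerate(a):
        out[u + m] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def mann_whitney_one_sided(x, y) -> RankTestResult:
    """One-sided Mann-Whitney U test, alternative: x stochastically > y.

    U counts pairs (x_i, y_j) with x_i > y_j (ties count 1/2).  The exact
    p-value P(U >= u_obs) is used when min(n) <= 10 and there are no ties;
    otherwise the normal approximation with continuity and tie correction.
    All-identical input is degenerate and reported as p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 1 or ny < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2)

    if np.ptp(pooled) == 0:
        return RankTestResult(u, 1.0, "exact", nx, ny, degenerate=True)

    has_ties = len(np.unique(pooled)) < nx + ny
    if min(nx, ny) <= EXACT_MAX_N and not has_ties:
        counts = _u_counts(nx, ny)
        tail = sum(counts[int(u):])
        p = tail / comb(nx + ny, nx)
        return RankTestResult(u, float(p), "exact", nx, ny)

    n = nx + ny
    _, tie_sizes = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_sizes ** 3 - tie_sizes).sum()) / ((n) * (n - 1)))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    mu = nx * ny / 2.0
    if sigma2 <= 0:
        return RankTestResult(u, 1.0, "normal_approx", nx, ny, degenerate=True)
    z = (u - mu - 0.5) / np.sqrt(sigma2)
    p = float(sps.norm.sf(z))
    return RankTestResult(u, min(max(p, np.nextafter(0, 1)), 1.0),
                          "normal_approx", nx, ny)


def hypergeom_tail_p(overlap: int, n_a: int, n_b: int, cohort_size: int) -> float:
    """One-sided hypergeometric tail P(X >= overlap) for carrier
    co-occurrence of two alleles in a cohort (Fisher exact, greater)."""
    if n_a == 0 or n_b == 0:
        return 1.0
    return float(sps.hypergeom.sf(overlap - 1, cohort_size, n_a, n_b))
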