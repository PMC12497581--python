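"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity from first principles, deliberately
avoiding the code path (and where practical the library calls) used by the
implementation under test.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def phi_bruteforce(u, v) -> float:
    """Pearson correlation of two binary vectors from the 2x2 contingency table."""
    u = np.asarray(u, dtype=int)
    v = np.asarray(v, dtype=int)
    n11 = int(((u == 1) & (v == 1)).sum())
    n10 = int(((u == 1) & (v == 0)).sum())
    n01 = int(((u == 0) & (v == 1)).sum())
    n00 = int(((u == 0) & (v == 0)).sum())
    num = n11 * n00 - n10 * n01
    den = math.sqrt((n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
    return num / den


def nb_quantile_bruteforce(mean: float, dispersion: float, q: float) -> int:
    """Smallest k with CDF(k) >= q by direct pmf-recurrence summation.

    NB in (mean, dispersion) form; ``dispersion=inf`` means Poisson.
    """
    if mean == 0.0:
        return 0
    if math.isinf(dispersion):
        pmf = math.exp(-mean)  # Poisson pmf(0)
        step = lambda k, pmf: pmf * mean / (k + 1)
    else:
        r = dispersion
        p = r / (r + mean)
        pmf = p**r
        step = lambda k, pmf: pmf * (k + r) / (k + 1) * (1.0 - p)
    cdf = pmf
    k = 0
    while cdf < q:
        pmf = step(k, pmf)
        k += 1
        cdf += pmf
    return k


def bh_stepup_bruteforce(pvalues) -> np.ndarray:
    """BH q-values by the defining step-up formula: q_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_upper_tail_exact(k: int, M: int, n: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(M, n, N), exact rational arithmetic."""
    total = Fraction(0)
    denom = math.comb(M, N)
    for x in range(k, min(n, N) + 1):
        total += Fraction(math.comb(n, x) * math.comb(M - n, N - x), denom)
    return total


def ranksum_exact_p(x, y) -> float:
    """Two-sided exact permutation p of the Wilcoxon rank-sum statistic."""
    x = list(x)
    y = list(y)
    pooled = x + y
    n = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}  # assumes no ties
    observed = sum(ranks[v] for v in x)
    mu = n * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        stat = sum(ranks[pooled[i]] for i in combo)
        total += 1
        if abs(stat - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total
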