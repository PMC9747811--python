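"""Independent brute-force oracles used to verify statistical primitives.

These are deliberately naive implementations — direct enumeration of the
definitions — and never call the code paths they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def ks_statistic_brute(a, b) -> float:
    """Two-sample KS statistic from the definition: sup over pooled points
    of |F_a - F_b| with right-continuous empirical CDFs."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pts = np.concatenate([a, b])
    d = 0.0
    for x in pts:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        d = max(d, abs(fa - fb))
    return d


def ks_pvalue_brute(a, b) -> float:
    """Exact two-sided p-value by full enumeration of group assignments.

    Under H0 (continuous, no ties) every split of the pooled sample into
    groups of sizes n and m is equally likely; p = fraction of splits
    whose KS statistic is >= the observed one.  Feasible for n+m <= ~16.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n = a.size
    d_obs = ks_statistic_brute(a, b)
    idx = range(pooled.size)
    hits = 0
    total = 0
    for pick in combinations(idx, n):
        mask = np.zeros(pooled.size, bool)
        mask[list(pick)] = True
        d = ks_statistic_brute(pooled[mask], pooled[~mask])
        hits += d >= d_obs - 1e-12
        total += 1
    return hits / total


def fisher_pvalue_brute(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    With margins fixed, P(a) = C(r1, a) * C(r2, c1 - a) / C(N, c1); the
    two-sided p sums P(k) over all k whose probability does not exceed
    the observed one.
    """
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    denom = comb(N, c1)

    def pmf(k: int) -> float:
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return comb(r1, k) * comb(r2, c1 - k) / denom

    p_obs = pmf(a)
    return sum(p for k in range(0, min(r1, c1) + 1)
               if (p := pmf(k)) <= p_obs * (1 + 1e-9))
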