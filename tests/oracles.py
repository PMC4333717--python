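"""Independent oracles used by the test suite.

Each oracle is a deliberately naive computation (exhaustive search, exact
rational arithmetic, full enumeration) kept separate from the library code
paths it checks.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def brute_force_maximal_segments(x) -> list[tuple[int, int, float]]:
    """Disjoint maximal scoring subsequences by exhaustive interval search.

    Recursively extracts the maximum-sum contiguous interval and recurses on
    both flanks, keeping positive-sum intervals. Returns (i, j, score) with
    inclusive indices, sorted by position.
    """
    x = np.asarray(x, dtype=float)
    out: list[tuple[int, int, float]] = []

    def best_interval(lo: int, hi: int) -> tuple[float, int, int]:
        prefix = np.concatenate([[0.0], np.cumsum(x[lo : hi + 1])])
        m = hi - lo + 1
        sums = prefix[None, 1:] - prefix[:-1, None]  # sums[i, j] = x[lo+i..lo+j]
        sums = np.where(np.triu(np.ones((m, m), dtype=bool)), sums, -np.inf)
        i, j = np.unravel_index(int(np.argmax(sums)), sums.shape)
        return float(sums[i, j]), lo + int(i), lo + int(j)

    def rec(lo: int, hi: int) -> None:
        if lo > hi:
            return
        s, i, j = best_interval(lo, hi)
        if s <= 0:
            return
        rec(lo, i - 1)
        out.append((i, j, s))
        rec(j + 1, hi)

    rec(0, len(x) - 1)
    return sorted(out)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher P by full hypergeometric enumeration in rationals.

    Sums the exact probabilities of every table with the observed margins
    whose probability is at most that of the observed table.
    """
    r1, c1 = a + b, a + c
    r2 = c + d
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum((pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs), Fraction(0))


def rank_sum_exact_p(a, b) -> float:
    """Two-sided rank-sum P by enumerating all label assignments.

    Assumes no ties. Statistic is the rank sum of group a; the P value is
    the fraction of assignments whose statistic is at least as extreme
    (two-sided around the mean rank sum).
    """
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n_a = len(a)
    obs = sum(ranks[v] for v in a)
    mean = n_a * (len(pooled) + 1) / 2
    count = 0
    total = 0
    for subset in combinations(pooled, n_a):
        s = sum(ranks[v] for v in subset)
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total
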