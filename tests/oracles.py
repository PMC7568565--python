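"""Independent brute-force oracles the implementation is checked against.

These deliberately avoid the code paths (and, where possible, the
libraries) they validate: binomial tails by term-wise log-gamma summation,
hypergeometric p-values by exact rational enumeration, interval unions by
position sets, k-medoids by exhaustive medoid enumeration, and complete
linkage by naive agglomeration.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def _big_ratio_to_float(num: int, den: int) -> float:
    """num/den as a float without overflow, for arbitrarily large integers."""
    if num == 0:
        return 0.0
    shift = den.bit_length() - num.bit_length() + 64
    if shift > 0:
        scaled = (num << shift) // den
    else:
        scaled = num // (den << -shift)
    return float(scaled) * 2.0 ** float(-shift)


def binom_upper_tails(n: int, p: Fraction) -> list[float]:
    """P(X >= k) for X ~ Binomial(n, p) and every k in 0..n, term by term.

    Terms are exact integers over the common denominator p.denominator**n
    (via the recurrence N_{i+1} = N_i (n-i) a / ((i+1) b) with p = a/c,
    q = b/c), summed exactly and converted to float only at the end, so the
    result is correct to float precision for any n.
    """
    a, c = p.numerator, p.denominator
    b = c - a  # numerator of q = 1 - p
    term = b**n  # k = 0 term numerator: C(n,0) a^0 b^n
    terms = [term]
    for i in range(n):
        term = term * (n - i) * a // ((i + 1) * b)
        terms.append(term)
    denom = c**n
    tails: list[float] = []
    suffix = 0
    for t in reversed(terms):
        suffix += t
        tails.append(_big_ratio_to_float(suffix, denom))
    tails.reverse()
    tails[0] = 1.0  # suffix over all k is the whole denominator by construction
    return tails


def binom_upper_tail(k: int, n: int, p: Fraction) -> float:
    """P(X >= k) for a single k (convenience wrapper over the exact table)."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    return binom_upper_tails(n, p)[k]


def fisher_greater_exact(a: int, na: int, b: int, nb: int) -> Fraction:
    """Exact one-sided (enrichment in A) Fisher p as a rational number.

    Conditions on margins: K = a + b present genomes among N = na + nb;
    sums hypergeometric point masses C(K, x) C(N-K, na-x) / C(N, na) for
    x >= a.
    """
    N, K = na + nb, a + b
    denom = math.comb(N, na)
    num = sum(
        math.comb(K, x) * math.comb(N - K, na - x)
        for x in range(a, min(K, na) + 1)
        if na - x <= N - K
    )
    return Fraction(num, denom)


def fisher_two_sided_exact(a: int, na: int, b: int, nb: int) -> Fraction:
    """Exact two-sided Fisher p: sum of all point masses <= the observed one."""
    N, K = na + nb, a + b
    denom = math.comb(N, na)

    def mass(x: int) -> int:
        if na - x > N - K or x > K or x < 0:
            return 0
        return math.comb(K, x) * math.comb(N - K, na - x)

    observed = mass(a)
    num = sum(m for x in range(0, min(K, na) + 1) if (m := mass(x)) <= observed)
    return Fraction(num, denom)


def span_union_bruteforce(intervals) -> int:
    """Union length of 1-based inclusive intervals via an explicit position set."""
    covered: set[int] = set()
    for s, e in intervals:
        covered.update(range(s, e + 1))
    return len(covered)


def kmedoids_bruteforce(dist: np.ndarray, k: int) -> tuple[float, list[tuple[int, ...]]]:
    """Optimal cost and ALL optimal medoid sets by exhaustive enumeration."""
    n = dist.shape[0]
    best = math.inf
    argbest: list[tuple[int, ...]] = []
    for medoids in itertools.combinations(range(n), min(k, n)):
        cost = float(dist[list(medoids)].min(axis=0).sum())
        if cost < best - 1e-12:
            best, argbest = cost, [medoids]
        elif abs(cost - best) <= 1e-12:
            argbest.append(medoids)
    return best, argbest


def complete_linkage_bruteforce(dist: np.ndarray, threshold: float) -> list[set[int]]:
    """Naive agglomerative complete linkage cut at ``threshold``.

    Repeatedly merges the pair of clusters with the smallest maximum
    pairwise distance while that distance is <= threshold.
    """
    clusters: list[set[int]] = [{i} for i in range(dist.shape[0])]
    while len(clusters) > 1:
        best_pair, best_d = None, math.inf
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
            if d < best_d:
                best_d, best_pair = d, (i, j)
        if best_d > threshold or best_pair is None:
            break
        i, j = best_pair
        clusters[i] |= clusters[j]
        del clusters[j]
    return clusters
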