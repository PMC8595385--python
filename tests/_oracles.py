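"""Independent brute-force oracles used only by the tests.

These enumerate entire outcome spaces for tiny libraries; they share no code
with the sampling paths they check.
"""

from __future__ import annotations

import itertools
from math import comb, factorial, prod

import numpy as np


def enumerate_hypergeometric_pmf(counts, depth) -> dict[tuple[int, ...], float]:
    """Exact multivariate hypergeometric pmf by complete enumeration.

    P(k) = prod_i C(n_i, k_i) / C(N, depth) over all k with 0 <= k_i <= n_i
    and sum k = depth.
    """
    counts = [int(c) for c in counts]
    total = sum(counts)
    denom = comb(total, depth)
    pmf = {}
    for k in itertools.product(*(range(min(c, depth) + 1) for c in counts)):
        if sum(k) == depth:
            pmf[k] = prod(comb(c, x) for c, x in zip(counts, k)) / denom
    return pmf


def enumerate_multinomial_pmf(counts, depth) -> dict[tuple[int, ...], float]:
    """Exact multinomial pmf over all outcomes summing to ``depth``."""
    counts = [int(c) for c in counts]
    total = sum(counts)
    p = [c / total for c in counts]
    pmf = {}
    for k in itertools.product(*(range(depth + 1) for _ in counts)):
        if sum(k) == depth:
            coef = factorial(depth) / prod(factorial(x) for x in k)
            pmf[k] = coef * prod(pi**x for pi, x in zip(p, k))
    return pmf


def total_variation(empirical: dict, exact: dict) -> float:
    """TV distance between an empirical outcome frequency map and an exact pmf."""
    keys = set(empirical) | set(exact)
    return 0.5 * sum(abs(empirical.get(k, 0.0) - exact.get(k, 0.0)) for k in keys)


def empirical_outcome_frequencies(draws: np.ndarray) -> dict[tuple[int, ...], float]:
    """Frequency map over outcome vectors, rows of ``draws``."""
    outcomes, counts = np.unique(draws, axis=0, return_counts=True)
    n = draws.shape[0]
    return {tuple(int(v) for v in row): c / n for row, c in zip(outcomes, counts)}


def brute_force_expected_richness(counts, depth) -> float:
    """E[richness] under without-replacement subsampling, by enumeration."""
    pmf = enumerate_hypergeometric_pmf(counts, depth)
    return sum(p * sum(1 for x in k if x > 0) for k, p in pmf.items())
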