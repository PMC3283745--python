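"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive double loops over observation pairs so
they share no code path with the package's searchsorted/rank implementations.
"""

import numpy as np
import pytest

from npmct import GroupedSample


def brute_pairwise_effect(xi, xj) -> float:
    """P(X_i < X_j) + 0.5 P(X_i = X_j) by explicit enumeration of all pairs."""
    xi, xj = np.asarray(xi, float), np.asarray(xj, float)
    total = 0.0
    for a in xi:
        for b in xj:
            if a < b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (xi.size * xj.size)


def brute_unweighted_effects(groups) -> np.ndarray:
    """p_i = (1/3) sum_j int F_j dF_i, with the diagonal term equal to 1/2."""
    p = np.zeros(3)
    for i in range(3):
        tot = 0.5
        for j in range(3):
            if j != i:
                tot += brute_pairwise_effect(groups[j], groups[i])
        p[i] = tot / 3.0
    return p


def brute_pseudo_ranks(groups) -> np.ndarray:
    """1/2 + N * mean_j F_j(x), each EDF evaluated by counting."""
    N = sum(len(g) for g in groups)
    out = []
    for g in groups:
        for x in g:
            G = 0.0
            for h in groups:
                h = np.asarray(h, float)
                G += (np.sum(h < x) + 0.5 * np.sum(h == x)) / h.size
            out.append(0.5 + N * G / 3.0)
    return np.array(out)


def random_grouped(rng, max_n=30, tied=False, min_n=2) -> GroupedSample:
    """A random 3-group sample; `tied` draws from 5 categories only."""
    n = rng.integers(min_n, max_n + 1, size=3)
    if tied:
        groups = [rng.integers(0, 5, size=k).astype(float) for k in n]
    else:
        groups = [
            rng.normal(rng.normal(0, 1), rng.uniform(0.5, 2.0), size=k) for k in n
        ]
    return GroupedSample(tuple(groups))


@pytest.fixture
def rng():
    return np.random.default_rng(20120221)
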