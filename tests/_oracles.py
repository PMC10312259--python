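"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: p-values come from
scipy's distribution objects, subgraph enumeration from exhaustive subset
scans, and the testability correction factor from explicit evaluation of
m(k) for k = 1, 2, ...
"""

from __future__ import annotations

import itertools

from scipy.stats import binom, hypergeom

from sgmine import count_support, union_edge_universe
from sgmine.exact_tests import fisher_min_p, mcnemar_min_p


def fisher_two_sided_scipy(f1: int, n1: int, f: int, n: int) -> float:
    """Two-sided Fisher p as doubled smaller hypergeometric tail (scipy)."""
    dist = hypergeom(n, f, n1)
    left = dist.cdf(f1)
    right = dist.sf(f1 - 1)
    return min(1.0, 2.0 * min(left, right))


def mcnemar_two_sided_scipy(y10: int, d: int) -> float:
    dist = binom(d, 0.5)
    left = dist.cdf(y10)
    right = dist.sf(y10 - 1)
    return min(1.0, 2.0 * min(left, right))


def brute_force_supported(dataset, min_support=1, max_links=None):
    """All supported subgraphs by scanning every subset of the edge universe."""
    universe = union_edge_universe(dataset)
    found = {}
    max_r = len(universe) if max_links is None else min(max_links, len(universe))
    for r in range(1, max_r + 1):
        for combo in itertools.combinations(universe, r):
            sc = count_support(dataset, combo)
            if sc.f >= min_support:
                found[frozenset(combo)] = sc
    return found


def brute_force_tarone(dataset, alpha, max_links=None):
    """K(alpha) by explicit evaluation of m(k) for k = 1, 2, ..."""
    supported = brute_force_supported(dataset, 1, max_links)
    if dataset.design == "within":
        stats = [sc.d for sc in supported.values()]
        minp = mcnemar_min_p
    else:
        stats = [sc.f for sc in supported.values()]
        minp = lambda s: fisher_min_p(s, dataset.n1, dataset.n2)
    k = 1
    while True:
        m = sum(1 for s in stats if minp(s) <= alpha / k)
        if m <= k:
            return k, m
        k += 1
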