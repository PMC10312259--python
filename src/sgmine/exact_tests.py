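"""Exact conditional tests for subgraph occurrence counts.

Between-groups comparisons use Fisher's exact test: conditional on the total
number of occurrences f of a subgraph, the count in group 1 is hypergeometric
under the null hypothesis of equal occurrence probabilities.  Within-subject
comparisons use McNemar's exact test: conditional on the number of discordant
pairs d, the count of "condition-A-only" subjects is Binomial(d, 1/2) under
marginal homogeneity.

Both tests are discrete, so each margin has a *minimum achievable p-value*:
the smallest two-sided p any allocation of the observed total could produce.
This is the quantity Tarone-style testability corrections are built on.

All tail sums are computed in exact integer arithmetic (a single float
division at the end), so results are reproducible to full double precision.
Two-sided p-values are twice the smaller tail, capped at 1; rejection is
always inclusive (reject iff p <= threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

__all__ = [
    "ContingencyTable",
    "PValueTriple",
    "fisher_p",
    "fisher_p_values",
    "fisher_min_p",
    "fisher_min_support",
    "mcnemar_p",
    "mcnemar_p_values",
    "mcnemar_min_p",
    "mcnemar_min_d",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Margins of the 2x2 occurrence table.

    ``f1`` occurrences in group 1 (of ``n1`` graphs), ``f`` total occurrences
    in the pooled sample of ``n`` graphs.
    """

    f1: int
    n1: int
    f: int
    n: int

    def __post_init__(self):
        if not (0 < self.n1 < self.n):
            raise ValueError(f"need 0 < n1 < n, got n1={self.n1}, n={self.n}")
        if not (0 <= self.f <= self.n):
            raise ValueError(f"need 0 <= f <= n, got f={self.f}, n={self.n}")
        lo = max(0, self.f - (self.n - self.n1))
        hi = min(self.f, self.n1)
        if not (lo <= self.f1 <= hi):
            raise ValueError(
                f"infeasible table: f1={self.f1} outside [{lo}, {hi}] "
                f"for n={self.n}, n1={self.n1}, f={self.f}"
            )


@dataclass(frozen=True)
class PValueTriple:
    """Left-, right-, and two-sided p-values of one exact test."""

    left: float
    right: float
    two_sided: float


def _two_sided(left: float, right: float) -> float:
    return min(1.0, 2.0 * min(left, right))


@lru_cache(maxsize=100_000)
def _hyper_tails(n: int, n1: int, f: int) -> tuple[int, list, list, int]:
    """Exact hypergeometric tail numerators over the feasible f1 range.

    Returns (lo, left_cums, right_cums, total) where left_cums[i] is the
    integer numerator of P(F1 <= lo+i) and right_cums[i] of P(F1 >= lo+i),
    with denominator C(n, n1).
    """
    lo = max(0, f - (n - n1))
    hi = min(f, n1)
    weights = [comb(f, k) * comb(n - f, n1 - k) for k in range(lo, hi + 1)]
    left = []
    acc = 0
    for w in weights:
        acc += w
        left.append(acc)
    right = []
    acc = 0
    for w in reversed(weights):
        acc += w
        right.append(acc)
    right.reverse()
    return lo, left, right, comb(n, n1)


def fisher_p(table: ContingencyTable) -> PValueTriple:
    """Fisher's exact test p-values for a 2x2 occurrence table.

    The right tail sums the hypergeometric probabilities of all feasible
    counts >= f1, the left tail those <= f1; the two-sided p is twice the
    smaller tail, capped at 1.
    """
    lo, left, right, total = _hyper_tails(table.n, table.n1, table.f)
    i = table.f1 - lo
    pl = left[i] / total
    pr = right[i] / total
    return PValueTriple(pl, pr, _two_sided(pl, pr))


@lru_cache(maxsize=50_000)
def fisher_p_values(n: int, n1: int, f: int) -> tuple[float, ...]:
    """Two-sided Fisher p for every feasible f1, indexed by f1 directly.

    Infeasible f1 positions are filled with 1.0; used for vectorized lookups
    in the permutation engine.
    """
    lo, left, right, total = _hyper_tails(n, n1, f)
    out = [1.0] * (n1 + 1)
    for i in range(len(left)):
        out_idx = lo + i
        out[out_idx] = _two_sided(left[i] / total, right[i] / total)
    return tuple(out)


@lru_cache(maxsize=100_000)
def fisher_min_p(f: int, n1: int, n2: int) -> float:
    """Minimum achievable two-sided Fisher p over all allocations of f.

    Attained when the f occurrences are split as unevenly as the margins
    allow, i.e. at one of the two extreme feasible values of f1.
    """
    n = n1 + n2
    if not (0 <= f <= n):
        raise ValueError(f"need 0 <= f <= n1+n2, got f={f}")
    if f == 0 or f == n:
        return 1.0
    lo = max(0, f - n2)
    hi = min(f, n1)
    best = 1.0
    for f1 in {lo, hi}:
        best = min(best, fisher_p(ContingencyTable(f1, n1, f, n)).two_sided)
    return best


@lru_cache(maxsize=10_000)
def fisher_min_support(threshold: float, n1: int, n2: int):
    """Smallest total support f whose minimum achievable p is <= threshold.

    Returns None when no f qualifies (the threshold is unattainable).  Used
    as the anti-monotone pruning bound in the miner: supports below this can
    never be testable at the given level.
    """
    for f in range(0, n1 + n2 + 1):
        if fisher_min_p(f, n1, n2) <= threshold:
            return f
    return None


@lru_cache(maxsize=50_000)
def _binom_tails(d: int) -> tuple[list, list, int]:
    """Integer Binomial(d, 1/2) tail numerators with denominator 2^d."""
    weights = [comb(d, k) for k in range(d + 1)]
    left = []
    acc = 0
    for w in weights:
        acc += w
        left.append(acc)
    right = []
    acc = 0
    for w in reversed(weights):
        acc += w
        right.append(acc)
    right.reverse()
    return left, right, 1 << d


def mcnemar_p(y10: int, d: int) -> PValueTriple:
    """McNemar's exact test from the discordant-pair split.

    ``y10`` subjects showed the subgraph only in condition A out of ``d``
    discordant subjects; under the null y10 ~ Binomial(d, 1/2).
    """
    if d < 0 or not (0 <= y10 <= d):
        raise ValueError(f"need 0 <= y10 <= d, got y10={y10}, d={d}")
    if d == 0:
        return PValueTriple(1.0, 1.0, 1.0)
    left, right, total = _binom_tails(d)
    pl = left[y10] / total
    pr = right[y10] / total
    return PValueTriple(pl, pr, _two_sided(pl, pr))


@lru_cache(maxsize=10_000)
def mcnemar_p_values(d: int) -> tuple[float, ...]:
    """Two-sided McNemar p for every y10 in 0..d (vector lookup table)."""
    if d == 0:
        return (1.0,)
    left, right, total = _binom_tails(d)
    return tuple(
        _two_sided(left[k] / total, right[k] / total) for k in range(d + 1)
    )


def mcnemar_min_p(d: int) -> float:
    """Minimum achievable two-sided McNemar p: min(1, 2 * (1/2)^d).

    Attained at y10 = 0 or y10 = d; depends on the margin only through the
    discordant-pair count.
    """
    if d < 0:
        raise ValueError(f"need d >= 0, got {d}")
    if d <= 1:
        return 1.0
    return 2.0 ** (1 - d)


@lru_cache(maxsize=10_000)
def mcnemar_min_d(threshold: float, n_max: int):
    """Smallest discordant count d with mcnemar_min_p(d) <= threshold.

    Returns None when even d = n_max cannot reach the threshold.  Since
    d <= f, this doubles as a support pruning bound in the within design.
    """
    for d in range(0, n_max + 1):
        if mcnemar_min_p(d) <= threshold:
            return d
    return None
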