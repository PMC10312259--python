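"""Subgraph enumeration with testability pruning and discrete FWER corrections.

Because subgraph occurrence is containment of an edge set, enumerating all
supported subgraphs is frequent-itemset mining over the observed edge
universe: total support f(G) is anti-monotone under adding edges, so a
depth-first search over the deterministic edge order can prune any branch
whose support falls below the current minimum-support bound.

Three corrections for the multiple-comparison problem live here:

``bonferroni``
    Divide alpha by the number of conceivable subgraphs (2^(l^2) - 1 for
    static directed data).  Usually hopeless: the corrected threshold is
    often below the smallest achievable p-value.
``tarone``
    Exploit discreteness: only subgraphs whose *minimum achievable* p-value
    reaches alpha/k can ever be rejected at that level.  The correction
    factor K(alpha) is the smallest integer k such that the number m(k) of
    (alpha/k)-testable supported subgraphs is at most k.
``hommel``
    Opt-in refinement of Tarone: the integer correction factor is relaxed to
    the best real-valued rejection threshold t* <= alpha satisfying the same
    union bound m(t) * t <= alpha.  Never less powerful than plain Tarone.

The Westfall-Young permutation correction is in :mod:`sgmine.westfall_young`.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterator, Optional

from .core import (
    BETWEEN,
    WITHIN,
    Edge,
    GraphDataset,
    SupportCounts,
    union_edge_universe,
)
from . import exact_tests as et

__all__ = [
    "SubgraphRecord",
    "MiningResult",
    "enumerate_supported",
    "tarone_factor",
    "bonferroni_factor",
    "mine",
    "complement_dataset",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubgraphRecord:
    """One candidate subgraph with its counts and p-values."""

    edges: tuple[Edge, ...]
    support: SupportCounts
    p_value: float
    min_p: float
    corrected_p: Optional[float] = None


@dataclass(frozen=True)
class MiningResult:
    """Outcome of one mining run.

    ``correction_factor`` is K(alpha) for Tarone (int), the conceivable-
    subgraph count for Bonferroni (int), alpha/t* for the Hommel refinement
    (float), or the corrected level delta for Westfall-Young (float).
    ``significant`` is sorted by p-value, ties broken by edge-universe order.
    """

    method: str
    alpha: float
    design: str
    correction_factor: object
    num_testable: int
    significant: tuple[SubgraphRecord, ...]
    n_perm: Optional[int] = None
    seed: Optional[int] = None
    max_links: Optional[int] = None
    universe_size: int = 0


class _BitData:
    """Bitset view of a dataset for fast support counting.

    Each universe edge maps to an integer bitmask over the transactions
    (between: group A graphs then group B graphs; within: condition A then
    condition B, subject-aligned).  Support counting of an edge set is then
    AND + popcount.
    """

    def __init__(self, dataset: GraphDataset, max_links: Optional[int] = None):
        self.dataset = dataset
        self.design = dataset.design
        self.universe = union_edge_universe(dataset)
        self.max_links = max_links
        self.n1 = dataset.n1
        self.n2 = dataset.n2
        graphs = list(dataset.group_a) + list(dataset.group_b)
        self.n_trans = len(graphs)
        self.full_mask = (1 << self.n_trans) - 1
        self.edge_masks = []
        for edge in self.universe:
            m = 0
            for t, g in enumerate(graphs):
                if edge in g.edges:
                    m |= 1 << t
            self.edge_masks.append(m)
        self.mask_a = (1 << self.n1) - 1
        if self.design == WITHIN:
            n = self.n1
            # min-p depends on the discordant count d; d <= f bounds pruning
            self.minp_by_stat = [et.mcnemar_min_p(d) for d in range(n + 1)]
        else:
            n = self.n1 + self.n2
            self.minp_by_stat = [
                et.fisher_min_p(f, self.n1, self.n2) for f in range(n + 1)
            ]

    # -- per-node quantities ------------------------------------------------

    def counts(self, mask: int) -> SupportCounts:
        a = mask & self.mask_a
        f1 = a.bit_count()
        if self.design == WITHIN:
            b = mask >> self.n1
            f2 = b.bit_count()
            y11 = (a & b).bit_count()
            y10 = f1 - y11
            y01 = f2 - y11
            y00 = self.n1 - y11 - y10 - y01
            return SupportCounts(f1, f2, y11, y10, y01, y00)
        f2 = (mask >> self.n1).bit_count()
        return SupportCounts(f1, f2)

    def stat(self, mask: int) -> int:
        """Margin the minimum achievable p depends on: f (between) or d (within)."""
        if self.design == WITHIN:
            a = mask & self.mask_a
            b = mask >> self.n1
            return a.bit_count() + b.bit_count() - 2 * (a & b).bit_count()
        return mask.bit_count()

    def p_value(self, mask: int) -> float:
        if self.design == WITHIN:
            a = mask & self.mask_a
            b = mask >> self.n1
            y11 = (a & b).bit_count()
            y10 = a.bit_count() - y11
            d = y10 + (b.bit_count() - y11)
            return et.mcnemar_p_values(d)[y10]
        f1 = (mask & self.mask_a).bit_count()
        f = mask.bit_count()
        n = self.n1 + self.n2
        return et.fisher_p_values(n, self.n1, f)[f1]

    def min_support_for(self, threshold: float) -> Optional[int]:
        """Smallest total support compatible with testability at threshold."""
        if self.design == WITHIN:
            return et.mcnemar_min_d(threshold, self.n1)
        return et.fisher_min_support(threshold, self.n1, self.n2)

    def record(self, idxs: tuple[int, ...], mask: int,
               corrected_p: Optional[float] = None) -> SubgraphRecord:
        support = self.counts(mask)
        stat = support.d if self.design == WITHIN else support.f
        return SubgraphRecord(
            edges=tuple(self.universe[i] for i in idxs),
            support=support,
            p_value=self.p_value(mask),
            min_p=self.minp_by_stat[stat],
            corrected_p=corrected_p,
        )


def _iter_nodes(bd: _BitData, min_support: int,
                max_links: Optional[int]) -> Iterator[tuple[tuple[int, ...], int]]:
    """DFS over supported edge sets, extending only with later-ordered edges."""
    edge_masks = bd.edge_masks
    n_edges = len(edge_masks)

    def rec(prefix: tuple[int, ...], mask: int, start: int):
        for j in range(start, n_edges):
            m = mask & edge_masks[j]
            if m.bit_count() < min_support:
                continue
            item = prefix + (j,)
            yield item, m
            if max_links is None or len(item) < max_links:
                yield from rec(item, m, j + 1)

    if min_support <= bd.n_trans:
        yield from rec((), bd.full_mask, 0)


def enumerate_supported(
    dataset: GraphDataset,
    min_support: int = 1,
    max_links: Optional[int] = None,
) -> Iterator[SubgraphRecord]:
    """Yield every nonempty supported subgraph exactly once (DFS preorder).

    A subgraph is yielded iff its total support f(G) is at least
    ``min_support`` and it has at most ``max_links`` edges.  ``corrected_p``
    is left unset; :func:`mine` fills it for significant subgraphs.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    bd = _BitData(dataset)
    for idxs, mask in _iter_nodes(bd, min_support, max_links):
        yield bd.record(idxs, mask)


def _tarone_search(bd: _BitData, alpha: float,
                   max_links: Optional[int]) -> tuple[int, int, Counter]:
    """Find K(alpha) by frequency mining with an adaptively rising support bound.

    Visits every supported subgraph whose margin statistic could still be
    testable at the current candidate level alpha/k, tallying the multiset of
    margin statistics (total support f for between, discordant count d for
    within).  Whenever the partial testable count m exceeds k, k is
    incremented and the support bound tightened; subgraphs pruned by the
    tighter bound are untestable at every remaining level, so the final
    (k, m(k)) agree with explicit evaluation of m(k) for k = 1..K.
    """
    minp_stat = bd.minp_by_stat
    k = 1
    sigma = bd.min_support_for(alpha)
    counter: Counter = Counter()
    if sigma is None:
        return 1, 0, counter
    m = 0
    threshold = alpha
    edge_masks = bd.edge_masks
    n_edges = len(edge_masks)
    stack = [(0, bd.full_mask, 0)]  # (depth, mask, start)
    while stack:
        depth, mask, start = stack.pop()
        for j in range(start, n_edges):
            msub = mask & edge_masks[j]
            f = msub.bit_count()
            if f < sigma:
                continue
            s = bd.stat(msub)
            counter[s] += 1
            if minp_stat[s] <= threshold:
                m += 1
                while m > k:
                    k += 1
                    threshold = alpha / k
                    m = sum(
                        c for s2, c in counter.items() if minp_stat[s2] <= threshold
                    )
                    new_sigma = bd.min_support_for(threshold)
                    sigma = (
                        bd.n_trans + 1 if new_sigma is None else new_sigma
                    )
            if max_links is None or depth + 1 < max_links:
                stack.append((depth + 1, msub, j + 1))
    m = sum(c for s2, c in counter.items() if minp_stat[s2] <= alpha / k)
    return k, m, counter


def tarone_factor(dataset: GraphDataset, alpha: float = 0.05,
                  max_links: Optional[int] = None) -> tuple[int, int]:
    """Tarone correction factor K(alpha) and the testable count m(K).

    K(alpha) is the smallest integer k with m(k) <= k, where m(k) counts the
    supported subgraphs whose minimum achievable p-value is at most alpha/k.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    bd = _BitData(dataset)
    k, m, _ = _tarone_search(bd, alpha, max_links)
    return k, m


def bonferroni_factor(dataset: GraphDataset) -> int:
    """Number of conceivable nonempty subgraphs, used as Bonferroni factor.

    2^(l^2) - 1 link patterns for static directed data (diagonal included),
    2^(l(l+1)/2) - 1 for undirected.  With lag labels the space of possible
    patterns is unbounded a priori, so the observed edge universe is used
    instead (conservative and well-defined); a warning is logged.
    """
    l = dataset.n_nodes
    if dataset.has_lags:
        n_pos = len(union_edge_universe(dataset))
        logger.warning(
            "lag-labelled data: Bonferroni factor based on the %d observed "
            "edge positions rather than a closed-form pattern count", n_pos,
        )
    elif dataset.directed:
        n_pos = l * l
    else:
        n_pos = l * (l + 1) // 2
    return (1 << n_pos) - 1


def _threshold_from_factor(alpha: float, factor) -> float:
    try:
        return alpha / float(factor)
    except OverflowError:
        return 0.0


def _capped_scaled_p(factor, p: float) -> float:
    """min(1, factor * p), robust to astronomically large integer factors."""
    try:
        v = float(factor) * p
    except OverflowError:
        return 1.0
    return 1.0 if (v > 1.0 or math.isinf(v)) else v


def _collect_significant(bd: _BitData, threshold: float, factor,
                         max_links: Optional[int]) -> tuple[list, int]:
    """Enumerate at the operative level; return significant records and m."""
    sigma = bd.min_support_for(threshold)
    records = []
    num_testable = 0
    if sigma is None:
        return records, 0
    minp_stat = bd.minp_by_stat
    for idxs, mask in _iter_nodes(bd, sigma, max_links):
        s = bd.stat(mask)
        if minp_stat[s] > threshold:
            continue
        num_testable += 1
        p = bd.p_value(mask)
        if p <= threshold:
            records.append(
                (p, idxs, bd.record(idxs, mask, _capped_scaled_p(factor, p)))
            )
    records.sort(key=lambda t: (t[0], t[1]))
    return [r for _, _, r in records], num_testable


def _hommel_threshold(bd: _BitData, alpha: float, k_star: int,
                      counter: Counter) -> float:
    """Best real-valued rejection threshold satisfying m(t) * t <= alpha.

    Candidates are the achievable minimum p-values t_i <= alpha, the levels
    alpha/m(t_i), and Tarone's alpha/K (so the result is never below it).
    """
    minp_stat = bd.minp_by_stat
    levels = sorted({minp_stat[s] for s in counter if minp_stat[s] <= alpha})

    def m_at(t: float) -> int:
        return sum(c for s, c in counter.items() if minp_stat[s] <= t)

    candidates = set(levels) | {alpha / k_star}
    for t in levels:
        mt = m_at(t)
        if mt:
            candidates.add(alpha / mt)
    best = 0.0
    for t in candidates:
        if t <= alpha and m_at(t) * t <= alpha:
            best = max(best, t)
    return best


def mine(
    dataset: GraphDataset,
    method: str = "tarone",
    alpha: float = 0.05,
    max_links: Optional[int] = None,
) -> MiningResult:
    """Mine all subgraphs occurring with significantly different probabilities.

    Between-design datasets are tested with Fisher's exact test, within-design
    datasets with McNemar's exact test; ``method`` selects the multiple-
    comparison correction (``tarone``, ``hommel``, or ``bonferroni``).
    Rejection is inclusive (p <= corrected threshold).
    """
    if method not in ("tarone", "hommel", "bonferroni"):
        raise ValueError(
            f"unknown method {method!r}; use tarone, hommel, bonferroni "
            "(or mine_wy for westfall_young)"
        )
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if max_links is not None and max_links < 1:
        raise ValueError("max_links must be >= 1 (or None for unlimited)")
    bd = _BitData(dataset)
    if method == "bonferroni":
        factor = bonferroni_factor(dataset)
        threshold = _threshold_from_factor(alpha, factor)
    elif method == "tarone":
        k_star, _, _ = _tarone_search(bd, alpha, max_links)
        factor = k_star
        threshold = alpha / k_star
    else:  # hommel
        k_star, _, counter = _tarone_search(bd, alpha, max_links)
        # counter from the adaptive search may lack low-support entries; redo
        # the tally at the alpha level so every candidate threshold is exact
        sigma1 = bd.min_support_for(alpha)
        counter = Counter()
        if sigma1 is not None:
            for _, mask in _iter_nodes(bd, sigma1, max_links):
                counter[bd.stat(mask)] += 1
        threshold = _hommel_threshold(bd, alpha, k_star, counter)
        factor = alpha / threshold if threshold > 0 else math.inf
    significant, num_testable = _collect_significant(
        bd, threshold, factor, max_links
    )
    logger.debug(
        "mine: method=%s design=%s universe=%d testable=%d significant=%d",
        method, dataset.design, len(bd.universe), num_testable, len(significant),
    )
    return MiningResult(
        method=method,
        alpha=alpha,
        design=dataset.design,
        correction_factor=factor,
        num_testable=num_testable,
        significant=tuple(significant),
        max_links=max_links,
        universe_size=len(bd.universe),
    )


def complement_dataset(dataset: GraphDataset) -> GraphDataset:
    """Negative version of every graph: flip each possible link position.

    Useful for very densely connected data, where mining the sparse
    complement is much cheaper.  Only defined for unlagged data.
    """
    if dataset.has_lags:
        raise ValueError("complement is undefined for lag-labelled data")
    l = dataset.n_nodes
    if dataset.directed:
        all_edges = frozenset(Edge(i, j) for i in range(l) for j in range(l))
    else:
        all_edges = frozenset(
            Edge(i, j) for i in range(l) for j in range(i, l)
        )

    def flip(g):
        from .core import GraphSample
        return GraphSample(all_edges - g.edges)

    return GraphDataset(
        dataset.design,
        l,
        dataset.directed,
        tuple(flip(g) for g in dataset.group_a),
        tuple(flip(g) for g in dataset.group_b),
    )
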