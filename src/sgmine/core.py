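"""Graph samples, datasets, and subgraph-occurrence semantics.

A "graph" here is one observed binary network: a set of links on a fixed node
set ``{0, ..., l-1}``.  Links may optionally carry a nonnegative integer time
lag (e.g. the sample offset of an information-transfer interaction); two links
between the same endpoints with different lags are distinct.  A *subgraph* is
simply a set of links, and it *occurs* in an observed graph when all of its
links are present — extra links in the observed graph are allowed.

Two study designs are supported:

``between``
    Two independent groups of subjects, one graph per subject.
``within``
    One group of subjects measured under two conditions; index ``i`` in both
    condition sequences refers to the same subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

__all__ = [
    "Edge",
    "GraphSample",
    "GraphDataset",
    "SupportCounts",
    "as_edge",
    "occurs",
    "count_support",
    "union_edge_universe",
]

BETWEEN = "between"
WITHIN = "within"


class Edge(NamedTuple):
    """A link from ``source`` to ``target``, optionally labelled with a lag.

    Identity is the full triple: ``(0, 1, 5)`` and ``(0, 1, 10)`` are
    different links.  For undirected data, edges are stored canonically with
    ``source <= target``.
    """

    source: int
    target: int
    lag: Optional[int] = None


def edge_sort_key(edge: Edge) -> tuple[int, int, int]:
    """Deterministic ordering key; unlagged edges sort before lagged ones."""
    return (edge.source, edge.target, -1 if edge.lag is None else edge.lag)


def as_edge(edge, *, directed: bool = True) -> Edge:
    """Coerce a 2/3-tuple (or Edge) into a validated, canonical :class:`Edge`."""
    if isinstance(edge, Edge):
        source, target, lag = edge
    else:
        tup = tuple(edge)
        if len(tup) == 2:
            source, target = tup
            lag = None
        elif len(tup) == 3:
            source, target, lag = tup
        else:
            raise ValueError(f"edge must have 2 or 3 components, got {tup!r}")
    if not (isinstance(source, int) and isinstance(target, int)):
        raise ValueError(f"edge endpoints must be integers, got {edge!r}")
    if source < 0 or target < 0:
        raise ValueError(f"edge endpoints must be >= 0, got {edge!r}")
    if lag is not None and (not isinstance(lag, int) or lag < 0):
        raise ValueError(f"edge lag must be a nonnegative integer, got {edge!r}")
    if not directed and source > target:
        source, target = target, source
    return Edge(source, target, lag)


@dataclass(frozen=True)
class GraphSample:
    """One observed network: a duplicate-free set of edges."""

    edges: frozenset[Edge]

    @classmethod
    def from_iterable(cls, edges: Iterable, *, directed: bool = True) -> "GraphSample":
        canonical = [as_edge(e, directed=directed) for e in edges]
        edge_set = frozenset(canonical)
        if len(edge_set) != len(canonical):
            raise ValueError("duplicate edges in graph sample")
        return cls(edge_set)

    def __iter__(self) -> Iterator[Edge]:
        return iter(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, edge: Edge) -> bool:
        return edge in self.edges


def _check_graph(graph: GraphSample, l: int, directed: bool, where: str) -> None:
    for e in graph.edges:
        if e.source >= l or e.target >= l:
            raise ValueError(
                f"{where}: edge {tuple(e)} out of range for {l} nodes"
            )
        if not directed and e.source > e.target:
            raise ValueError(
                f"{where}: undirected edge {tuple(e)} not in canonical order"
            )


@dataclass(frozen=True)
class GraphDataset:
    """Two groups (or conditions) of graph samples on a common node set.

    Parameters
    ----------
    design
        ``"between"`` for two independent groups, ``"within"`` for one group
        of subjects observed under two conditions (index-aligned).
    n_nodes
        Number of nodes ``l``; all edges must satisfy ``0 <= node < l``.
        Self-loops are legal: the underlying random adjacency matrix is the
        full ``l x l`` grid including the diagonal.
    directed
        Whether links are directed.  Undirected edges are stored with
        ``source <= target``.
    group_a, group_b
        The two samples of graphs (group 1 / group 2, or condition A / B).
    """

    design: str
    n_nodes: int
    directed: bool
    group_a: tuple[GraphSample, ...]
    group_b: tuple[GraphSample, ...]

    def __post_init__(self):
        if self.design not in (BETWEEN, WITHIN):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if len(self.group_a) < 1 or len(self.group_b) < 1:
            raise ValueError("both groups must contain at least one graph")
        if self.design == WITHIN and len(self.group_a) != len(self.group_b):
            raise ValueError("within design requires equally sized, paired groups")
        lag_states = set()
        for name, group in (("group_a", self.group_a), ("group_b", self.group_b)):
            for i, g in enumerate(group):
                _check_graph(g, self.n_nodes, self.directed, f"{name}[{i}]")
                for e in g.edges:
                    lag_states.add(e.lag is not None)
        if len(lag_states) > 1:
            raise ValueError("lagged and unlagged edges may not be mixed in one dataset")

    @classmethod
    def build(
        cls,
        design: str,
        n_nodes: int,
        directed: bool,
        group_a: Sequence[Iterable],
        group_b: Sequence[Iterable],
    ) -> "GraphDataset":
        """Construct from plain edge iterables, canonicalizing as needed."""
        ga = tuple(GraphSample.from_iterable(g, directed=directed) for g in group_a)
        gb = tuple(GraphSample.from_iterable(g, directed=directed) for g in group_b)
        return cls(design, n_nodes, directed, ga, gb)

    @property
    def n1(self) -> int:
        return len(self.group_a)

    @property
    def n2(self) -> int:
        return len(self.group_b)

    @property
    def has_lags(self) -> bool:
        for group in (self.group_a, self.group_b):
            for g in group:
                for e in g.edges:
                    return e.lag is not None
        return False

    def validate_subgraph(self, subgraph: Iterable[Edge]) -> frozenset[Edge]:
        """Validate a candidate subgraph against this dataset's conventions."""
        edges = frozenset(as_edge(e, directed=self.directed) for e in subgraph)
        for e in edges:
            if e.source >= self.n_nodes or e.target >= self.n_nodes:
                raise ValueError(
                    f"subgraph edge {tuple(e)} out of range for {self.n_nodes} nodes"
                )
        return edges


@dataclass(frozen=True)
class SupportCounts:
    """Occurrence counts of one subgraph in a dataset.

    ``f1``/``f2`` are occurrence counts in group/condition A and B.  For the
    within design, the four paired categories are filled as well: ``y11``
    (occurred in both conditions), ``y10`` (A only), ``y01`` (B only), ``y00``
    (neither); ``d = y10 + y01`` is the number of discordant pairs.
    """

    f1: int
    f2: int
    y11: Optional[int] = None
    y10: Optional[int] = None
    y01: Optional[int] = None
    y00: Optional[int] = None

    @property
    def f(self) -> int:
        """Total occurrences across both groups/conditions."""
        return self.f1 + self.f2

    @property
    def d(self) -> Optional[int]:
        """Number of discordant pairs (within design only)."""
        if self.y10 is None or self.y01 is None:
            return None
        return self.y10 + self.y01


def occurs(subgraph: Iterable[Edge], graph: GraphSample) -> bool:
    """True iff every edge of ``subgraph`` is present in ``graph``.

    Occurrence is containment: the observed graph may have additional edges.
    Edge identity includes the lag label.
    """
    edges = subgraph if isinstance(subgraph, (set, frozenset)) else set(subgraph)
    return edges <= graph.edges


def count_support(dataset: GraphDataset, subgraph: Iterable[Edge]) -> SupportCounts:
    """Count occurrences of ``subgraph`` in each group of ``dataset``.

    For the within design the four paired category counts are filled by
    pairing subject index ``i`` across the two conditions.
    """
    edges = dataset.validate_subgraph(subgraph)
    in_a = [occurs(edges, g) for g in dataset.group_a]
    in_b = [occurs(edges, g) for g in dataset.group_b]
    f1, f2 = sum(in_a), sum(in_b)
    if dataset.design == WITHIN:
        y11 = sum(a and b for a, b in zip(in_a, in_b))
        y10 = f1 - y11
        y01 = f2 - y11
        y00 = len(in_a) - y11 - y10 - y01
        return SupportCounts(f1, f2, y11, y10, y01, y00)
    return SupportCounts(f1, f2)


def union_edge_universe(dataset: GraphDataset) -> tuple[Edge, ...]:
    """All distinct edges observed in at least one graph, deterministically ordered.

    Any subgraph containing an edge outside this universe has zero support,
    hence p-value 1 and minimum achievable p-value 1: it can never be testable
    at any level below 1, so mining can safely restrict itself to this set.
    """
    seen: set[Edge] = set()
    for group in (dataset.group_a, dataset.group_b):
        for g in group:
            seen.update(g.edges)
    return tuple(sorted(seen, key=edge_sort_key))
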