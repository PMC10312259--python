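"""Random-graph simulators and error-statistics experiment harnesses.

Erdős-Rényi processes (every link position independently present with a
common probability p) are the validation workhorse: the probability that a
subgraph G occurs is then p^|E_G|, which makes family-wise error rates and
power directly checkable.  Identical densities in both groups realize the
complete null; unequal densities (p2 = p1 + e) realize the complete
alternative with per-subgraph effect sizes |p1^|E| - p2^|E||.

The module also provides the within-subject null generator (dependent
condition pairs with identical marginals), empirical resampling of an
observed dataset (independent links, or jointly with replacement), and the
effect-size-stratified detection analysis used for empirical power studies.
All samplers are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import BETWEEN, WITHIN, Edge, GraphDataset, GraphSample
from .mining import MiningResult, enumerate_supported, mine
from .westfall_young import PermutationPlan, mine_wy

__all__ = [
    "ErdosRenyiSpec",
    "ExperimentReport",
    "sample_er_dataset",
    "sample_dependent_within",
    "estimate_fwer",
    "estimate_power",
    "resample_dataset",
    "resampling_power",
    "detection_by_effect",
    "preset_dataset",
    "PRESETS",
]


@dataclass(frozen=True)
class ErdosRenyiSpec:
    """An Erdős-Rényi graph process: each link position present w.p. ``p``.

    The position grid is the full l x l adjacency (diagonal included) for
    directed graphs by default; ``include_self_loops=False`` drops the
    diagonal, and undirected processes use canonical (i <= j) positions.
    """

    l: int
    p: float
    directed: bool = True
    include_self_loops: bool = True

    def __post_init__(self):
        if self.l < 1:
            raise ValueError("l must be >= 1")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must be in [0, 1], got {self.p}")

    @property
    def positions(self) -> tuple[Edge, ...]:
        if self.directed:
            pairs = (
                (i, j) for i in range(self.l) for j in range(self.l)
            )
        else:
            pairs = (
                (i, j) for i in range(self.l) for j in range(i, self.l)
            )
        return tuple(
            Edge(i, j)
            for i, j in pairs
            if self.include_self_loops or i != j
        )


@dataclass(frozen=True)
class ExperimentReport:
    """One row of an error-statistics experiment: setting plus estimate."""

    kind: str  # "fwer" or "power"
    method: str
    design: str
    alpha: float
    reps: int
    seed: int
    estimate: float
    se: float
    l: Optional[int] = None
    p: Optional[float] = None
    effect: Optional[float] = None
    n1: Optional[int] = None
    n2: Optional[int] = None
    n_perm: Optional[int] = None
    rho: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            k: v
            for k, v in self.__dict__.items()
            if k != "extra" and v is not None
        }
        row.update(self.extra)
        return row


def _sample_graphs(positions: Sequence[Edge], p: float, count: int,
                   rng: np.random.Generator) -> list[GraphSample]:
    hits = rng.random((count, len(positions))) < p
    return [
        GraphSample(frozenset(e for e, h in zip(positions, row) if h))
        for row in hits
    ]


def sample_er_dataset(
    spec_a: ErdosRenyiSpec,
    spec_b: ErdosRenyiSpec,
    n1: int,
    n2: int,
    seed,
) -> GraphDataset:
    """Two independent Erdős-Rényi samples as a between-design dataset."""
    if (spec_a.l, spec_a.directed, spec_a.include_self_loops) != (
        spec_b.l, spec_b.directed, spec_b.include_self_loops
    ):
        raise ValueError("the two process specs must share node count and grid")
    rng = np.random.default_rng(seed)
    pos = spec_a.positions
    return GraphDataset(
        BETWEEN,
        spec_a.l,
        spec_a.directed,
        tuple(_sample_graphs(pos, spec_a.p, n1, rng)),
        tuple(_sample_graphs(pos, spec_b.p, n2, rng)),
    )


def sample_dependent_within(
    spec: ErdosRenyiSpec,
    n: int,
    rho: float,
    seed,
) -> GraphDataset:
    """Dependent condition pairs with equal marginals (a complete within-null).

    Condition A links are Bernoulli(p); each condition B link copies its A
    counterpart with probability ``rho`` and is resampled Bernoulli(p)
    otherwise.  Marginals are identical by construction, so every subgraph
    null hypothesis holds, while pairs are positively dependent for rho > 0.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    rng = np.random.default_rng(seed)
    pos = spec.positions
    a = rng.random((n, len(pos))) < spec.p
    copy = rng.random((n, len(pos))) < rho
    fresh = rng.random((n, len(pos))) < spec.p
    b = np.where(copy, a, fresh)
    to_graph = lambda row: GraphSample(
        frozenset(e for e, h in zip(pos, row) if h)
    )
    return GraphDataset(
        WITHIN,
        spec.l,
        spec.directed,
        tuple(to_graph(row) for row in a),
        tuple(to_graph(row) for row in b),
    )


def _run_method(dataset: GraphDataset, method: str, alpha: float,
                n_perm: Optional[int], seed: int,
                max_links: Optional[int]) -> MiningResult:
    if method in ("westfall_young", "westfall-young"):
        plan = PermutationPlan(dataset.design, n_perm or 10_000, seed)
        return mine_wy(dataset, alpha, plan, max_links)
    return mine(dataset, method, alpha, max_links)


def _spawn_seeds(seed, count: int) -> list[int]:
    """Independent per-replicate integer seeds below 2^31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(count) % (2**31)]


def estimate_fwer(
    null_spec: ErdosRenyiSpec,
    n1: int,
    n2: int,
    method: str,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
    n_perm: Optional[int] = None,
    max_links: Optional[int] = None,
    design: str = BETWEEN,
    rho: float = 0.0,
) -> ExperimentReport:
    """Empirical FWER under a complete null: fraction of runs with any rejection.

    ``design="between"`` samples both groups from ``null_spec``;
    ``design="within"`` uses the dependent-pairs null generator with
    within-pair dependence ``rho`` (``n1`` subjects; ``n2`` must match).
    """
    if design == WITHIN and n1 != n2:
        raise ValueError("within design requires n1 == n2 (subject count)")
    seeds = _spawn_seeds(seed, 2 * reps)
    hits = 0
    for r in range(reps):
        if design == WITHIN:
            ds = sample_dependent_within(null_spec, n1, rho, seeds[2 * r])
        else:
            ds = sample_er_dataset(null_spec, null_spec, n1, n2, seeds[2 * r])
        result = _run_method(ds, method, alpha, n_perm, seeds[2 * r + 1],
                             max_links)
        if result.significant:
            hits += 1
    est = hits / reps
    se = float(np.sqrt(est * (1.0 - est) / reps))
    return ExperimentReport(
        kind="fwer", method=method, design=design, alpha=alpha, reps=reps,
        seed=seed, estimate=est, se=se, l=null_spec.l, p=null_spec.p,
        n1=n1, n2=n2, n_perm=n_perm, rho=rho if design == WITHIN else None,
    )


def estimate_power(
    l: int,
    p1: float,
    e: float,
    n1: int,
    n2: int,
    method: str,
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int = 0,
    n_perm: Optional[int] = None,
    max_links: Optional[int] = None,
    directed: bool = True,
    include_self_loops: bool = True,
) -> ExperimentReport:
    """Mean number of significant subgraphs when group densities differ.

    Group 1 links appear with probability ``p1``, group 2 with ``p1 + e``;
    every subgraph's null is false, so each rejection is a true detection.
    """
    if not (0.0 <= p1 + e <= 1.0):
        raise ValueError("p1 + e must be a probability")
    spec_a = ErdosRenyiSpec(l, p1, directed, include_self_loops)
    spec_b = ErdosRenyiSpec(l, p1 + e, directed, include_self_loops)
    seeds = _spawn_seeds(seed, 2 * reps)
    counts = np.empty(reps)
    for r in range(reps):
        ds = sample_er_dataset(spec_a, spec_b, n1, n2, seeds[2 * r])
        result = _run_method(ds, method, alpha, n_perm, seeds[2 * r + 1],
                             max_links)
        counts[r] = len(result.significant)
    est = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return ExperimentReport(
        kind="power", method=method, design=BETWEEN, alpha=alpha, reps=reps,
        seed=seed, estimate=est, se=se, l=l, p=p1, effect=e, n1=n1, n2=n2,
        n_perm=n_perm,
    )


def resample_dataset(
    dataset: GraphDataset,
    mode: str,
    n1_new: int,
    n2_new: int,
    seed,
) -> GraphDataset:
    """Resample a dataset to new group sizes from its empirical distributions.

    ``independent_links``: each observed edge is sampled independently per
    new graph with its group-specific empirical frequency (an independent-
    links idealization).  ``joint``: new graphs are drawn uniformly with
    replacement from the group's observed graphs, preserving all link
    dependencies.  The result is always a between-design dataset.
    """
    rng = np.random.default_rng(seed)
    from .core import union_edge_universe

    if mode == "joint":
        groups = []
        for group, n_new in ((dataset.group_a, n1_new), (dataset.group_b, n2_new)):
            idx = rng.integers(0, len(group), size=n_new)
            groups.append(tuple(group[i] for i in idx))
    elif mode == "independent_links":
        universe = union_edge_universe(dataset)
        groups = []
        for group, n_new in ((dataset.group_a, n1_new), (dataset.group_b, n2_new)):
            freqs = np.array(
                [sum(e in g.edges for g in group) / len(group) for e in universe]
            )
            hits = rng.random((n_new, len(universe))) < freqs
            groups.append(
                tuple(
                    GraphSample(frozenset(e for e, h in zip(universe, row) if h))
                    for row in hits
                )
            )
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")
    return GraphDataset(
        BETWEEN, dataset.n_nodes, dataset.directed, groups[0], groups[1]
    )


def resampling_power(
    dataset: GraphDataset,
    mode: str,
    n_new: int,
    method: str,
    alpha: float = 0.05,
    reps: int = 400,
    seed: int = 0,
    n_perm: Optional[int] = None,
    max_links: Optional[int] = None,
) -> tuple[np.ndarray, ExperimentReport]:
    """Per-replicate significant-subgraph counts on resampled data.

    Returns the counts (length ``reps``) and a summary report whose estimate
    is the mean count.
    """
    seeds = _spawn_seeds(seed, 2 * reps)
    counts = np.empty(reps, dtype=int)
    for r in range(reps):
        ds = resample_dataset(dataset, mode, n_new, n_new, seeds[2 * r])
        result = _run_method(ds, method, alpha, n_perm, seeds[2 * r + 1],
                             max_links)
        counts[r] = len(result.significant)
    est = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    report = ExperimentReport(
        kind="power", method=method, design=BETWEEN, alpha=alpha, reps=reps,
        seed=seed, estimate=est, se=se, n1=n_new, n2=n_new, n_perm=n_perm,
        extra={"mode": mode},
    )
    return counts, report


def detection_by_effect(
    dataset: GraphDataset,
    mode: str,
    n_new: int,
    method: str,
    alpha: float = 0.05,
    reps: int = 100,
    seed: int = 0,
    n_perm: Optional[int] = None,
    max_links: Optional[int] = None,
    bin_width: float = 0.05,
) -> pd.DataFrame:
    """Detection probability of observed subgraphs, stratified by effect size.

    Every supported subgraph of the source dataset defines a ground-truth
    entry with empirical occurrence probabilities (pi1, pi2) = (f1/n1,
    f2/n2); its effect size is |pi1 - pi2|.  Each replicate resamples both
    groups at size ``n_new``, mines, and scores each ground-truth subgraph as
    detected iff it appears in the significant set.  Results are aggregated
    into bins of effect size and of min(pi1, pi2) (multiples of
    ``bin_width``); the standard error is the naive across-subgraph SE of the
    mean detection frequency, ignoring between-subgraph detection covariance.
    """
    truth = {}
    for rec in enumerate_supported(dataset, min_support=1, max_links=max_links):
        pi1 = rec.support.f1 / dataset.n1
        pi2 = rec.support.f2 / dataset.n2
        truth[frozenset(rec.edges)] = (pi1, pi2)
    names = list(truth)
    detections = np.zeros(len(names))
    seeds = _spawn_seeds(seed, 2 * reps)
    for r in range(reps):
        ds = resample_dataset(dataset, mode, n_new, n_new, seeds[2 * r])
        result = _run_method(ds, method, alpha, n_perm, seeds[2 * r + 1],
                             max_links)
        found = {frozenset(rec.edges) for rec in result.significant}
        for i, key in enumerate(names):
            if key in found:
                detections[i] += 1
    freq = detections / reps
    rows = []
    for i, key in enumerate(names):
        pi1, pi2 = truth[key]
        rows.append(
            {
                "effect_bin": round(abs(pi1 - pi2) / bin_width) * bin_width,
                "min_prob_bin": round(min(pi1, pi2) / bin_width) * bin_width,
                "detection": freq[i],
            }
        )
    df = pd.DataFrame(rows)
    grouped = (
        df.groupby(["effect_bin", "min_prob_bin"])["detection"]
        .agg(["count", "mean", "std"])
        .reset_index()
        .rename(columns={"count": "n_subgraphs", "mean": "mean_detection"})
    )
    grouped["se"] = (
        grouped.pop("std").fillna(0.0) / np.sqrt(grouped["n_subgraphs"])
    )
    return grouped


def _toy_testability_dataset() -> GraphDataset:
    """A 3-node, 10-vs-10 dataset illustrating testability at alpha = 0.05.

    Contains a subgraph occurring twice in total (untestable: its minimum
    achievable p is ~0.47), one occurring nine times (testable but not
    significant), and a single edge occurring once in group 1 and ten times
    in group 2 (significant after Tarone correction).
    """
    base = [Edge(0, 1)]
    group_a = [set() for _ in range(10)]
    group_b = [set(base) for _ in range(10)]
    group_a[0].add(Edge(0, 1))
    # nine total occurrences, split 4 vs 5: testable, far from significant
    for i in range(4):
        group_a[i].add(Edge(1, 2))
    for i in range(5):
        group_b[i].add(Edge(1, 2))
    # fully connected pattern occurring twice, both in group 2: untestable
    full = {Edge(i, j) for i in range(3) for j in range(3)}
    for i in (8, 9):
        group_b[i] |= full
    return GraphDataset.build(BETWEEN, 3, True, group_a, group_b)


PRESETS = ("er-null", "er-effect", "within-null", "toy-fig4-style")


def preset_dataset(name: str, seed: int = 0) -> GraphDataset:
    """Named synthetic fixture datasets used by the CLI and the test suite."""
    if name == "er-null":
        spec = ErdosRenyiSpec(4, 0.2)
        return sample_er_dataset(spec, spec, 20, 20, seed)
    if name == "er-effect":
        return sample_er_dataset(
            ErdosRenyiSpec(4, 0.2), ErdosRenyiSpec(4, 0.5), 20, 20, seed
        )
    if name == "within-null":
        return sample_dependent_within(ErdosRenyiSpec(4, 0.2), 20, 0.5, seed)
    if name == "toy-fig4-style":
        return _toy_testability_dataset()
    raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
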