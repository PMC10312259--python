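"""Westfall-Young permutation correction for subgraph mining.

The corrected level delta is the alpha-quantile of the permutation
distribution of the minimum p-value over all subgraphs under the complete
null hypothesis.  For two independent groups the group labels are uniformly
reshuffled (preserving the group sizes); for within-subject data only the
two condition labels of each subject are exchanged, by independent fair coin
flips, which keeps both the total occurrences f(G) and the discordant-pair
counts d(G) of every subgraph fixed.  The identity permutation (the observed
dataset) is always included as the first permutation.

Per-permutation minima are taken over the candidate set T(1) of supported
subgraphs whose minimum achievable p-value reaches alpha.  This is exact,
not an approximation: membership in T(1) depends only on permutation-
invariant margins, and any subgraph outside T(1) has p > alpha >= delta in
every permutation, so it can affect neither the quantile at level alpha nor
the rejections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import BETWEEN, WITHIN, GraphDataset
from . import exact_tests as et
from .mining import MiningResult, _BitData, _iter_nodes

__all__ = ["PermutationPlan", "WyDistribution", "wy_null_distribution", "mine_wy"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PermutationPlan:
    """How to resample: design, number of permutations (identity included), seed."""

    design: str
    n_perm: int
    seed: int
    includes_identity: bool = True

    def __post_init__(self):
        if self.design not in (BETWEEN, WITHIN):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not self.includes_identity:
            raise ValueError("the identity permutation must always be included")


@dataclass(frozen=True)
class WyDistribution:
    """Sorted permutation minima and the corrected level delta.

    ``delta`` is realized as the floor(alpha * n_perm)-th smallest minimum
    p-value, adjusted downward past ties so that the fraction of permutation
    minima at or below delta never exceeds alpha; when floor(alpha * n_perm)
    is zero the quantile is undefined and delta degenerates to 0 (no
    rejections).  ``observed_min_p`` is the identity permutation's minimum.
    """

    min_p_values: np.ndarray
    delta: float
    alpha: float
    n_perm: int
    observed_min_p: float


def _candidates(bd: _BitData, alpha: float, max_links: Optional[int]):
    """Supported subgraphs with minimum achievable p <= alpha (the set T(1))."""
    sigma = bd.min_support_for(alpha)
    out = []
    if sigma is None:
        return out
    minp_stat = bd.minp_by_stat
    for idxs, mask in _iter_nodes(bd, sigma, max_links):
        if minp_stat[bd.stat(mask)] <= alpha:
            out.append((idxs, mask))
    return out


def _mask_to_bools(mask: int, n: int) -> np.ndarray:
    return np.array([(mask >> t) & 1 for t in range(n)], dtype=bool)


def _between_min_p(bd: _BitData, cands, n_perm: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-permutation minimum p over candidates, identity first."""
    n, n1 = bd.n_trans, bd.n1
    base = np.zeros(n, dtype=bool)
    base[:n1] = True  # identity assignment: first n1 transactions are group 1
    masks = np.tile(base, (n_perm, 1))
    for r in range(1, n_perm):
        masks[r] = rng.permutation(base)
    if not cands:
        return np.ones(n_perm)
    occ = np.stack([_mask_to_bools(m, n) for _, m in cands])
    f1 = occ.astype(np.float32) @ masks.T.astype(np.float32)  # (C, n_perm)
    f1 = np.rint(f1).astype(np.int64)
    p = np.ones((len(cands), n_perm))
    for c, (_, mask) in enumerate(cands):
        f = mask.bit_count()
        table = np.asarray(et.fisher_p_values(n, n1, f))
        p[c] = table[f1[c]]
    return p.min(axis=0)


def _within_min_p(bd: _BitData, cands, n_perm: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Within-subject condition flips: minimum p per flip vector, identity first."""
    n = bd.n1  # subjects
    flips = rng.random((n_perm, n)) < 0.5
    flips[0] = False  # identity
    if not cands:
        return np.ones(n_perm)
    keep = (~flips).astype(np.float32)
    swap = flips.astype(np.float32)
    p = np.ones((len(cands), n_perm))
    for c, (_, mask) in enumerate(cands):
        a = _mask_to_bools(mask & bd.mask_a, n)
        b = _mask_to_bools(mask >> n, n)
        a_only = (a & ~b).astype(np.float32)
        b_only = (b & ~a).astype(np.float32)
        d = int(a_only.sum() + b_only.sum())
        # after flipping subject i, an A-only pair becomes B-only and vice versa
        y10 = np.rint(keep @ a_only + swap @ b_only).astype(np.int64)
        table = np.asarray(et.mcnemar_p_values(d))
        p[c] = table[y10]
    return p.min(axis=0)


def _delta_from_minima(min_p: np.ndarray, alpha: float, n_perm: int) -> float:
    j = int(np.floor(alpha * n_perm))
    if j == 0:
        return 0.0
    s = np.sort(min_p)
    v = s[j - 1]
    if np.searchsorted(s, v, side="right") <= j:
        return float(v)
    # ties straddle the quantile index: step down to the next distinct value
    i = np.searchsorted(s, v, side="left")
    return float(s[i - 1]) if i > 0 else 0.0


def _raw_min_p(dataset: GraphDataset, alpha: float, plan: PermutationPlan,
               max_links: Optional[int]):
    if plan.design != dataset.design:
        raise ValueError(
            f"permutation plan design {plan.design!r} does not match "
            f"dataset design {dataset.design!r}"
        )
    if not (0 <= alpha < 1):
        raise ValueError("alpha must be in [0, 1)")
    bd = _BitData(dataset)
    cands = _candidates(bd, alpha, max_links) if alpha > 0 else []
    rng = np.random.default_rng(plan.seed)
    if dataset.design == WITHIN:
        min_p = _within_min_p(bd, cands, plan.n_perm, rng)
    else:
        min_p = _between_min_p(bd, cands, plan.n_perm, rng)
    return bd, cands, min_p


def wy_null_distribution(
    dataset: GraphDataset,
    alpha: float,
    plan: PermutationPlan,
    max_links: Optional[int] = None,
) -> WyDistribution:
    """Permutation distribution of the minimum p-value and the level delta."""
    _, _, min_p = _raw_min_p(dataset, alpha, plan, max_links)
    delta = _delta_from_minima(min_p, alpha, plan.n_perm)
    return WyDistribution(
        min_p_values=np.sort(min_p),
        delta=delta,
        alpha=alpha,
        n_perm=plan.n_perm,
        observed_min_p=float(min_p[0]),
    )


def mine_wy(
    dataset: GraphDataset,
    alpha: float = 0.05,
    plan: Optional[PermutationPlan] = None,
    max_links: Optional[int] = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> MiningResult:
    """Mine with the Westfall-Young permutation correction.

    Significant subgraphs are those whose observed two-sided p-value is at
    most delta; each gets ``corrected_p`` equal to the fraction of
    permutation minima at or below its observed p-value.
    """
    if plan is None:
        plan = PermutationPlan(dataset.design, n_perm, seed)
    bd, cands, min_p = _raw_min_p(dataset, alpha, plan, max_links)
    delta = _delta_from_minima(min_p, alpha, plan.n_perm)
    sorted_min_p = np.sort(min_p)
    records = []
    num_testable = len(cands)
    for idxs, mask in cands:
        p = bd.p_value(mask)
        if p <= delta:
            corrected = float(
                np.searchsorted(sorted_min_p, p, side="right") / plan.n_perm
            )
            records.append((p, idxs, bd.record(idxs, mask, corrected)))
    records.sort(key=lambda t: (t[0], t[1]))
    logger.debug(
        "mine_wy: design=%s universe=%d candidates=%d delta=%.3g significant=%d",
        dataset.design, len(bd.universe), num_testable, delta, len(records),
    )
    return MiningResult(
        method="westfall_young",
        alpha=alpha,
        design=dataset.design,
        correction_factor=delta,
        num_testable=num_testable,
        significant=tuple(r for _, _, r in records),
        n_perm=plan.n_perm,
        seed=plan.seed,
        max_links=max_links,
        universe_size=len(bd.universe),
    )
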