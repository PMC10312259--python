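import math

import numpy as np
import pytest

from sgmine import (
    Edge,
    ErdosRenyiSpec,
    GraphDataset,
    GraphSample,
    bonferroni_factor,
    count_support,
    enumerate_supported,
    mine,
    sample_er_dataset,
    tarone_factor,
)
from sgmine.exact_tests import fisher_p_values, mcnemar_p_values
from _oracles import brute_force_supported, brute_force_tarone


def er(l, p, n1, n2, seed):
    spec = ErdosRenyiSpec(l, p)
    return sample_er_dataset(spec, spec, n1, n2, seed)


class TestEnumeration:
    def test_all_empty_graphs_yield_nothing(self):
        ds = GraphDataset.build("between", 3, True, [[], []], [[]])
        assert list(enumerate_supported(ds)) == []

    def test_single_two_edge_graph(self):
        ds = GraphDataset.build("between", 2, True, [[(0, 1), (1, 0)]], [[]])
        found = {frozenset(r.edges) for r in enumerate_supported(ds)}
        assert found == {
            frozenset({Edge(0, 1)}),
            frozenset({Edge(1, 0)}),
            frozenset({Edge(0, 1), Edge(1, 0)}),
        }

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_scan(self, seed):
        ds = er(3, 0.35, 6, 6, seed)
        brute = brute_force_supported(ds)
        mined = {frozenset(r.edges): r.support for r in enumerate_supported(ds)}
        assert set(mined) == set(brute)
        for key, sc in brute.items():
            assert (mined[key].f1, mined[key].f2) == (sc.f1, sc.f2)

    def test_min_support_filters(self, small_er_dataset):
        for r in enumerate_supported(small_er_dataset, min_support=3):
            assert r.support.f >= 3

    def test_max_links_filters(self, small_er_dataset):
        for r in enumerate_supported(small_er_dataset, max_links=2):
            assert len(r.edges) <= 2

    def test_each_subgraph_once(self, small_er_dataset):
        seen = [frozenset(r.edges) for r in enumerate_supported(small_er_dataset)]
        assert len(seen) == len(set(seen))


class TestTaroneFactor:
    def test_nothing_testable(self):
        # 1 + 1 graphs: even the most extreme table cannot reach p <= 0.05
        ds = GraphDataset.build("between", 2, True, [[(0, 1)]], [[]])
        assert tarone_factor(ds, 0.05) == (1, 0)

    def test_rare_subgraph_never_testable(self, toy_dataset):
        # the pattern occurring twice in 10 + 10 has min achievable p ~0.47
        full = {Edge(i, j) for i in range(3) for j in range(3)}
        sc = count_support(toy_dataset, full)
        assert sc.f == 2
        k, _ = tarone_factor(toy_dataset, 0.05)
        rec = [
            r for r in enumerate_supported(toy_dataset) if set(r.edges) == full
        ]
        assert rec[0].min_p > 0.05 / k and rec[0].min_p > 0.05

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_explicit_mk_evaluation(self, seed):
        ds = er(3, 0.3, 8, 8, seed)
        assert tarone_factor(ds, 0.05) == brute_force_tarone(ds, 0.05)

    def test_within_design(self):
        from sgmine import sample_dependent_within

        ds = sample_dependent_within(ErdosRenyiSpec(2, 0.4), 10, 0.3, 11)
        assert tarone_factor(ds, 0.05) == brute_force_tarone(ds, 0.05)


class TestMine:
    def test_identical_groups_nothing_significant(self):
        graphs = [[(0, 1)], [(0, 1), (1, 0)], []] * 3
        ds = GraphDataset.build("between", 2, True, graphs, graphs)
        for method in ("tarone", "hommel", "bonferroni"):
            assert mine(ds, method).significant == ()

    def test_bonferroni_unattainable_for_large_networks(self):
        # 2^(10^2)-1 tests: the corrected level is below any achievable p
        ds = er(10, 0.2, 20, 20, 3)
        res = mine(ds, "bonferroni")
        assert res.correction_factor == 2**100 - 1
        assert res.significant == ()
        assert res.num_testable == 0

    def test_bonferroni_within_tarone(self):
        ds = sample_er_dataset(
            ErdosRenyiSpec(3, 0.2), ErdosRenyiSpec(3, 0.6), 15, 15, 7
        )
        tarone = mine(ds, "tarone")
        bonf = mine(ds, "bonferroni")
        assert bonf.correction_factor >= tarone.correction_factor
        sig_t = {frozenset(r.edges) for r in tarone.significant}
        sig_b = {frozenset(r.edges) for r in bonf.significant}
        assert sig_b <= sig_t

    def test_hommel_never_less_powerful_than_tarone(self):
        for seed in range(4):
            ds = sample_er_dataset(
                ErdosRenyiSpec(3, 0.2), ErdosRenyiSpec(3, 0.6), 15, 15, seed
            )
            sig_t = {frozenset(r.edges) for r in mine(ds, "tarone").significant}
            hommel = mine(ds, "hommel")
            sig_h = {frozenset(r.edges) for r in hommel.significant}
            assert sig_t <= sig_h
            # union bound at the operative threshold still controls alpha
            t_star = hommel.alpha / hommel.correction_factor
            assert hommel.num_testable * t_star <= hommel.alpha + 1e-12

    def test_significant_records_recompute(self):
        ds = sample_er_dataset(
            ErdosRenyiSpec(3, 0.2), ErdosRenyiSpec(3, 0.7), 15, 15, 9
        )
        res = mine(ds, "tarone")
        assert res.significant
        n, n1 = ds.n1 + ds.n2, ds.n1
        for rec in res.significant:
            sc = count_support(ds, rec.edges)
            assert (sc.f1, sc.f2) == (rec.support.f1, rec.support.f2)
            assert rec.p_value == fisher_p_values(n, n1, sc.f)[sc.f1]
            assert rec.min_p <= rec.p_value
            assert rec.p_value <= rec.corrected_p <= 1.0
            assert rec.p_value <= res.alpha / res.correction_factor

    def test_results_sorted_by_p(self):
        ds = sample_er_dataset(
            ErdosRenyiSpec(3, 0.1), ErdosRenyiSpec(3, 0.8), 15, 15, 2
        )
        res = mine(ds, "tarone")
        pvals = [r.p_value for r in res.significant]
        assert pvals == sorted(pvals)

    def test_max_links_restriction_never_adds_rejections(self):
        # with an identical (Bonferroni) correction factor, restricting the
        # search space can only remove rejections
        ds = sample_er_dataset(
            ErdosRenyiSpec(2, 0.2), ErdosRenyiSpec(2, 0.8), 12, 12, 5
        )
        full = {frozenset(r.edges) for r in mine(ds, "bonferroni").significant}
        restricted = {
            frozenset(r.edges)
            for r in mine(ds, "bonferroni", max_links=1).significant
        }
        assert restricted <= full

    def test_within_design_mcnemar_p_values(self):
        from sgmine import sample_dependent_within

        base = sample_dependent_within(ErdosRenyiSpec(2, 0.5), 20, 0.0, 31)
        # force a large effect: drop most edges from condition B
        gb = tuple(
            GraphSample(frozenset(e for e in g.edges if e.source == 0))
            for g in base.group_b
        )
        ds = GraphDataset("within", 2, True, base.group_a, gb)
        res = mine(ds, "tarone")
        for rec in res.significant:
            sc = count_support(ds, rec.edges)
            assert rec.p_value == mcnemar_p_values(sc.d)[sc.y10]

    def test_unknown_method_rejected(self, small_er_dataset):
        with pytest.raises(ValueError, match="unknown method"):
            mine(small_er_dataset, "fdr")
        with pytest.raises(ValueError):
            mine(small_er_dataset, "tarone", alpha=1.5)


class TestBonferroniFactor:
    def test_directed_static(self):
        ds = GraphDataset.build("between", 3, True, [[(0, 1)]], [[]])
        assert bonferroni_factor(ds) == 2**9 - 1

    def test_undirected_static(self):
        ds = GraphDataset.build("between", 3, False, [[(0, 1)]], [[]])
        assert bonferroni_factor(ds) == 2**6 - 1

    def test_lagged_uses_observed_universe(self):
        ds = GraphDataset.build(
            "between", 3, True, [[(0, 1, 5), (1, 2, 10)]], [[(0, 1, 5)]]
        )
        assert bonferroni_factor(ds) == 2**2 - 1


def test_fwer_with_planted_shared_edge():
    """Partial-null FWER: a link present in every graph of both groups keeps
    all null hypotheses true, so any rejection is a false positive."""
    rng = np.random.default_rng(99)
    reps, alpha = 300, 0.05
    hits = {"tarone": 0, "bonferroni": 0}
    for _ in range(reps):
        ds = er(2, 0.3, 15, 15, int(rng.integers(2**31)))
        planted = Edge(0, 0)
        ga = tuple(GraphSample(g.edges | {planted}) for g in ds.group_a)
        gb = tuple(GraphSample(g.edges | {planted}) for g in ds.group_b)
        ds = GraphDataset("between", 2, True, ga, gb)
        for method in hits:
            if mine(ds, method, alpha).significant:
                hits[method] += 1
    for method, h in hits.items():
        est = h / reps
        se = math.sqrt(max(est, 0.01) * (1 - max(est, 0.01)) / reps)
        assert est <= alpha + 2 * se, (method, est)
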