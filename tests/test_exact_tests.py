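import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sgmine.exact_tests import (
    ContingencyTable,
    fisher_min_p,
    fisher_min_support,
    fisher_p,
    fisher_p_values,
    mcnemar_min_d,
    mcnemar_min_p,
    mcnemar_p,
    mcnemar_p_values,
)
from _oracles import fisher_two_sided_scipy, mcnemar_two_sided_scipy


class TestFisher:
    @pytest.mark.parametrize(
        "f1,n1,f,n,expected",
        [
            # urn example: 3 of 12 occurrences fall into a group of 7 out of 20
            (3, 7, 12, 20, 0.5015479876160991),
            # degenerate margin: subgraph never occurs
            (0, 7, 0, 20, 1.0),
            # maximally uneven split of 11 occurrences over 10+10
            (1, 10, 11, 20, 2 * 11 / 184756),
        ],
    )
    def test_two_sided_examples(self, f1, n1, f, n, expected):
        p = fisher_p(ContingencyTable(f1, n1, f, n)).two_sided
        assert p == pytest.approx(expected, rel=1e-12)

    def test_tails_are_probabilities_and_consistent(self):
        t = fisher_p(ContingencyTable(3, 7, 12, 20))
        assert 0 < t.left <= 1 and 0 < t.right <= 1
        assert t.two_sided == min(1.0, 2 * min(t.left, t.right))

    def test_infeasible_table_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            ContingencyTable(f1=8, n1=7, f=12, n=20)
        with pytest.raises(ValueError):
            ContingencyTable(f1=0, n1=0, f=0, n=20)

    def test_matches_scipy_oracle_sampled(self):
        for n, n1, f in [(20, 7, 12), (30, 11, 4), (25, 13, 25), (9, 4, 5)]:
            table = fisher_p_values(n, n1, f)
            for f1 in range(max(0, f - (n - n1)), min(f, n1) + 1):
                assert table[f1] == pytest.approx(
                    fisher_two_sided_scipy(f1, n1, f, n), abs=1e-13
                )


class TestFisherMinP:
    @pytest.mark.parametrize(
        "f,n1,n2,expected",
        [
            (2, 10, 10, 0.47368421052631576),
            (9, 10, 10, 0.00011907597046915932),
            (0, 10, 10, 1.0),
            (20, 10, 10, 1.0),
        ],
    )
    def test_values(self, f, n1, n2, expected):
        assert fisher_min_p(f, n1, n2) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("n1,n2", [(6, 6), (5, 9), (10, 10), (3, 12)])
    def test_extreme_allocation_attains_minimum(self, n1, n2):
        n = n1 + n2
        for f in range(n + 1):
            full_scan = min(
                fisher_p(ContingencyTable(f1, n1, f, n)).two_sided
                for f1 in range(max(0, f - n2), min(f, n1) + 1)
            )
            assert fisher_min_p(f, n1, n2) == pytest.approx(full_scan, rel=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(1, 15), st.integers(1, 15), st.integers(0, 30))
    def test_symmetry(self, n1, n2, f):
        if f > n1 + n2:
            return
        v = fisher_min_p(f, n1, n2)
        assert v == fisher_min_p(n1 + n2 - f, n1, n2)
        assert v == fisher_min_p(f, n2, n1)
        assert 0 < v <= 1

    def test_min_support_threshold(self):
        # smallest f whose min achievable p reaches 0.05 for 20 + 20 graphs
        sigma = fisher_min_support(0.05, 20, 20)
        assert fisher_min_p(sigma, 20, 20) <= 0.05
        assert fisher_min_p(sigma - 1, 20, 20) > 0.05
        assert fisher_min_support(1e-30, 5, 5) is None


class TestMcNemar:
    @pytest.mark.parametrize(
        "y10,d,expected",
        [
            (0, 0, 1.0),
            (5, 5, 0.0625),
            (2, 4, 1.0),  # symmetric split: both tails 11/16, doubled and capped
        ],
    )
    def test_two_sided_examples(self, y10, d, expected):
        assert mcnemar_p(y10, d).two_sided == pytest.approx(expected, rel=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            mcnemar_p(3, 2)
        with pytest.raises(ValueError):
            mcnemar_p(-1, 2)

    @pytest.mark.parametrize(
        "d,expected", [(0, 1.0), (1, 1.0), (10, 2.0**-9)]
    )
    def test_min_p(self, d, expected):
        assert mcnemar_min_p(d) == pytest.approx(expected, rel=1e-12)

    def test_min_p_attained_at_extremes(self):
        for d in range(2, 20):
            scan = min(mcnemar_p(y, d).two_sided for y in range(d + 1))
            assert mcnemar_min_p(d) == pytest.approx(scan, rel=1e-12)
            assert mcnemar_p(0, d).two_sided == pytest.approx(
                mcnemar_min_p(d), rel=1e-12
            )

    def test_matches_scipy_oracle_sampled(self):
        for d in (1, 4, 9, 17):
            table = mcnemar_p_values(d)
            for y in range(d + 1):
                assert table[y] == pytest.approx(
                    mcnemar_two_sided_scipy(y, d), abs=1e-13
                )

    def test_min_d_threshold(self):
        d = mcnemar_min_d(0.05, 40)
        assert mcnemar_min_p(d) <= 0.05 < mcnemar_min_p(d - 1)
        assert mcnemar_min_d(1e-30, 20) is None


class TestNullValidity:
    """P(p <= alpha) <= alpha under the null: conservative discrete tests."""

    ALPHAS = (0.01, 0.05, 0.1, 0.2)

    def test_fisher_null_level(self):
        rng = np.random.default_rng(2024)
        n1 = n2 = 15
        sims = 4000
        f1 = rng.binomial(n1, 0.3, size=sims)
        f2 = rng.binomial(n2, 0.3, size=sims)
        pvals = np.array(
            [fisher_p_values(n1 + n2, n1, int(a + b))[int(a)] for a, b in zip(f1, f2)]
        )
        for alpha in self.ALPHAS:
            rate = (pvals <= alpha).mean()
            se = math.sqrt(alpha * (1 - alpha) / sims)
            assert rate <= alpha + 2 * se

    def test_mcnemar_null_level(self):
        rng = np.random.default_rng(2025)
        n = 20
        sims = 4000
        # dependent pairs with equal marginals: occurrence copied w.p. 0.5
        a = rng.random((sims, n)) < 0.4
        copy = rng.random((sims, n)) < 0.5
        b = np.where(copy, a, rng.random((sims, n)) < 0.4)
        y10 = (a & ~b).sum(axis=1)
        d = (a != b).sum(axis=1)
        pvals = np.array(
            [mcnemar_p_values(int(dd))[int(y)] for y, dd in zip(y10, d)]
        )
        for alpha in self.ALPHAS:
            rate = (pvals <= alpha).mean()
            se = math.sqrt(alpha * (1 - alpha) / sims)
            assert rate <= alpha + 2 * se
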