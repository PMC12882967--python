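"""Whittaker dissimilarity and the turnover/rewiring partition."""

import itertools

import numpy as np
import pytest

from swarmnet.betadiv import (
    BetaPartition,
    all_pairs,
    partition_pair,
    proportions,
    site_pair_summary,
    whittaker_beta,
)
from swarmnet.errors import ValidationError

from conftest import net_from_edges, random_network


def oracle_partition(edges_1, nodes_1, edges_2, nodes_2):
    """Brute-force partition that materializes interaction sets explicitly
    and evaluates the printed form of the Whittaker equation."""
    e1 = {frozenset(e) for e in edges_1}
    e2 = {frozenset(e) for e in edges_2}

    def whit(s1, s2):
        a = len(s1 & s2)
        b = len(s1 - s2)
        c = len(s2 - s1)
        return (a + b + c) / ((2 * a + b + c) / 2) - 1

    beta_wn = whit(e1, e2)
    shared = set(nodes_1) & set(nodes_2)
    s1 = {e for e in e1 if e <= shared}
    s2 = {e for e in e2 if e <= shared}
    beta_os = 0.0 if not (s1 | s2) else whit(s1, s2)
    return beta_wn, beta_wn - beta_os, beta_os


class TestWhittaker:
    def test_printed_equation_value(self):
        assert whittaker_beta(1, 1, 1) == pytest.approx(0.5)

    @pytest.mark.parametrize("k", [1, 5, 50])
    def test_identical_networks(self, k):
        assert whittaker_beta(k, 0, 0) == 0.0

    def test_fully_disjoint(self):
        assert whittaker_beta(0, 3, 2) == 1.0

    def test_all_zero_undefined(self):
        with pytest.raises(ValidationError):
            whittaker_beta(0, 0, 0)

    def test_closed_form_equivalence_on_grid(self):
        """(a+b+c)/((2a+b+c)/2) − 1 == (b+c)/(2a+b+c) over an exhaustive grid."""
        a, b, c = np.meshgrid(*[np.arange(51)] * 3, indexing="ij")
        mask = (a + b + c) > 0
        a, b, c = a[mask], b[mask], c[mask]
        lhs = (a + b + c) / ((2 * a + b + c) / 2) - 1
        rhs = (b + c) / (2 * a + b + c)
        np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-14)


class TestPartitionPair:
    def test_pure_turnover_example(self):
        n1 = net_from_edges([("A", "B"), ("A", "C")])
        n2 = net_from_edges([("A", "B"), ("B", "D")], swarm="sw2")
        p = partition_pair(n1, n2)
        assert p.beta_wn == pytest.approx(0.5)
        assert p.beta_os == pytest.approx(0.0)
        assert p.beta_st == pytest.approx(0.5)

    def test_pure_rewiring_example(self):
        n1 = net_from_edges([("A", "B"), ("C", "D")])
        n2 = net_from_edges([("A", "C"), ("B", "D")], swarm="sw2")
        p = partition_pair(n1, n2)
        assert (p.beta_wn, p.beta_os, p.beta_st) == pytest.approx((1.0, 1.0, 0.0))

    def test_identical_networks(self):
        n1 = net_from_edges([("A", "B"), ("B", "C")])
        n2 = net_from_edges([("A", "B"), ("B", "C")], swarm="sw2")
        p = partition_pair(n1, n2)
        assert (p.beta_wn, p.beta_st, p.beta_os) == (0.0, 0.0, 0.0)

    def test_edgeless_network_rejected(self):
        n1 = net_from_edges([("A", "B")])
        n2 = net_from_edges([], isolated=["A", "B"], swarm="sw2")
        with pytest.raises(ValidationError):
            partition_pair(n1, n2)

    def test_symmetry_swaps_unique_counts(self, rng):
        for _ in range(20):
            n1, n2 = random_network(rng), random_network(rng)
            p12, p21 = partition_pair(n1, n2), partition_pair(n2, n1)
            assert p12.beta_wn == pytest.approx(p21.beta_wn)
            assert p12.beta_os == pytest.approx(p21.beta_os)
            assert (p12.unique_1, p12.unique_2) == (p21.unique_2, p21.unique_1)

    def test_brute_force_oracle_on_random_pairs(self, rng):
        for _ in range(500):
            n1, n2 = random_network(rng), random_network(rng)
            p = partition_pair(n1, n2)
            wn, st, os_ = oracle_partition(
                n1.binary_edges, n1.nodes, n2.binary_edges, n2.nodes
            )
            assert p.beta_wn == pytest.approx(wn, abs=1e-12)
            assert p.beta_st == pytest.approx(st, abs=1e-12)
            assert p.beta_os == pytest.approx(os_, abs=1e-12)
            # structural invariants
            assert abs(p.beta_wn - (p.beta_st + p.beta_os)) < 1e-12
            assert p.beta_os <= p.beta_wn + 1e-12
            if n1.nodes == n2.nodes:
                assert p.beta_os == pytest.approx(p.beta_wn)


class TestAllPairs:
    @pytest.mark.parametrize("n,expected", [(2, 1), (7, 21)])
    def test_pair_counts(self, n, expected):
        nets = [net_from_edges([("A", "B")], swarm=f"sw{i}") for i in range(n)]
        assert len(all_pairs(nets)) == expected

    def test_too_few_eligible(self):
        nets = [
            net_from_edges([("A", "B")], swarm="sw1"),
            net_from_edges([], isolated=["C"], swarm="sw2"),
        ]
        with pytest.raises(ValidationError):
            all_pairs(nets)


class TestProportions:
    def test_turnover_share(self):
        p = BetaPartition(None, None, 0.89, 0.53, 0.36, 1, 1, 1)
        turnover, rewiring = proportions(p)
        assert turnover == pytest.approx(0.53 / 0.89)
        assert turnover + rewiring == pytest.approx(1.0)

    def test_degenerate_shares(self):
        p = BetaPartition(None, None, 0.0, 0.0, 0.0, 3, 0, 0)
        with pytest.raises(ValidationError):
            proportions(p)

    def test_pure_component_shares(self):
        p_os = BetaPartition(None, None, 0.4, 0.0, 0.4, 1, 1, 1)
        assert proportions(p_os) == pytest.approx((0.0, 1.0))
        p_st = BetaPartition(None, None, 0.4, 0.4, 0.0, 1, 1, 1)
        assert proportions(p_st) == pytest.approx((1.0, 0.0))


class TestSitePairSummary:
    def test_single_spanning_pair_equals_its_values(self):
        n1 = net_from_edges([("A", "B")], site="S1")
        n2 = net_from_edges([("A", "C")], site="S2", swarm="sw2")
        p = partition_pair(n1, n2)
        (summary,) = site_pair_summary([p])
        assert (summary.site_1, summary.site_2) == ("S1", "S2")
        assert summary.mean_beta_wn == pytest.approx(p.beta_wn)
        assert summary.n_pairs == 1

    def test_seven_sites_give_21_between_site_rows(self):
        nets = [
            net_from_edges([("A", f"B{i}")], site=f"S{i}", swarm=f"sw{i}{j}")
            for i in range(1, 8)
            for j in range(2)
        ]
        summaries = site_pair_summary(all_pairs(nets))
        between = [s for s in summaries if s.site_1 != s.site_2]
        assert len(between) == 21
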