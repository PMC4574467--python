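"""The penalized softwired criterion: worked example and invariants."""

import math

import numpy as np
import pytest

from softwired.io import parse_enewick
from softwired.matrix import CharacterMatrix, CostMatrix
from softwired.network import enumerate_display_trees
from softwired.parsimony import exhaustive_tree_score, hardwired_score
from softwired.scoring import (
    best_display_tree,
    edge_difference,
    network_cost,
    network_penalty,
    softwired_score,
)

from conftest import C1, C2, matrix_from_columns, random_instance


class TestWorkedExample:
    """Toy 1-reticulation network displaying ((A,B),(C,D)) and (A,((B,C),D))."""

    def test_softwired_minima(self, toy_network, toy_matrix_c112):
        rows, s = softwired_score(toy_network, toy_matrix_c112)
        assert [r.cost for r in rows] == [1, 1, 1]
        assert s == 3

    def test_best_display_tree_and_cost(self, toy_network, toy_matrix_c112):
        tau, cost, _ = best_display_tree(toy_network, toy_matrix_c112)
        assert cost == 4
        assert frozenset({"A", "B"}) in tau.clusters

    def test_penalty_and_verdict(self, toy_network, toy_matrix_c112):
        assert network_penalty(toy_network, toy_matrix_c112) == pytest.approx(1 / 6)
        rep = network_cost(toy_network, toy_matrix_c112)
        assert rep.network == pytest.approx(19 / 6)
        assert rep.verdict == "network"

    def test_unused_edge_gives_infinite_penalty(self, toy_network, toy_matrix_c11):
        rep = network_cost(toy_network, toy_matrix_c11)
        assert math.isinf(rep.penalty)
        assert math.isinf(rep.network)
        assert rep.verdict == "tree"
        assert not all(rep.edge_usage.values())

    def test_tied_totals_break_toward_smaller_penalty(self, toy_network):
        # [c1, c2]: both display trees total 3; chosen tau_min minimizes P
        m = matrix_from_columns(C1, C2)
        _, cost, idx = best_display_tree(toy_network, m)
        assert cost == 3
        pen = network_penalty(toy_network, m)
        trees = enumerate_display_trees(toy_network)
        rows, _ = softwired_score(toy_network, m)
        # both candidates give the same penalty here by symmetry
        assert pen == pytest.approx(1 * 2 / (2 * 6))

    def test_tree_input_penalty_zero(self):
        net = parse_enewick("((A,B),(C,D));")
        m = matrix_from_columns(C1, C2)
        rep = network_cost(net, m)
        assert rep.penalty == 0
        assert rep.verdict == "tree"
        assert rep.network == rep.tree_cost == rep.softwired


class TestEdgeDifference:
    def test_identical_trees(self, toy_network):
        t = enumerate_display_trees(toy_network)[0]
        assert edge_difference(t, t) == 0

    def test_toy_pair_differs_by_two(self, toy_network):
        t1, t2 = enumerate_display_trees(toy_network)
        assert edge_difference(t1, t2) == 2
        assert edge_difference(t2, t1) == 2

    def test_bounded_by_n_minus_2_on_four_leaves(self, rng):
        from softwired.simulate import random_binary_tree

        trees = []
        for seed in range(12):
            r = np.random.default_rng(seed)
            net = random_binary_tree(["A", "B", "C", "D"], r)
            (t,) = enumerate_display_trees(net)
            trees.append(t)
        for a in trees:
            for b in trees:
                assert edge_difference(a, b) <= 2


class TestOrderingSandwich:
    def test_softwired_le_tree_le_hardwired(self, rng):
        """S(N,C) <= best display-tree total <= H(N,C); all equal at r=0."""
        for _ in range(30):
            net, m = random_instance(
                rng, max_leaves=5, max_retics=2, max_chars=6, max_states=3
            )
            rep = network_cost(net, m)
            hw = hardwired_score(net, m).total
            assert rep.softwired <= rep.tree_cost + 1e-9
            assert rep.tree_cost <= hw + 1e-9
            if net.n_reticulations == 0:
                assert rep.softwired == rep.tree_cost == hw

    def test_softwired_matches_display_tree_bruteforce(self, rng):
        unit = CostMatrix.unit()
        for _ in range(20):
            net, m = random_instance(
                rng, max_leaves=5, max_retics=2, max_chars=5, max_states=3
            )
            rows, s = softwired_score(net, m)
            trees = enumerate_display_trees(net)
            expected = sum(
                min(exhaustive_tree_score(t, j, m, unit).cost for t in trees)
                for j in range(m.n_characters)
            )
            assert s == expected


class TestHomogeneityAndInvariance:
    def test_cost_scaling_scales_all_components(self, toy_network, toy_matrix_c112):
        rep1 = network_cost(toy_network, toy_matrix_c112)
        scaled = CostMatrix(["0", "1"], {("0", "1"): 3.0, ("1", "0"): 3.0})
        rep3 = network_cost(toy_network, toy_matrix_c112, scaled)
        assert rep3.softwired == pytest.approx(3 * rep1.softwired)
        assert rep3.tree_cost == pytest.approx(3 * rep1.tree_cost)
        assert rep3.penalty == pytest.approx(3 * rep1.penalty)

    def test_duplicating_characters_doubles_s_and_p(self, toy_network, toy_matrix_c112):
        m = toy_matrix_c112
        doubled = CharacterMatrix(m.taxa, m.columns + m.columns)
        rep1 = network_cost(toy_network, m)
        rep2 = network_cost(toy_network, doubled)
        assert rep2.softwired == pytest.approx(2 * rep1.softwired)
        assert rep2.penalty == pytest.approx(2 * rep1.penalty)

    def test_verdict_invariant_under_permutations(self, toy_network, toy_matrix_c112):
        m = toy_matrix_c112
        base = network_cost(toy_network, m)
        perm_taxa = CharacterMatrix(tuple(reversed(m.taxa)), m.columns)
        perm_chars = CharacterMatrix(m.taxa, tuple(reversed(m.columns)))
        for variant in (perm_taxa, perm_chars):
            rep = network_cost(toy_network, variant)
            assert rep.verdict == base.verdict
            assert rep.network == pytest.approx(base.network)

    def test_penalty_nonnegative_on_random_instances(self, rng):
        for _ in range(25):
            net, m = random_instance(rng, max_leaves=6, max_retics=2, max_chars=8)
            rep = network_cost(net, m)
            assert rep.penalty >= 0
            if math.isfinite(rep.penalty):
                assert rep.network == pytest.approx(rep.softwired + rep.penalty)
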