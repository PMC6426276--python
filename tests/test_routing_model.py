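"""Biased strategies, the shortest-path limit, and the absorbing chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import routewalk as rw

from conftest import random_connected_net


def two_neighbor_net():
    """Node 0 linked to 1 and 2; 1 reaches target 3 directly, 2 via 4, 5.

    All edges have weight e^-1 (unit distance), so d_01 = d_02 = 1,
    g(1, 3) = 1, g(2, 3) = 3.
    """
    w = math.exp(-1)
    mat = np.zeros((6, 6))
    for i, j in [(0, 1), (0, 2), (1, 3), (2, 4), (4, 5), (5, 3)]:
        mat[i, j] = mat[j, i] = w
    return rw.WeightedNetwork.from_normalized(mat)


class TestBuildStrategy:
    def test_lambda_zero_is_weight_over_strength(self, toy):
        net, dg = toy
        strat = rw.build_strategy(net, dg, 0.0, target=7)
        expected = net.norm_weights / net.strengths[:, None]
        for i in range(net.n_nodes):
            if i != 7:
                assert np.allclose(strat.trans[i], expected[i], atol=1e-12)

    def test_lambda_zero_target_independent(self, toy):
        net, dg = toy
        a = rw.build_strategy(net, dg, 0.0, target=0)
        b = rw.build_strategy(net, dg, 0.0, target=7)
        rows = [i for i in range(net.n_nodes) if i not in (0, 7)]
        assert np.allclose(a.trans[rows], b.trans[rows], atol=1e-12)

    def test_lambda_one_two_neighbor_example(self):
        """d_0j = d_0k = 1, g_jt = 1, g_kt = 3 → P(j) = 1/(1+e^-2)."""
        net = two_neighbor_net()
        dg = rw.prepare(net)
        strat = rw.build_strategy(net, dg, 1.0, target=3)
        assert strat.trans[0, 1] == pytest.approx(1 / (1 + math.exp(-2)), abs=1e-5)
        assert strat.trans[0, 2] == pytest.approx(0.11920, abs=1e-5)

    def test_negative_lambda_rejected(self, path3):
        net, dg = path3
        with pytest.raises(rw.RoutingModelError):
            rw.build_strategy(net, dg, -0.5, 0)

    def test_infinite_lambda_rejected_by_finite_limb(self, path3):
        net, dg = path3
        with pytest.raises(rw.RoutingModelError):
            rw.build_strategy(net, dg, math.inf, 0)

    @settings(max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10_000), lam=st.floats(0.0, 60.0))
    def test_rows_stochastic_and_support_exact(self, seed, lam):
        """Rows sum to 1 to 1e-12; finite-λ support equals the edge set."""
        rng = np.random.default_rng(seed)
        net = random_connected_net(7, 0.45, rng)
        dg = rw.prepare(net)
        target = int(rng.integers(0, 7))
        strat = rw.build_strategy(net, dg, lam, target)
        assert np.allclose(strat.trans.sum(axis=1), 1.0, atol=1e-12)
        for i in range(7):
            if i != target:
                assert ((strat.trans[i] > 0) == (net.norm_weights[i] > 0)).all()
        assert strat.trans[target, target] == 1.0


class TestShortestPathLimit:
    def test_unique_path_deterministic(self, path3):
        net, dg = path3
        strat = rw.shortest_path_limit_strategy(net, dg, target=2)
        assert strat.trans[0, 1] == 1.0
        assert strat.trans[1, 2] == 1.0

    def test_degenerate_tie_weighted_by_edge_distance(self):
        """Two tied shortest-path edges with d=1 and d=2 split e^-1 : e^-2."""
        # 0 connects to 1 (d=1) and 2 (d=2); 1 -> t has d=3, 2 -> t has d=2,
        # so both routes to t have length 4.
        mat = np.zeros((4, 4))
        mat[0, 1] = mat[1, 0] = math.exp(-1)
        mat[0, 2] = mat[2, 0] = math.exp(-2)
        mat[1, 3] = mat[3, 1] = math.exp(-3)
        mat[2, 3] = mat[3, 2] = math.exp(-2)
        net = rw.WeightedNetwork.from_normalized(mat)
        dg = rw.prepare(net)
        strat = rw.shortest_path_limit_strategy(net, dg, target=3)
        denom = math.exp(-1) + math.exp(-2)
        assert strat.trans[0, 1] == pytest.approx(math.exp(-1) / denom, abs=1e-4)
        assert strat.trans[0, 1] == pytest.approx(0.7311, abs=1e-4)

    def test_uniform_over_equal_distance_ties(self):
        """All admissible edges at equal distance get uniform mass."""
        w = math.exp(-1)
        mat = np.zeros((5, 5))
        for j in (1, 2, 3):  # three parallel 2-hop routes 0 -> j -> 4
            mat[0, j] = mat[j, 0] = w
            mat[j, 4] = mat[4, j] = w
        net = rw.WeightedNetwork.from_normalized(mat)
        dg = rw.prepare(net)
        strat = rw.shortest_path_limit_strategy(net, dg, target=4)
        assert np.allclose(strat.trans[0, 1:4], 1 / 3, atol=1e-12)

    def test_finite_lambda_converges_to_limit(self):
        """λ = 50 matches the symbolic limit to 1e-6 on non-degenerate graphs.

        Fixtures are chosen so competing path lengths differ by ≥ 0.4 nats
        (trees, and a two-route graph with a length gap of 2), so the
        sub-optimal mass at λ = 50 is below e^-20.
        """
        nets = [
            rw.canonical_graph("path", 5, weight=0.45),
            rw.canonical_graph("star", 9, weight=0.6),
            two_neighbor_net(),
        ]
        for net in nets:
            dg = rw.prepare(net)
            for target in range(net.n_nodes):
                fin = rw.build_strategy(net, dg, 50.0, target)
                lim = rw.shortest_path_limit_strategy(net, dg, target)
                assert np.allclose(fin.trans, lim.trans, atol=1e-6)


class TestReferenceStrategy:
    def test_equals_lambda_zero(self, toy):
        net, dg = toy
        ref = rw.reference_strategy(net, 3)
        strat = rw.build_strategy(net, dg, 0.0, 3)
        assert np.allclose(ref.trans, strat.trans, atol=1e-12)

    def test_rows_proportional_to_weights(self, toy):
        net, _ = toy
        ref = rw.reference_strategy(net, 5)
        i = 0
        assert np.allclose(
            ref.trans[i], net.norm_weights[i] / net.strengths[i], atol=1e-14
        )

    def test_targets_differ_only_in_absorbing_row(self, toy):
        net, _ = toy
        a = rw.reference_strategy(net, 1)
        b = rw.reference_strategy(net, 6)
        rows = [i for i in range(net.n_nodes) if i not in (1, 6)]
        assert np.array_equal(a.trans[rows], b.trans[rows])


class TestFundamentalMatrix:
    def test_path3_visit_counts(self, path3):
        net, dg = path3
        chain = rw.fundamental_matrix(rw.build_strategy(net, dg, 0.0, 2))
        assert chain.visits[0, 0] == pytest.approx(2.0)
        assert chain.visits[0, 1] == pytest.approx(2.0)
        assert chain.visits[1, 0] == pytest.approx(1.0)
        assert chain.visits[1, 1] == pytest.approx(2.0)

    def test_deterministic_single_pass(self, path3):
        net, dg = path3
        chain = rw.fundamental_matrix(rw.shortest_path_limit_strategy(net, dg, 2))
        assert chain.visits[0, 0] == pytest.approx(1.0)
        assert chain.visits[0, 1] == pytest.approx(1.0)

    def test_diagonal_at_least_one(self, toy):
        net, dg = toy
        for lam in (0.0, 1.0):
            chain = rw.fundamental_matrix(rw.build_strategy(net, dg, lam, 4))
            diag = np.diag(chain.visits)
            assert all(diag[i] >= 1.0 - 1e-12 for i in range(8) if i != 4)

    def test_matches_truncated_expectation(self):
        """Visits agree with probability-weighted enumeration of short walks.

        On a 4-node graph, iterating p_{s+1} = p_s Q for 60 steps accumulates
        the expected occupation; the residual mass bounds the truncation error.
        """
        rng = np.random.default_rng(5)
        net = random_connected_net(4, 0.7, rng)
        dg = rw.prepare(net)
        strat = rw.build_strategy(net, dg, 0.7, target=3)
        chain = rw.fundamental_matrix(strat)
        keep = [0, 1, 2]
        Q = strat.trans[np.ix_(keep, keep)]
        for src in range(3):
            p = np.zeros(3)
            p[src] = 1.0
            acc = p.copy()
            for _ in range(60):
                p = p @ Q
                acc += p
            residual = p.sum()
            got = chain.visits[src, keep]
            assert np.all(np.abs(acc - got) <= residual * 100 + 1e-9)

    def test_singular_chain_raises(self, path3):
        net, dg = path3
        strat = rw.shortest_path_limit_strategy(net, dg, 2)
        # reverse the flow at node 1 so target 2 becomes unreachable from 0, 1
        strat.trans[1] = 0.0
        strat.trans[1, 0] = 1.0
        strat.trans[0] = 0.0
        strat.trans[0, 1] = 1.0
        with pytest.raises(rw.AbsorptionError):
            rw.fundamental_matrix(strat)


def test_write_strategy_round_trip(tmp_path, path3):
    net, dg = path3
    strat = rw.build_strategy(net, dg, 1.0, 2)
    out = tmp_path / "strategy.csv"
    rw.write_strategy(strat, out)
    back = np.loadtxt(out, delimiter=",")
    assert np.allclose(back, strat.trans, rtol=1e-12)


class TestSimulateWalk:
    def test_deterministic_strategy_every_seed(self, path3):
        net, dg = path3
        strat = rw.shortest_path_limit_strategy(net, dg, 2)
        for seed in (0, 1, 99):
            rec = rw.simulate_walk(strat, 0, seed)
            assert rec.nodes == [0, 1, 2]
            assert rec.distance == pytest.approx(2.0)
            assert not rec.truncated

    def test_source_is_target(self, path3):
        net, dg = path3
        strat = rw.reference_strategy(net, 1)
        rec = rw.simulate_walk(strat, 1, 0)
        assert rec.nodes == [] and rec.distance == 0.0

    def test_same_seed_same_walk(self, toy):
        net, dg = toy
        strat = rw.build_strategy(net, dg, 0.3, 6)
        a = rw.simulate_walk(strat, 0, 42)
        b = rw.simulate_walk(strat, 0, 42)
        assert a.nodes == b.nodes and a.distance == b.distance

    def test_truncation_flagged(self, path3):
        net, dg = path3
        strat = rw.reference_strategy(net, 2)
        rec = rw.simulate_walk(strat, 0, 0, max_steps=1)
        assert rec.truncated

    def test_mean_distance_matches_mfpt(self, path3):
        """λ=0 mean walk distance A→C approaches the closed-form value 4."""
        net, dg = path3
        strat = rw.build_strategy(net, dg, 0.0, 2)
        mean, se, visits, _ = rw.simulate_walks(
            strat, 0, 20_000, np.random.default_rng(1)
        )
        assert abs(mean - 4.0) < 3 * se
        assert abs(visits[0] - 2.0) < 0.1
        assert abs(visits[1] - 2.0) < 0.1
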