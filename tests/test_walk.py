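"""Transition matrices, the restart walk, and Markov-chain identities."""

import math

import networkx as nx
import numpy as np
import pytest

from metnetwalk import (
    WMAN,
    fundamental_matrix,
    rank_metabolites,
    rwr,
    rwr_closed_form,
    stationary_distribution,
    transition_matrix,
)
from metnetwalk.walk import RWRResult
from conftest import random_connected_wman


def _wman_from_edges(edges):
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    return WMAN(graph=g)


@pytest.fixture
def pair():
    return _wman_from_edges([("a", "b", 0.8)])


@pytest.fixture
def star():
    return _wman_from_edges([("c", "l1", 1.0), ("c", "l2", 1.0), ("c", "l3", 1.0)])


class TestTransitionMatrix:
    def test_single_edge_weight_cancels(self, pair):
        for orientation in ("column", "row"):
            tm = transition_matrix(pair, orientation=orientation)
            np.testing.assert_allclose(tm.values, [[0, 1], [1, 0]])

    def test_star_column_leaf_sends_all_mass_to_center(self, star):
        tm = transition_matrix(star, orientation="column")
        i_c = tm.node_ids.index("c")
        i_l1 = tm.node_ids.index("l1")
        assert tm.values[i_c, i_l1] == 1.0
        np.testing.assert_allclose(tm.values.sum(axis=0), 1.0)

    def test_weighted_triangle_per_column_division(self):
        net = _wman_from_edges([("a", "b", 0.8), ("b", "c", 0.9), ("a", "c", 1.0)])
        tm = transition_matrix(net, orientation="column")
        np.testing.assert_allclose(tm.values.sum(axis=0), 1.0, atol=1e-14)
        # independent per-column normalization of the adjacency
        adj = np.array([[0, 0.8, 1.0], [0.8, 0, 0.9], [1.0, 0.9, 0]])
        np.testing.assert_allclose(tm.values, adj / adj.sum(axis=0), atol=1e-14)

    def test_row_and_column_are_transposes(self, star):
        col = transition_matrix(star, orientation="column").values
        row = transition_matrix(star, orientation="row").values
        np.testing.assert_allclose(col, row.T, atol=1e-14)

    def test_bad_orientation(self, pair):
        with pytest.raises(ValueError):
            transition_matrix(pair, orientation="diag")


class TestRWR:
    def test_two_node_hand_solution(self, pair):
        # P = 0.15 A P + 0.85 P0 with A = [[0,1],[1,0]], P0 = (1, 0):
        # P_a = 0.85 / (1 - 0.15^2) ~ 0.86957
        res = rwr(pair, seeds={"a"}, gamma=0.85)
        assert res.converged
        assert res.score("a") == pytest.approx(0.85 / 0.9775, abs=1e-8)
        assert res.score("b") == pytest.approx(0.1275 / 0.9775, abs=1e-8)

    def test_cycle_all_seeds_uniform(self):
        n = 6
        net = _wman_from_edges(
            [(f"v{i}", f"v{(i + 1) % n}", 1.0) for i in range(n)]
        )
        res = rwr(net, seeds=set(net.nodes), gamma=0.85)
        np.testing.assert_allclose(res.probabilities, 1 / n, atol=1e-9)

    def test_high_gamma_limit_returns_seed_vector(self, star):
        res = rwr(star, seeds={"l1"}, gamma=0.999)
        assert res.score("l1") == pytest.approx(1.0, abs=2e-3)

    def test_probability_conservation_every_iteration(self, star):
        # truncate the iteration at every step count and check mass is 1
        for k in range(1, 12):
            res = rwr(star, seeds={"c"}, gamma=0.85, tolerance=1e-300, max_iter=k)
            assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_iterations_within_contraction_bound(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            net = random_connected_wman(rng, max_nodes=30)
            res = rwr(net, seeds={net.nodes[0]}, gamma=0.85, tolerance=1e-10)
            assert res.converged
            bound = math.log(1e-10) / math.log(1 - 0.85)
            assert res.iterations <= math.ceil(bound) + 1

    def test_mass_zero_off_seed_component(self):
        net = _wman_from_edges([("a", "b", 1.0), ("x", "y", 1.0)])
        res = rwr(net, seeds={"a"}, gamma=0.85)
        assert res.score("x") == 0.0
        assert res.score("y") == 0.0

    def test_unknown_seed_rejected(self, pair):
        with pytest.raises(ValueError, match="seed"):
            rwr(pair, seeds={"zzz"})
        with pytest.raises(ValueError):
            rwr(pair, seeds=set())

    def test_non_convergence_flagged(self, star, caplog):
        with caplog.at_level("WARNING"):
            res = rwr(star, seeds={"c"}, tolerance=1e-15, max_iter=2)
        assert not res.converged
        assert any("converge" in r.message for r in caplog.records)


class TestClosedForm:
    def test_single_node_impossible_but_pair_matches(self, pair):
        p = rwr_closed_form(pair, seeds={"a"}, gamma=0.85)
        np.testing.assert_allclose(
            p, [0.85 / 0.9775, 0.1275 / 0.9775], atol=1e-12
        )

    def test_matches_iteration_on_random_networks(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            net = random_connected_wman(rng, max_nodes=50)
            seeds = set(
                rng.choice(net.nodes, size=int(rng.integers(1, len(net.nodes) + 1)),
                           replace=False)
            )
            it = rwr(net, seeds, gamma=0.85, tolerance=1e-12).probabilities
            cf = rwr_closed_form(net, seeds, gamma=0.85)
            assert np.abs(it - cf).max() < 1e-8


class TestStationaryDistribution:
    def test_single_edge(self, pair):
        np.testing.assert_allclose(stationary_distribution(pair), [0.5, 0.5])

    def test_star_degrees(self, star):
        pi = stationary_distribution(star)
        nodes = star.nodes
        expected = {"c": 3 / 6, "l1": 1 / 6, "l2": 1 / 6, "l3": 1 / 6}
        np.testing.assert_allclose(pi, [expected[n] for n in nodes])

    def test_fixed_point_of_row_chain(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            net = random_connected_wman(rng, max_nodes=40)
            pi = stationary_distribution(net)
            p_row = transition_matrix(net, orientation="row").values
            assert np.abs(pi @ p_row - pi).max() < 1e-12


class TestFundamentalMatrix:
    def test_standard_rows_sum_to_one(self, pair):
        z = fundamental_matrix(pair, sign_convention="standard_plus")
        np.testing.assert_allclose(z.sum(axis=1), 1.0, atol=1e-10)

    def test_inverse_identity(self, star):
        z = fundamental_matrix(star)
        p = transition_matrix(star, orientation="row").values
        pi = stationary_distribution(star)
        w = np.tile(pi, (len(pi), 1))
        np.testing.assert_allclose(z @ (np.eye(len(pi)) - p + w), np.eye(len(pi)),
                                   atol=1e-10)

    def test_conventions_differ_on_two_node_chain(self, pair):
        z_plus = fundamental_matrix(pair, sign_convention="standard_plus")
        z_minus = fundamental_matrix(pair, sign_convention="as_printed_minus")
        # direct 2x2 inversions: P = [[0,1],[1,0]], pi = (1/2, 1/2)
        m = np.array([[1.0, -1.0], [-1.0, 1.0]])
        w = np.full((2, 2), 0.5)
        np.testing.assert_allclose(z_plus, np.linalg.inv(m + w), atol=1e-12)
        np.testing.assert_allclose(z_minus, np.linalg.inv(m - w), atol=1e-12)
        assert not np.allclose(z_plus, z_minus)

    def test_unknown_convention(self, pair):
        with pytest.raises(ValueError):
            fundamental_matrix(pair, sign_convention="plus")


class TestRanking:
    def _result(self, scores):
        ids = tuple(sorted(scores))
        import numpy as np

        return RWRResult(
            node_ids=ids,
            probabilities=np.array([scores[i] for i in ids]),
            iterations=1,
            converged=True,
            gamma=0.85,
            tolerance=1e-10,
        )

    def test_distinct_scores_strictly_decreasing(self):
        ranked = rank_metabolites(self._result({"a": 0.5, "b": 0.3, "c": 0.2}))
        assert [r[0] for r in ranked] == ["a", "b", "c"]
        assert [r[2] for r in ranked] == [1, 2, 3]

    def test_exclude_all_gives_empty(self):
        ranked = rank_metabolites(self._result({"a": 0.5}), exclude={"a"})
        assert ranked == []

    def test_competition_ranking_on_ties(self):
        ranked = rank_metabolites(
            self._result({"a": 0.4, "b": 0.4, "c": 0.2})
        )
        assert ranked == [("a", 0.4, 1), ("b", 0.4, 1), ("c", 0.2, 3)]
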