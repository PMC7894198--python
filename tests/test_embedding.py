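"""Biased second-order walks: search bias, transition law, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcembed.connectivity import WeightedGraph
from fcembed.embedding import (Node2vecParams, _step_batch, search_bias,
                               simulate_walks, transition_distribution)
from conftest import random_weighted_graph


class TestSearchBias:
    def test_distance_one_is_unity_for_any_pq(self):
        for p, q in [(0.1, 1.6), (2.0, 0.3), (1.0, 1.0)]:
            assert search_bias(1, p, q) == 1.0

    def test_return_and_outward_cases(self):
        assert search_bias(0, 0.1, 1.6) == pytest.approx(10.0)
        assert search_bias(2, 0.1, 1.6) == pytest.approx(0.625)

    def test_contract_violation_outside_0_1_2(self):
        with pytest.raises(ValueError):
            search_bias(3, 1.0, 1.0)


class TestTransitionDistribution:
    def test_triangle_hand_enumeration(self, triangle_graph):
        # from v=1 after t=0 with p=0.5, q=1: unnormalized (t: 2, a: 1)
        nbrs, probs = transition_distribution(triangle_graph, t=0, v=1, p=0.5, q=1.0)
        lookup = dict(zip(nbrs.tolist(), probs.tolist()))
        assert lookup[0] == pytest.approx(2 / 3)
        assert lookup[2] == pytest.approx(1 / 3)

    def test_p_q_unity_is_uniform(self, triangle_graph):
        nbrs, probs = transition_distribution(triangle_graph, t=0, v=1, p=1.0, q=1.0)
        assert np.allclose(probs, 1 / nbrs.size)

    def test_first_step_uses_static_weights(self):
        w = np.array([[0.0, 3.0, 1.0], [3.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        g = WeightedGraph(w, list("abc"), "absolute")
        nbrs, probs = transition_distribution(g, t=None, v=0, p=0.1, q=1.6)
        assert np.allclose(probs, [0.75, 0.25])

    def test_neighborless_node_yields_empty(self):
        w = np.zeros((2, 2))
        w[0, 1] = 0.0
        g = WeightedGraph(w, list("ab"), "clip")
        nbrs, probs = transition_distribution(g, None, 0)
        assert nbrs.size == 0 and probs.size == 0

    def test_nonadjacent_previous_node_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        g = WeightedGraph(w, list("abc"), "absolute")
        with pytest.raises(ValueError, match="not adjacent"):
            transition_distribution(g, t=2, v=0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 12))
    def test_probabilities_sum_to_one_on_random_graphs(self, seed, n):
        g = random_weighted_graph(np.random.default_rng(seed), n)
        rng = np.random.default_rng(seed + 1)
        v = int(rng.integers(n))
        nbrs = g.neighbors(v)
        t = int(nbrs[rng.integers(nbrs.size)])
        _, probs = transition_distribution(g, t, v, p=0.3, q=2.0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        _, probs0 = transition_distribution(g, None, v, p=0.3, q=2.0)
        assert probs0.sum() == pytest.approx(1.0, abs=1e-12)


class TestSimulateWalks:
    def test_two_node_path_alternates(self, path_graph_2):
        params = Node2vecParams(walk_length=4, num_walks=3, dim=2, seed=5)
        corpus = simulate_walks(path_graph_2, params)
        for walk in corpus.walks:
            assert walk in ([0, 1, 0, 1], [1, 0, 1, 0])

    def test_walks_start_at_every_node_num_walks_times(self, triangle_graph):
        params = Node2vecParams(walk_length=5, num_walks=7, dim=2, seed=1)
        corpus = simulate_walks(triangle_graph, params)
        starts = [w[0] for w in corpus.walks]
        assert len(corpus) == 3 * 7
        assert all(starts.count(v) == 7 for v in range(3))

    def test_never_traverses_a_non_edge(self, rng):
        g = random_weighted_graph(np.random.default_rng(42), 9, edge_prob=0.3)
        params = Node2vecParams(walk_length=8, num_walks=10, dim=2, seed=9)
        corpus = simulate_walks(g, params)
        for walk in corpus.walks:
            for a, b in zip(walk[:-1], walk[1:]):
                assert g.weights[a, b] > 0

    def test_reproducible_from_seed(self, triangle_graph):
        params = Node2vecParams(walk_length=6, num_walks=4, dim=2, seed=13)
        c1 = simulate_walks(triangle_graph, params)
        c2 = simulate_walks(triangle_graph, params)
        assert c1.walks == c2.walks

    def test_corpus_size_at_study_scale(self):
        rng = np.random.default_rng(0)
        g = random_weighted_graph(rng, 116, edge_prob=0.9)
        params = Node2vecParams(walk_length=3, num_walks=200, dim=2, seed=2)
        corpus = simulate_walks(g, params)
        assert len(corpus) == 23_200

    def test_dangling_node_emits_single_node_walk(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        g = WeightedGraph(w, list("abc"), "clip")
        params = Node2vecParams(walk_length=5, num_walks=2, dim=2, seed=3)
        corpus = simulate_walks(g, params)
        solo = [wk for wk in corpus.walks if wk[0] == 2]
        assert all(wk == [2] for wk in solo) and len(solo) == 2


class TestMonteCarloAgainstAnalytic:
    def test_first_step_frequencies_match_transition_distribution(self):
        """Empirical (t, v) step frequencies vs the analytic law, 1e5 draws."""
        g = random_weighted_graph(np.random.default_rng(7), 6, edge_prob=0.7)
        p, q = 0.1, 1.6
        v = 0
        t = int(g.neighbors(v)[0])
        n = 100_000
        rng = np.random.default_rng(123)
        draws = _step_batch(g, np.full(n, t), np.full(n, v), rng, p, q)
        nbrs, probs = transition_distribution(g, t, v, p, q)
        counts = np.bincount(draws, minlength=6)
        for x, pi in zip(nbrs, probs):
            se = np.sqrt(pi * (1 - pi) / n)
            assert abs(counts[x] / n - pi) < 3 * se + 1e-12
        # non-neighbors are never sampled
        assert counts[np.setdiff1d(np.arange(6), nbrs)].sum() == 0
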