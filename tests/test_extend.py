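"""Association probabilities, conductance and the greedy extension loop."""

import math

import numpy as np
import pytest

from netquery import (
    SeedState,
    association_probability,
    best_candidate,
    conductance,
    entry_probability,
    extend,
    extend_step,
    score_frontier,
    seed_stationary,
)

from conftest import (
    brute_force_conductance,
    brute_force_p2,
    net,
    random_connected_graph,
)


class TestSeedStationary:
    def test_triangle_uniform(self, triangle):
        seed = SeedState(triangle, {0, 1, 2})
        assert list(seed_stationary(seed).values()) == pytest.approx([1/3] * 3)

    def test_path_degree_weighted(self, path3):
        seed = SeedState(path3, {0, 1, 2})
        pi = seed_stationary(seed)
        assert pi[path3.index("a")] == pytest.approx(0.25)
        assert pi[path3.index("b")] == pytest.approx(0.5)
        assert pi[path3.index("c")] == pytest.approx(0.25)

    def test_single_node_seed(self, triangle):
        seed = SeedState(triangle, {0})
        assert seed_stationary(seed) == {0: 1.0}


class TestEntryAndAssociation:
    def test_single_term_entry(self):
        # seed = path a-b-c (pi_s = 1/4,1/2,1/4); v adjacent only to b;
        # b also has a 4th target edge, so d_T(b)=4 and P1 = (1/2)/4
        t = net(("a", "b"), ("b", "c"), ("b", "v"), ("b", "d"))
        seed = SeedState(t, {t.index("a"), t.index("b"), t.index("c")})
        assert entry_probability(seed, t, t.index("v")) == pytest.approx(1/8)

    def test_no_adjacency_gives_zero_entry(self):
        t = net(("a", "b"), ("c", "v"), ("b", "c"))
        seed = SeedState(t, {t.index("a"), t.index("b")})
        assert entry_probability(seed, t, t.index("v")) == 0.0

    def test_triangle_fully_adjacent_neighbor(self, ):
        # v adjacent to every node of a triangle seed; each seed node d_T=3
        t = net(("a", "b"), ("b", "c"), ("a", "c"),
                ("v", "a"), ("v", "b"), ("v", "c"))
        seed = SeedState(t, {t.index("a"), t.index("b"), t.index("c")})
        v = t.index("v")
        assert entry_probability(seed, t, v) == pytest.approx(1/3)
        # r = d_T(v) = 3, so P2 attains its upper bound P1
        assert association_probability(seed, t, v) == pytest.approx(1/3)

    def test_p2_is_p1_times_return_ratio(self):
        # P1 = 1/8 fixture; v has r=2 edges into seed, d_T(v)=4
        t = net(("a", "b"), ("b", "c"), ("b", "d"),
                ("v", "b"), ("v", "x"), ("v", "y"))
        seed = SeedState(t, {t.index(k) for k in "abc"})
        v = t.index("v")
        p1 = entry_probability(seed, t, v)
        assert association_probability(seed, t, v) == pytest.approx(p1 * 1 / 3)

    @pytest.mark.parametrize("trial", range(12))
    def test_two_hop_brute_force_equivalence(self, trial):
        """P2 equals the enumerated probability of leaving the seed to v_n
        and stepping straight back in."""
        rng = np.random.default_rng(300 + trial)
        t = random_connected_graph(rng, n_max=10, n_min=4)
        start = int(rng.integers(t.n))
        seed_nodes = {start} | set(
            int(v) for v in t.neighbors(start)[: int(rng.integers(1, 3))]
        )
        seed = SeedState(t, seed_nodes)
        for v in sorted(seed.frontier):
            expected = brute_force_p2(t, seed_nodes, v)
            assert association_probability(seed, t, v) == pytest.approx(expected)

    def test_p2_bounded_by_p1(self):
        rng = np.random.default_rng(17)
        t = random_connected_graph(rng, n_max=10, n_min=5)
        seed = SeedState(t, {0, int(t.neighbors(0)[0])})
        for v in sorted(seed.frontier):
            p1 = entry_probability(seed, t, v)
            p2 = association_probability(seed, t, v)
            assert 0 <= p2 <= p1 <= 1


class TestConductance:
    def test_two_k4_bridge_is_one_thirteenth(self, two_k4_bridge):
        k4 = {two_k4_bridge.index(f"l{i}") for i in range(4)}
        assert conductance(two_k4_bridge, k4) == pytest.approx(1 / 13)

    def test_whole_graph_is_infinite(self, triangle):
        assert math.isinf(conductance(triangle, {0, 1, 2}))

    def test_single_node_is_one(self, two_k4_bridge):
        assert conductance(two_k4_bridge, {two_k4_bridge.index("l1")}) == 1.0

    @pytest.mark.parametrize("trial", range(15))
    def test_matches_brute_force_counting(self, trial):
        rng = np.random.default_rng(400 + trial)
        t = random_connected_graph(rng, n_max=12, n_min=4)
        k = int(rng.integers(1, t.n))
        subset = set(int(v) for v in rng.choice(t.n, size=k, replace=False))
        assert conductance(t, subset) == pytest.approx(
            brute_force_conductance(t, subset)
        )


class TestExtension:
    @pytest.fixture
    def module_in_background(self):
        """Dense 4-clique hanging off a long path."""
        pairs = [("m1", "m2"), ("m1", "m3"), ("m1", "m4"), ("m2", "m3"),
                 ("m2", "m4"), ("m3", "m4"), ("m4", "p1"), ("p1", "p2"),
                 ("p2", "p3"), ("p3", "p4"), ("p4", "p5")]
        return net(*pairs)

    def test_forced_single_candidate_added(self, module_in_background):
        t = module_in_background
        seed = SeedState(t, {t.index("m1"), t.index("m2"), t.index("m3")})
        updated = extend_step(seed, t)
        assert updated is not None and t.index("m4") in updated.nodes

    def test_equal_conductance_tie_prefers_higher_p2(self):
        # two candidates u, v each with one edge into the 2-node seed and
        # one edge out; v's anchor has higher stationary mass
        t = net(("a", "b"), ("b", "c"), ("a", "u"), ("b", "v"),
                ("u", "x"), ("v", "x"), ("b", "d"))
        seed = SeedState(t, {t.index("a"), t.index("b")})
        ranked = score_frontier(seed, t)
        by_node = {c.node: c.p2 for c in ranked}
        assert by_node[t.index("u")] != by_node[t.index("v")]
        winner = best_candidate(seed, t, K=20)
        phis = {
            c: conductance(t, seed.nodes | {c})
            for c in (t.index("u"), t.index("v"))
        }
        if phis[t.index("u")] == phis[t.index("v")]:
            expected = max(by_node, key=lambda n: (by_node[n], -n))
            assert winner.node == expected

    def test_top_k_screening_excludes_low_p2(self):
        """A node outside the top-K by association probability is never
        conductance-evaluated, even if adding it would win."""
        rng = np.random.default_rng(42)
        t = random_connected_graph(rng, n_max=10, n_min=8)
        start = 0
        seed_nodes = {start} | {int(t.neighbors(start)[0])}
        seed = SeedState(t, set(seed_nodes))
        ranked = score_frontier(seed, t)
        if len(ranked) >= 3:
            allowed = {c.node for c in ranked[:2]}
            winner = best_candidate(seed, t, K=2)
            assert winner.node in allowed

    def test_stop_at_max_size(self, module_in_background):
        t = module_in_background
        nodes = {t.index("m1"), t.index("m2"), t.index("m3"), t.index("m4")}
        seed = SeedState(t, set(nodes))
        extend(seed, t, max_size=4)
        assert seed.nodes == nodes
        assert seed.history[-1]["stop"] == "size_limit"

    def test_stop_when_no_conductance_drop(self, module_in_background):
        t = module_in_background
        nodes = {t.index("m1"), t.index("m2"), t.index("m3"), t.index("m4")}
        seed = SeedState(t, set(nodes))
        extend(seed, t, max_size=100, min_rel_drop=0.10)
        # adding path nodes only raises the cut; seed must not grow
        assert seed.nodes == nodes
        assert seed.history[-1]["stop"] == "conductance"

    def test_monotone_growth_and_strict_drops(self):
        rng = np.random.default_rng(9)
        t = random_connected_graph(rng, n_max=14, n_min=10)
        seed = SeedState(t, {0})
        phi = seed.conductance
        extend(seed, t, max_size=8, min_rel_drop=0.10)
        for event in seed.history:
            if "added_node" in event:
                new_phi = event["conductance_after"]
                if math.isfinite(phi):
                    assert new_phi <= phi * 0.9 + 1e-12
                phi = new_phi

    def test_deterministic_trace(self):
        rng = np.random.default_rng(13)
        t = random_connected_graph(rng, n_max=12, n_min=8)
        traces = []
        for _ in range(2):
            seed = SeedState(t, {0})
            extend(seed, t, max_size=6)
            traces.append(seed.history)
        assert traces[0] == traces[1]
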