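"""Integrated-walk construction, stationary distribution and flow matrix."""

import numpy as np
import pytest
import scipy.sparse as sp

from netquery import (
    build_walk,
    combine,
    correspondence,
    cross_transitions,
    intra_transition,
    power_stationary,
    stationary,
)
from netquery.correspondence import ConvergenceError
from netquery.io import SimilarityTable

from conftest import dense_stationary, net, random_integrated_instance, sim_from_dense


class TestIntraTransition:
    def test_triangle_rows_split_between_neighbors(self, triangle):
        P = intra_transition(triangle).toarray()
        for i in range(3):
            assert P[i, i] == 0
            assert sorted(P[i]) == pytest.approx([0, 0.5, 0.5])

    def test_path_normalization(self, path3):
        P = intra_transition(path3).toarray()
        b = path3.index("b")
        assert P[b].tolist() == pytest.approx([0.5, 0, 0.5])
        for end in ("a", "c"):
            row = P[path3.index(end)]
            assert row[b] == 1.0 and row.sum() == 1.0

    def test_star_center_degree_normalization(self):
        star = net(("c", "l1"), ("c", "l2"), ("c", "l3"))
        P = intra_transition(star).toarray()
        assert P[star.index("c")].tolist() == pytest.approx([0, 1 / 3, 1 / 3, 1 / 3])


class TestCrossTransitions:
    def test_single_query_two_targets_equal_scores(self):
        p_qt, p_tq = cross_transitions(sim_from_dense([[2.0, 2.0]]))
        assert p_qt.toarray().tolist() == [[0.5, 0.5]]
        assert p_tq.toarray().tolist() == [[1.0], [1.0]]

    def test_proportional_split(self):
        p_qt, _ = cross_transitions(sim_from_dense([[1.0, 3.0]]))
        assert p_qt.toarray().tolist() == [[0.25, 0.75]]

    def test_target_without_pseudo_edge_gets_zero_row(self):
        _, p_tq = cross_transitions(sim_from_dense([[1.0, 0.0]]))
        assert p_tq.toarray()[1].tolist() == [0.0]


class TestCombine:
    def test_dual_access_node_splits_half_half(self, triangle, path3):
        sim = sim_from_dense(np.ones((3, 3)))
        walk = combine(
            intra_transition(triangle), intra_transition(path3),
            *cross_transitions(sim),
        )
        P = walk.P.toarray()
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        # query node 0: half its mass intra (triangle), half cross
        assert P[0, :3].sum() == pytest.approx(0.5)
        assert P[0, 3:].sum() == pytest.approx(0.5)

    def test_cross_only_node_keeps_cross_row(self):
        # 1 query node, 1 target pair with an edge; query has no intra edges
        q = net(extra=("q1",), *[])
        t = net(("t1", "t2"))
        sim = sim_from_dense([[3.0, 0.0]])
        walk = build_walk(q, t, sim)
        P = walk.P.toarray()
        assert P[0].tolist() == pytest.approx([0, 1.0, 0])

    def test_isolated_node_self_loops(self):
        q = net(("q1", "q2"), extra=("q3",))
        t = net(("t1", "t2"))
        sim = sim_from_dense([[1, 0], [0, 1], [0, 0]])
        walk = build_walk(q, t, sim)
        P = walk.P.toarray()
        i = q.index("q3")
        assert P[i, i] == 1.0 and P[i].sum() == 1.0

    def test_block_structure_preserved(self, triangle):
        sim = sim_from_dense(np.eye(3) * 2.0)
        walk = build_walk(triangle, triangle, sim)
        # intra blocks are the scaled intra transitions
        np.testing.assert_allclose(
            walk.P.toarray()[:3, :3], 0.5 * intra_transition(triangle).toarray()
        )


class TestStationary:
    def test_degree_closed_form_on_intra_walk(self, two_k4_bridge):
        P = intra_transition(two_k4_bridge)
        pi = power_stationary(P).pi
        expected = two_k4_bridge.degrees / two_k4_bridge.degrees.sum()
        np.testing.assert_allclose(pi, expected, atol=1e-8)

    def test_symmetric_integrated_network_uniform(self, triangle):
        walk = build_walk(triangle, triangle, sim_from_dense(np.ones((3, 3))))
        pi = stationary(walk).pi
        np.testing.assert_allclose(pi, 1.0 / 6.0, atol=1e-8)

    def test_matches_dense_eigensolver(self):
        rng = np.random.default_rng(7)
        q, t, sim = random_integrated_instance(rng, n_max=8)
        walk = build_walk(q, t, sim)
        sd = stationary(walk)
        if np.all(sd.pi > 0):  # connected integrated network
            np.testing.assert_allclose(sd.pi, dense_stationary(walk.P), atol=1e-8)
        assert sd.residual <= 1e-10

    def test_disconnected_walk_runs_on_largest_cross_component(self):
        # two separate query-target pairs; the 3-node component wins
        q = net(("q1", "q2"), extra=("q3",))
        t = net(("t1", "t2"), extra=("t3",))
        sim = sim_from_dense([[5, 0, 0], [0, 0, 0], [0, 0, 5]])
        walk = build_walk(q, t, sim)
        pi = stationary(walk).pi
        # component {q1,q2,t1,t2} has 4 nodes; {q3,t3} has 2
        assert pi[q.index("q3")] == 0 and pi[3 + t.index("t3")] == 0
        assert pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_nonconvergence_raises(self, triangle, path3):
        # asymmetric instance: uniform start is far from the fixed point
        walk = build_walk(triangle, path3, sim_from_dense([[1, 0, 0], [0, 2, 0], [0, 0, 3]]))
        with pytest.raises(ConvergenceError):
            power_stationary(walk.P, tol=1e-16, max_iter=1)


class TestCorrespondence:
    def test_two_state_chain_flow_is_one(self):
        q = net(extra=("q1",), *[])
        t = net(extra=("t1",), *[])
        sim = SimilarityTable.from_entries({(0, 0): 5.0}, (1, 1))
        walk = build_walk(q, t, sim)
        pi = stationary(walk).pi
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-10)
        C = correspondence(walk, pi)
        assert C[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_zero_pi_component_has_zero_flow(self):
        q = net(("q1", "q2"), extra=("q3",))
        t = net(("t1", "t2"), extra=("t3",))
        sim = sim_from_dense([[5, 0, 0], [0, 0, 0], [0, 0, 5]])
        walk = build_walk(q, t, sim)
        pi = stationary(walk).pi
        C = correspondence(walk, pi)
        assert C[q.index("q3"), t.index("t3")] == 0.0

    def test_total_flow_equals_block_sums(self):
        rng = np.random.default_rng(21)
        q, t, sim = random_integrated_instance(rng)
        walk = build_walk(q, t, sim)
        pi = stationary(walk).pi
        C = correspondence(walk, pi)
        nq = walk.n_query
        out_q = pi[:nq] @ walk.combined_qt.toarray().sum(axis=1)
        out_t = pi[nq:] @ walk.combined_tq.toarray().sum(axis=1)
        assert C.sum() == pytest.approx(out_q + out_t, abs=1e-12)

    def test_support_is_pseudo_edge_set(self):
        rng = np.random.default_rng(3)
        q, t, sim = random_integrated_instance(rng)
        walk = build_walk(q, t, sim)
        pi = stationary(walk).pi
        C = correspondence(walk, pi)
        if np.all(pi > 0):
            assert set(zip(*C.nonzero())) == set(zip(*sim.matrix.nonzero()))
        else:
            assert set(zip(*C.nonzero())) <= set(zip(*sim.matrix.nonzero()))
        assert (C.data >= 0).all()

    def test_scale_equivariance(self):
        rng = np.random.default_rng(11)
        q, t, sim = random_integrated_instance(rng)
        walk1 = build_walk(q, t, sim)
        walk2 = build_walk(q, t, sim.scale(7.3))
        pi1, pi2 = stationary(walk1).pi, stationary(walk2).pi
        assert abs(walk1.P - walk2.P).max() <= 1e-12
        C1, C2 = correspondence(walk1, pi1), correspondence(walk2, pi2)
        assert abs(C1 - C2).max() <= 1e-12
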