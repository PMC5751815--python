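"""Shared fixtures and independent brute-force oracles.

The oracle helpers here deliberately avoid the code paths they check:
matchings are enumerated over permutations, conductance counts edges one by
one, two-hop association probabilities enumerate walk paths, and stationary
distributions come from a dense eigendecomposition.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp

from netquery import Network, SimilarityTable


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def net(*pairs: tuple[str, str], extra: tuple[str, ...] = ()) -> Network:
    return Network.from_edge_pairs(pairs, extra_nodes=extra)


def sim_from_dense(dense, s_t: float = 0.0) -> SimilarityTable:
    arr = np.asarray(dense, dtype=float)
    entries = {
        (i, j): arr[i, j]
        for i in range(arr.shape[0])
        for j in range(arr.shape[1])
        if arr[i, j] > s_t
    }
    return SimilarityTable.from_entries(entries, arr.shape, s_t=s_t)


def random_connected_graph(
    rng: np.random.Generator, n_max: int = 12, n_min: int = 3,
    require_nonbipartite: bool = False,
) -> Network:
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(0.25, 0.7))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if not nx.is_connected(g) or g.number_of_edges() == 0:
            continue
        if require_nonbipartite and nx.is_bipartite(g):
            continue
        return Network.from_edge_pairs(
            [(f"n{a}", f"n{b}") for a, b in sorted(g.edges())],
            extra_nodes=[f"n{i}" for i in range(n)],
        )


def random_integrated_instance(rng: np.random.Generator, n_max: int = 8):
    """Small (query, target, similarity) triple with a connected
    integrated network."""
    while True:
        q = random_connected_graph(rng, n_max=min(5, n_max), n_min=2)
        t = random_connected_graph(rng, n_max=n_max, n_min=3)
        dense = np.where(
            rng.random((q.n, t.n)) < 0.4, rng.uniform(0.5, 5.0, (q.n, t.n)), 0.0
        )
        if dense.sum() == 0:
            continue
        return q, t, sim_from_dense(dense)


@pytest.fixture
def triangle() -> Network:
    return net(("a", "b"), ("b", "c"), ("a", "c"))


@pytest.fixture
def path3() -> Network:
    return net(("a", "b"), ("b", "c"))


@pytest.fixture
def two_k4_bridge() -> Network:
    """Two 4-cliques joined by a single bridge edge."""
    pairs = []
    left = [f"l{i}" for i in range(4)]
    right = [f"r{i}" for i in range(4)]
    for group in (left, right):
        pairs.extend(itertools.combinations(group, 2))
    pairs.append(("l0", "r0"))
    return Network.from_edge_pairs(pairs)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_matching(W: np.ndarray) -> float:
    """Maximum total weight over all one-to-one partial matchings that use
    only positive-weight pairs, by exhaustive enumeration."""
    nq, nt = W.shape
    best = 0.0
    cols = list(range(nt))
    for k in range(1, min(nq, nt) + 1):
        for rows in itertools.combinations(range(nq), k):
            for perm in itertools.permutations(cols, k):
                total = sum(W[i, j] for i, j in zip(rows, perm))
                if all(W[i, j] > 0 for i, j in zip(rows, perm)):
                    best = max(best, total)
    return best


def brute_force_conductance(network: Network, node_set: set[int]) -> float:
    cut = 0
    for i, j in network.edges:
        if (i in node_set) != (j in node_set):
            cut += 1
    vol = sum(int(network.degrees[i]) for i in node_set)
    denom = min(vol, 2 * network.m - vol)
    return math.inf if denom <= 0 else cut / denom


def brute_force_p2(network: Network, seed_nodes: set[int], v_n: int) -> float:
    """Probability that a walker placed by the seed's internal stationary
    distribution takes one target-network step to v_n and one more step
    back into the seed, enumerated over all 2-step paths."""
    internal = network.induced_edges(seed_nodes)
    deg_s = {i: 0 for i in seed_nodes}
    for a, b in internal:
        deg_s[a] += 1
        deg_s[b] += 1
    tot = sum(deg_s.values())
    if tot == 0:
        pi_s = {i: 1.0 / len(seed_nodes) for i in seed_nodes}
    else:
        pi_s = {i: deg_s[i] / tot for i in seed_nodes}
    prob = 0.0
    for i in seed_nodes:
        for x in network.neighbors(i).tolist():
            if x != v_n:
                continue
            for y in network.neighbors(x).tolist():
                if y in seed_nodes:
                    prob += pi_s[i] / network.degrees[i] / network.degrees[x]
    return prob


def dense_stationary(P: sp.spmatrix) -> np.ndarray:
    """Left eigenvector of eigenvalue 1 via dense eigendecomposition."""
    dense = np.asarray(sp.csr_matrix(P).todense())
    vals, vecs = np.linalg.eig(dense.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v)
    return v / v.sum()
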