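"""Personalized-PageRank pruning of the fully extended seed.

The extended seed plus its immediate target neighborhood form an induced
network whose edges are the seed-internal edges and the seed-to-neighbor
edges (edges between two non-seed neighbors are excluded, so mass can only
reach a neighbor through the seed). A personalized PageRank vector with the
preference spread uniformly over seed nodes ranks all induced-network
nodes; nodes are kept in rank order until half the total mass is
accumulated, and the largest connected piece of the kept set is the final
querying result. Neighbors can out-rank seed members, so the final result
may recruit nodes the extension never added and drop nodes it did.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import Network
from .seed import SeedState

#: above this induced-network size, solve PPR by fixed-point iteration
DIRECT_SOLVE_LIMIT = 2000


def induce_neighborhood(extended: SeedState, target: Network) -> tuple[Network, frozenset[str]]:
    """Induced network on the extended seed and its target neighbors.

    Nodes: seed nodes plus every target neighbor of a seed node. Edges:
    seed-internal edges plus seed-to-neighbor edges only. Returns the
    induced network and the seed node ids within it.
    """
    seed_nodes = sorted(extended.nodes)
    neighbors = sorted(target.neighborhood(seed_nodes))
    ids = [target.node_ids[i] for i in seed_nodes + neighbors]
    seed_set = set(seed_nodes)
    pairs = []
    for i, j in sorted(target.induced_edges(set(seed_nodes) | set(neighbors))):
        if i in seed_set or j in seed_set:  # E_S ∪ E_A; neighbor-neighbor edges excluded
            pairs.append((target.node_ids[i], target.node_ids[j]))
    g_i = Network.from_edge_pairs(pairs, extra_nodes=ids)
    return g_i, frozenset(target.node_ids[i] for i in seed_nodes)


@dataclass(frozen=True)
class PPRSolution:
    r: np.ndarray
    alpha: float
    preference: np.ndarray
    M: sp.csr_matrix

    def residual(self) -> float:
        return float(
            np.abs(self.r - self.alpha * self.preference
                   - (1.0 - self.alpha) * (self.r @ self.M)).sum()
        )


class ConvergenceError(RuntimeError):
    pass


def personalized_pagerank(
    g_i: Network,
    seed_nodes: frozenset[str] | set[str],
    alpha: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 100000,
    method: str = "auto",
) -> PPRSolution:
    """Solve r = alpha·s + (1-alpha)·r·M on the induced network.

    The preference vector s is uniform over the seed nodes and zero
    elsewhere; M is the row-normalized adjacency of the induced network
    (zero-degree rows replaced by self-loops so M stays stochastic). With
    ``method="auto"``, small systems are solved directly and larger ones by
    fixed-point iteration; "direct" and "iterative" force a solver.
    """
    if method not in ("auto", "direct", "iterative"):
        raise ValueError(f"unknown method {method!r}")
    n = g_i.n
    if n == 0:
        raise ValueError("empty induced network")
    seed_idx = sorted(g_i.index(v) for v in seed_nodes)
    if not seed_idx:
        raise ValueError("no seed nodes in induced network")
    s = np.zeros(n)
    s[seed_idx] = 1.0 / len(seed_idx)

    deg = g_i.degrees
    adj = sp.lil_matrix(g_i.adjacency)
    for i in np.where(deg == 0)[0]:
        adj[i, i] = 1.0
    row_sums = np.asarray(adj.sum(axis=1)).ravel()
    M = sp.csr_matrix(sp.diags(1.0 / row_sums) @ adj.tocsr())

    if alpha >= 1.0:
        return PPRSolution(s.copy(), alpha, s, M)

    use_direct = method == "direct" or (method == "auto" and n <= DIRECT_SOLVE_LIMIT)
    if use_direct:
        # r (I - (1-alpha) M) = alpha s  ⇔  (I - (1-alpha) M)^T r^T = alpha s^T
        A = (sp.eye(n) - (1.0 - alpha) * M).T.tocsc()
        r = spla.spsolve(A, alpha * s)
        r = np.asarray(r).ravel()
    else:
        r = s.copy()
        for _ in range(max_iter):
            r_new = alpha * s + (1.0 - alpha) * (r @ M)
            if np.abs(r_new - r).sum() <= tol:
                r = r_new
                break
            r = r_new
        else:
            raise ConvergenceError(
                f"PPR iteration did not reach tol={tol}; residual "
                f"{np.abs(alpha * s + (1 - alpha) * (r @ M) - r).sum():.3e}"
            )
    sol = PPRSolution(r, alpha, s, M)
    if sol.residual() > 10 * max(tol, 1e-12):
        raise ConvergenceError(f"PPR residual {sol.residual():.3e} exceeds tolerance")
    return sol


def prune_by_mass(
    ppr: PPRSolution,
    g_i: Network,
    seed_nodes: frozenset[str] | set[str],
    mass: float = 0.5,
) -> frozenset[str]:
    """Keep the top-ranked nodes until the cumulative PPR mass reaches
    ``mass`` (the crossing node included), then return the largest
    connected component of the kept set within the induced network.

    Ranking ties break seed-members-first, then by node index. Component
    ties break by summed PPR mass, then by lowest node index.
    """
    r = np.asarray(ppr.r, dtype=float)
    total = r.sum()
    if total <= 0:
        raise ValueError("PPR vector has no mass")
    r = r / total
    in_seed = np.array([g_i.node_ids[i] in seed_nodes for i in range(g_i.n)])
    order = sorted(range(g_i.n), key=lambda i: (-r[i], 0 if in_seed[i] else 1, i))
    kept: list[int] = []
    cum = 0.0
    for i in order:
        kept.append(i)
        cum += r[i]
        if cum >= mass:
            break
    comps = g_i.components_of(kept)
    best = max(comps, key=lambda c: (len(c), float(r[sorted(c)].sum()), -min(c)))
    return frozenset(g_i.node_ids[i] for i in best)
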