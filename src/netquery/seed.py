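"""Seed selection: turn the correspondence matrix into a connected
starting subnetwork in the target.

A maximum-weight bipartite matching over positive correspondence scores
picks at most one target node per query node; the target-induced subgraph
on those nodes is the seed. If the induced graph is disconnected, the
largest connected component wins; if every matched node is isolated, the
single node with the highest correspondence score is the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linear_sum_assignment

from .extend import conductance
from .network import Network


def match_seed(C: sp.spmatrix) -> dict[int, int]:
    """Maximum-weight one-to-one matching of query to target nodes.

    Only pairs with positive correspondence may be matched; ties between
    equally heavy matchings break toward ascending (query, target) index
    pairs. Weights are nonnegative, so solving the full rectangular
    assignment and then dropping zero-weight pairs is optimal for the
    partial-matching problem.
    """
    W = np.asarray(sp.csr_matrix(C).todense(), dtype=float)
    if W.size == 0 or not (W > 0).any():
        raise ValueError("correspondence matrix has no positive entries")
    nq, nt = W.shape
    # infinitesimal lexicographic bias so equal-weight optima resolve to the
    # lowest (query, target) pairs; far below any meaningful score gap
    rank = np.add.outer(np.arange(nq) * nt, np.arange(nt)).astype(float)
    eps = W[W > 0].min() * 1e-12 / (nq * nt + 1)
    biased = W - eps * rank
    rows, cols = linear_sum_assignment(biased, maximize=True)
    return {int(i): int(j) for i, j in zip(rows, cols) if W[i, j] > 0}


@dataclass
class SeedState:
    """The evolving subnetwork in the target during extension.

    Mutation goes through :meth:`add_node`, which keeps the induced edge
    set, conductance and frontier consistent and appends to the history.
    """

    target: Network
    nodes: set[int]
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError("seed must be non-empty")
        self.nodes = set(int(i) for i in self.nodes)

    @property
    def internal_edges(self) -> set[tuple[int, int]]:
        return self.target.induced_edges(self.nodes)

    @property
    def conductance(self) -> float:
        return conductance(self.target, self.nodes)

    @property
    def frontier(self) -> set[int]:
        return self.target.neighborhood(self.nodes)

    @property
    def node_ids(self) -> frozenset[str]:
        return frozenset(self.target.node_ids[i] for i in self.nodes)

    def add_node(self, node: int, association_probability: float | None = None) -> None:
        if node in self.nodes:
            raise ValueError(f"node {node} already in seed")
        self.nodes.add(int(node))
        self.history.append(
            {
                "added_node": self.target.node_ids[node],
                "association_probability": association_probability,
                "conductance_after": self.conductance,
            }
        )


def induce_seed(
    matching: dict[int, int], target: Network, C: sp.spmatrix
) -> SeedState:
    """Build the seed from matched target nodes.

    Keeps the largest connected component of the induced subgraph (ties:
    component with the highest summed correspondence, then the one holding
    the lowest node index). If no two matched nodes are adjacent, the seed
    is the single matched node with the maximum correspondence score.
    """
    if not matching:
        raise ValueError("empty matching")
    Cd = sp.csr_matrix(C)
    score = {t: float(Cd[q, t]) for q, t in matching.items()}
    matched = sorted(score)
    comps = target.components_of(matched)
    best = max(
        comps,
        key=lambda comp: (len(comp), sum(score[t] for t in comp), -min(comp)),
    )
    if len(best) == 1 and all(len(c) == 1 for c in comps):
        # all matched nodes pairwise disconnected: take the max-score node
        solo = max(matched, key=lambda t: (score[t], -t))
        return SeedState(target, {solo})
    return SeedState(target, best)


def seed_is_connected(seed: SeedState) -> bool:
    comps = seed.target.components_of(sorted(seed.nodes))
    return len(comps) == 1
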