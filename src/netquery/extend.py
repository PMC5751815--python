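"""Greedy seed extension by association probability and conductance.

Each step scores the seed's frontier (target nodes adjacent to the seed)
by the probability that a random walker starting inside the seed leaves to
that node and returns to the seed within two hops. The top-K candidates by
that association probability compete on conductance: the one whose
inclusion minimizes the conductance of the grown seed wins. Growth stops
when the seed hits its size limit, the best candidate fails to cut
conductance by the minimum relative drop, or the frontier is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np

from .network import Network

if TYPE_CHECKING:  # avoid circular import; seed.py imports conductance from here
    from .seed import SeedState

#: conductance of a set with zero volume or full volume (undefined cut ratio)
INF_CONDUCTANCE = math.inf


def conductance(target: Network, node_set: Iterable[int]) -> float:
    """Conductance of a node set within the target network.

    cut / min(vol, 2m - vol), where cut counts target edges with exactly
    one endpoint in the set, vol is the sum of target degrees over the set
    and m the total number of undirected target edges. Returns +inf when
    either volume term is zero (whole graph or empty set).
    """
    nodes = set(int(i) for i in node_set)
    if not nodes:
        raise ValueError("node set must be non-empty")
    mask = np.zeros(target.n, dtype=bool)
    mask[list(nodes)] = True
    vol = float(target.degrees[mask].sum())
    two_m = 2.0 * target.m
    denom = min(vol, two_m - vol)
    if denom <= 0:
        return INF_CONDUCTANCE
    inside = 2.0 * len(target.induced_edges(nodes))
    cut = vol - inside
    return cut / denom


def seed_stationary(seed: "SeedState") -> dict[int, float]:
    """Stationary distribution of the uniform walk on the seed subgraph.

    For a connected undirected graph this is degree / total degree, with
    degrees counted inside the seed-induced subgraph. A seed without
    internal edges falls back to the uniform distribution.
    """
    nodes = sorted(seed.nodes)
    internal = seed.internal_edges
    if not internal:
        return {i: 1.0 / len(nodes) for i in nodes}
    deg = {i: 0 for i in nodes}
    for a, b in internal:
        deg[a] += 1
        deg[b] += 1
    total = sum(deg.values())
    return {i: deg[i] / total for i in nodes}


def entry_probability(
    seed: "SeedState", target: Network, v_n: int,
    pi_s: dict[int, float] | None = None,
) -> float:
    """Probability that a walker positioned by the seed's stationary
    distribution steps out of the seed onto frontier node ``v_n``.

    The escape step runs on the full target network, so each seed node's
    outgoing mass is split over its *target* degree.
    """
    if pi_s is None:
        pi_s = seed_stationary(seed)
    neigh = set(target.neighbors(v_n).tolist())
    return sum(
        pi_s[i] / target.degrees[i] for i in seed.nodes if i in neigh
    )


def association_probability(
    seed: "SeedState", target: Network, v_n: int,
    pi_s: dict[int, float] | None = None,
) -> float:
    """Probability of stepping out to ``v_n`` and returning to the seed on
    the next step: entry probability times r(v_n)/d(v_n), where r counts
    the target edges from ``v_n`` back into the seed."""
    p1 = entry_probability(seed, target, v_n, pi_s=pi_s)
    r = sum(1 for u in target.neighbors(v_n).tolist() if u in seed.nodes)
    assert r >= 1, "frontier node must touch the seed"
    return p1 * r / float(target.degrees[v_n])


@dataclass(frozen=True)
class CandidateScore:
    node: int
    p1: float
    p2: float
    r: int
    conductance_if_added: float


def score_frontier(seed: "SeedState", target: Network) -> list[CandidateScore]:
    """Association-probability scores for every frontier node, sorted by
    descending probability (ties: ascending node index). Conductance is not
    evaluated here; see :func:`best_candidate`."""
    pi_s = seed_stationary(seed)
    out = []
    for v in sorted(seed.frontier):
        p1 = entry_probability(seed, target, v, pi_s=pi_s)
        r = sum(1 for u in target.neighbors(v).tolist() if u in seed.nodes)
        p2 = p1 * r / float(target.degrees[v])
        out.append(CandidateScore(v, p1, p2, r, math.nan))
    out.sort(key=lambda c: (-c.p2, c.node))
    return out


def best_candidate(seed: "SeedState", target: Network, K: int = 20) -> CandidateScore | None:
    """Pick the winning frontier node for one extension step.

    The top ``K`` frontier nodes by association probability are screened;
    among them the node whose addition yields the minimal conductance wins
    (ties: higher association probability, then lower node index). Returns
    None when the frontier is empty.
    """
    ranked = score_frontier(seed, target)
    if not ranked:
        return None
    evaluated = [
        CandidateScore(
            c.node, c.p1, c.p2, c.r,
            conductance(target, seed.nodes | {c.node}),
        )
        for c in ranked[:K]
    ]
    return min(evaluated, key=lambda c: (c.conductance_if_added, -c.p2, c.node))


def extend_step(seed: "SeedState", target: Network, K: int = 20) -> "SeedState | None":
    """Perform one unconditional extension step in place.

    Returns the updated seed, or None ("stop") when the frontier is empty.
    The conductance stop rule is applied by :func:`extend`, which inspects
    the winner before committing.
    """
    winner = best_candidate(seed, target, K=K)
    if winner is None:
        return None
    seed.add_node(winner.node, association_probability=winner.p2)
    return seed


def extend(
    seed: "SeedState",
    target: Network,
    K: int = 20,
    max_size: int | None = None,
    min_rel_drop: float = 0.10,
) -> "SeedState":
    """Grow the seed until a stop condition fires.

    Stops when (a) the seed reaches ``max_size`` nodes, (b) the best
    candidate's relative conductance decrease falls below ``min_rel_drop``
    of the current conductance, or (c) the frontier is empty. Each accepted
    step strictly decreases conductance by at least the required fraction.
    """
    if max_size is None:
        max_size = target.n  # effectively unbounded
    while True:
        if len(seed.nodes) >= max_size:
            seed.history.append({"stop": "size_limit", "size": len(seed.nodes)})
            break
        winner = best_candidate(seed, target, K=K)
        if winner is None:
            seed.history.append({"stop": "empty_frontier", "size": len(seed.nodes)})
            break
        phi_old = seed.conductance
        phi_new = winner.conductance_if_added
        if math.isinf(phi_old):
            accept = math.isfinite(phi_new)  # any finite conductance is an improvement
        else:
            accept = phi_old > 0 and (phi_old - phi_new) / phi_old >= min_rel_drop
        if not accept:
            seed.history.append(
                {"stop": "conductance", "size": len(seed.nodes),
                 "phi": phi_old, "best_phi_if_added": phi_new}
            )
            break
        seed.add_node(winner.node, association_probability=winner.p2)
    return seed
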