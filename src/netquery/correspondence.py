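"""Steady-state network-flow node correspondence.

The query and target networks are fused into one integrated network by
adding a pseudo-edge between every (query node, target node) pair whose
similarity score exceeds the threshold. A random walker moves both within
each network (uniformly over interaction edges) and across networks
(proportionally to similarity scores over pseudo-edges). The long-run
probability mass flowing through each pseudo-edge — in both directions — is
the correspondence score of that node pair: it is large exactly when the
two nodes are both molecularly similar and embedded in similar
neighborhoods, because the walker keeps shuttling between them.

The construction is entirely linear-algebraic: four transition blocks, a
row renormalization that makes the combined matrix stochastic, a power
iteration for the stationary distribution, and a sparse product for the
flow matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .io import SimilarityTable
from .network import Network

logger = logging.getLogger(__name__)


def _row_normalize(mat: sp.spmatrix) -> sp.csr_matrix:
    """Divide each row by its sum; zero rows stay zero."""
    mat = sp.csr_matrix(mat, dtype=float)
    sums = np.asarray(mat.sum(axis=1)).ravel()
    inv = np.divide(1.0, sums, out=np.zeros_like(sums), where=sums > 0)
    return sp.diags(inv) @ mat


def intra_transition(net: Network) -> sp.csr_matrix:
    """Row-stochastic transition matrix of the uniform walk on a network.

    Row i is A[i, :] / degree(i); an isolated node keeps an all-zero row
    (resolved later when the blocks are combined).
    """
    if net.n == 0:
        raise ValueError("empty network")
    return _row_normalize(net.adjacency)


def cross_transitions(sim: SimilarityTable) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Cross-network transition blocks derived from the similarity table.

    The query-to-target block normalizes each query node's similarity row to
    a distribution; the target-to-query block is the transpose of the score
    matrix with each target node's row normalized by that node's total
    similarity mass. Nodes without pseudo-edges get zero rows.
    """
    if sim.n_entries == 0:
        raise ValueError("similarity table has no entries")
    p_qt = _row_normalize(sim.matrix)
    p_tq = _row_normalize(sim.matrix.T)
    return p_qt, p_tq


@dataclass(frozen=True)
class IntegratedWalk:
    """The combined stochastic walk over query ∪ target nodes.

    ``P`` is the row-stochastic transition over all n_q + n_t nodes; its
    four blocks after renormalization are exposed for flow computation. A
    node with both interaction edges and pseudo-edges splits its mass
    half/half between the two movement types; a node with only one kind
    keeps full mass there; a fully isolated node self-loops.
    """

    P: sp.csr_matrix
    P_Q: sp.csr_matrix
    P_T: sp.csr_matrix
    P_QT: sp.csr_matrix
    P_TQ: sp.csr_matrix
    n_query: int
    n_target: int

    @property
    def n(self) -> int:
        return self.n_query + self.n_target

    @property
    def combined_qt(self) -> sp.csr_matrix:
        """Query→target block of the renormalized combined matrix."""
        return sp.csr_matrix(self.P[: self.n_query, self.n_query:])

    @property
    def combined_tq(self) -> sp.csr_matrix:
        """Target→query block of the renormalized combined matrix."""
        return sp.csr_matrix(self.P[self.n_query:, : self.n_query])


def combine(
    p_q: sp.spmatrix,
    p_t: sp.spmatrix,
    p_qt: sp.spmatrix,
    p_tq: sp.spmatrix,
) -> IntegratedWalk:
    """Assemble the block transition matrix and renormalize rows.

    The blocks are concatenated as ``[[P_Q, P_QT], [P_TQ, P_T]]`` and each
    row is divided by its sum; rows that are entirely zero (isolated node
    with no pseudo-edge) become unit self-loops, which pins the walker
    there — such nodes simply carry no flow.
    """
    nq, nt = p_q.shape[0], p_t.shape[0]
    if p_qt.shape != (nq, nt) or p_tq.shape != (nt, nq):
        raise ValueError("inconsistent block dimensions")
    big = sp.bmat([[p_q, p_qt], [p_tq, p_t]], format="csr")
    sums = np.asarray(big.sum(axis=1)).ravel()
    dead = np.where(sums == 0)[0]
    if dead.size:
        logger.info("combine: %d node(s) with no edges at all get self-loops", dead.size)
        big = big + sp.coo_matrix(
            (np.ones(dead.size), (dead, dead)), shape=big.shape
        ).tocsr()
        sums = np.asarray(big.sum(axis=1)).ravel()
    P = sp.diags(1.0 / sums) @ big
    P = sp.csr_matrix(P)
    return IntegratedWalk(
        P=P,
        P_Q=sp.csr_matrix(p_q),
        P_T=sp.csr_matrix(p_t),
        P_QT=sp.csr_matrix(p_qt),
        P_TQ=sp.csr_matrix(p_tq),
        n_query=nq,
        n_target=nt,
    )


def build_walk(query: Network, target: Network, sim: SimilarityTable) -> IntegratedWalk:
    """Convenience constructor: intra blocks + cross blocks + combine."""
    p_qt, p_tq = cross_transitions(sim)
    return combine(intra_transition(query), intra_transition(target), p_qt, p_tq)


@dataclass(frozen=True)
class StationaryDistribution:
    pi: np.ndarray
    iterations: int
    residual: float


class ConvergenceError(RuntimeError):
    pass


def power_stationary(
    P: sp.csr_matrix,
    tol: float = 1e-10,
    max_iter: int = 10000,
    x0: np.ndarray | None = None,
) -> StationaryDistribution:
    """Stationary distribution of a stochastic matrix by power iteration.

    Iterates the lazy walk (I + P)/2, whose fixed points coincide with
    those of P but which converges even on periodic (e.g. bipartite)
    chains. Starts from the uniform distribution unless ``x0`` is given.
    """
    n = P.shape[0]
    x = np.full(n, 1.0 / n) if x0 is None else np.asarray(x0, dtype=float)
    for it in range(1, max_iter + 1):
        y = x @ P
        residual = float(np.abs(y - x).sum())  # fixed-point residual of P itself
        if residual <= tol:
            return StationaryDistribution(x, it, residual)
        x = 0.5 * (x + y)
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} iterations "
        f"(last residual {residual:.3e})"
    )


def stationary(
    walk: IntegratedWalk, tol: float = 1e-10, max_iter: int = 10000
) -> StationaryDistribution:
    """Stationary distribution of the integrated walk.

    If the integrated network is disconnected, the walk is restricted to
    the pseudo-edge-bearing connected component with the most nodes; all
    other nodes get zero stationary mass (logged). Ties go to the component
    containing the lowest node index.
    """
    P = walk.P
    support = P + P.T  # undirected support; edges and pseudo-edges are bidirectional
    ncomp, labels = connected_components(support, directed=False)
    if ncomp == 1:
        return power_stationary(P, tol=tol, max_iter=max_iter)

    # components that carry at least one pseudo-edge (a cross entry)
    qt = walk.combined_qt.tocoo()
    cross_labels = set(labels[qt.row].tolist())
    if not cross_labels:
        raise ValueError("integrated network has no pseudo-edges")
    best = max(
        cross_labels,
        key=lambda lab: (int((labels == lab).sum()), -int(np.where(labels == lab)[0][0])),
    )
    mask = labels == best
    idx = np.where(mask)[0]
    logger.info(
        "stationary: integrated network has %d components; walking on %d of %d nodes",
        ncomp, idx.size, P.shape[0],
    )
    sub = sp.csr_matrix(P[np.ix_(idx, idx)])
    sd = power_stationary(sub, tol=tol, max_iter=max_iter)
    pi = np.zeros(P.shape[0])
    pi[idx] = sd.pi
    return StationaryDistribution(pi, sd.iterations, sd.residual)


def correspondence(walk: IntegratedWalk, pi: np.ndarray) -> sp.csr_matrix:
    """Steady-state flow through every pseudo-edge.

    ``C[i, j] = pi(q_i) * P[q_i -> t_j] + P[t_j -> q_i] * pi(t_j)`` using
    the renormalized cross blocks of the combined walk, i.e. the actual
    probability mass per step traversing the pseudo-edge in either
    direction. Support is exactly the pseudo-edge set.
    """
    nq = walk.n_query
    pi = np.asarray(pi, dtype=float)
    pi_q, pi_t = pi[:nq], pi[nq:]
    C = sp.diags(pi_q) @ walk.combined_qt + (sp.diags(pi_t) @ walk.combined_tq).T
    C = sp.csr_matrix(C)
    C.eliminate_zeros()
    return C
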