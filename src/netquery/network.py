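"""Undirected labeled graphs with stable integer indexing.

Every other module indexes nodes through :class:`Network`, so the indexing
contract lives here: node indices are assigned in order of first appearance
in the input, edges are stored as unordered index pairs, and the adjacency
matrix is a symmetric 0/1 CSR matrix. Graphs are simple — no self-loops, no
parallel edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


@dataclass(frozen=True)
class Network:
    """An undirected simple graph over string node identifiers.

    Parameters
    ----------
    node_ids :
        Unique string identifiers, in deterministic (first-appearance) order.
        The position of an id in this tuple is its node index everywhere.
    edges :
        Unordered pairs ``(i, j)`` of node indices with ``i < j``.
    """

    node_ids: tuple[str, ...]
    edges: frozenset[tuple[int, int]]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        index = {nid: i for i, nid in enumerate(self.node_ids)}
        if len(index) != len(self.node_ids):
            raise ValueError("duplicate node identifiers")
        n = len(self.node_ids)
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) references unknown node index")
            if i > j:
                raise ValueError(f"edge ({i},{j}) not normalized to i < j")
        object.__setattr__(self, "_index", index)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edge_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "Network":
        """Build a network from (id, id) pairs, assigning indices by first
        appearance; self-loops and duplicate edges are collapsed silently
        (callers that need to warn count them beforehand)."""
        ids: list[str] = []
        index: dict[str, int] = {}

        def idx(nid: str) -> int:
            if nid not in index:
                index[nid] = len(ids)
                ids.append(nid)
            return index[nid]

        edges: set[tuple[int, int]] = set()
        for a, b in pairs:
            ia, ib = idx(a), idx(b)
            if ia == ib:
                continue
            edges.add((min(ia, ib), max(ia, ib)))
        for nid in extra_nodes:
            idx(nid)
        return cls(tuple(ids), frozenset(edges))

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def m(self) -> int:
        """Number of undirected edges."""
        return len(self.edges)

    def index(self, node_id: str) -> int:
        return self._index[node_id]

    def has_node(self, node_id: str) -> bool:
        return node_id in self._index

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 adjacency in CSR form (built lazily, cached)."""
        cached = getattr(self, "_adj_cache", None)
        if cached is None:
            n = self.n
            if self.edges:
                rows, cols = zip(*self.edges)
                rows, cols = np.array(rows), np.array(cols)
                data = np.ones(len(rows))
                a = sp.coo_matrix(
                    (np.concatenate([data, data]),
                     (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
                    shape=(n, n),
                ).tocsr()
            else:
                a = sp.csr_matrix((n, n))
            object.__setattr__(self, "_adj_cache", a)
            cached = a
        return cached

    @property
    def degrees(self) -> np.ndarray:
        cached = getattr(self, "_deg_cache", None)
        if cached is None:
            cached = np.asarray(self.adjacency.sum(axis=1)).ravel()
            object.__setattr__(self, "_deg_cache", cached)
        return cached

    def neighbors(self, i: int) -> np.ndarray:
        a = self.adjacency
        return a.indices[a.indptr[i]: a.indptr[i + 1]]

    def neighborhood(self, nodes: Iterable[int]) -> set[int]:
        """All neighbors of ``nodes``, excluding ``nodes`` themselves."""
        nodes = set(nodes)
        out: set[int] = set()
        for i in nodes:
            out.update(self.neighbors(i).tolist())
        return out - nodes

    # -- subgraph helpers --------------------------------------------------

    def induced_edges(self, nodes: Iterable[int]) -> set[tuple[int, int]]:
        """Edges of this network with both endpoints in ``nodes``."""
        s = set(nodes)
        return {(i, j) for (i, j) in self.edges if i in s and j in s}

    def components_of(self, nodes: Sequence[int]) -> list[set[int]]:
        """Connected components of the induced subgraph on ``nodes``,
        as sets of *this network's* node indices."""
        nodes = list(nodes)
        if not nodes:
            return []
        sub = self.adjacency[np.ix_(nodes, nodes)]
        ncomp, labels = connected_components(sub, directed=False)
        comps: list[set[int]] = [set() for _ in range(ncomp)]
        for local, lab in enumerate(labels):
            comps[lab].add(nodes[local])
        return comps
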