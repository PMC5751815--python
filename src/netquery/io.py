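"""Readers and writers for networks, similarity tables, annotations,
reference complexes, and querying results.

All formats are plain TSV. The loaders are deterministic: the same input
bytes always produce the same node indexing and the same in-memory
structures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import Network

logger = logging.getLogger(__name__)

#: GAF experimental evidence codes retained when loading annotations.
EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})

_ASPECT_TO_ROOT = {"P": "BP", "F": "MF", "C": "CC"}


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def read_network(path: str | Path, node_list: str | Path | None = None) -> Network:
    """Read an undirected network from a TSV/whitespace edge list.

    Lines starting with ``#`` are comments. Duplicate edges (in either
    orientation) are collapsed; self-loops are dropped with a warning but
    their node is retained. Isolated nodes appear only if listed in the
    optional ``node_list`` sidecar (one id per line).

    Raises
    ------
    ParseError
        On a data row with fewer than two tokens, or if no edges remain.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    self_loops = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ParseError(f"{path}:{lineno}: expected >=2 columns, got {len(tokens)}")
            a, b = tokens[0], tokens[1]
            if a == b:
                self_loops += 1
            pairs.append((a, b))
    if self_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, self_loops)
    extra: list[str] = []
    if node_list is not None:
        with open(node_list) as fh:
            extra = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    net = Network.from_edge_pairs(pairs, extra_nodes=extra)
    if net.m == 0:
        raise ParseError(f"{path}: empty edge set after cleaning")
    return net


def write_network(net: Network, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#node_a\tnode_b\n")
        for i, j in sorted(net.edges):
            fh.write(f"{net.node_ids[i]}\t{net.node_ids[j]}\n")


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityTable:
    """Sparse nonnegative node-similarity scores between a query and a
    target network.

    Only scores strictly greater than the threshold ``s_t`` are stored;
    each stored entry defines a pseudo-edge between the two networks.
    """

    matrix: sp.csr_matrix  # |V_Q| x |V_T|, entries > s_t
    s_t: float = 0.0

    @property
    def n_entries(self) -> int:
        return int(self.matrix.nnz)

    def scale(self, factor: float) -> "SimilarityTable":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return SimilarityTable(self.matrix * factor, self.s_t * factor)

    @classmethod
    def from_entries(
        cls,
        entries: Mapping[tuple[int, int], float],
        shape: tuple[int, int],
        s_t: float = 0.0,
    ) -> "SimilarityTable":
        kept = {k: v for k, v in entries.items() if v > s_t}
        if kept:
            rows, cols = zip(*kept.keys())
            mat = sp.coo_matrix((list(kept.values()), (rows, cols)), shape=shape).tocsr()
        else:
            mat = sp.csr_matrix(shape)
        return cls(mat, s_t)


def read_similarity(
    path: str | Path,
    query: Network,
    target: Network,
    s_t: float = 0.0,
) -> SimilarityTable:
    """Read a (query_id, target_id, score) TSV into a SimilarityTable.

    Entries with ids absent from either network are counted and logged, not
    fatal. Duplicate (query, target) rows keep the maximum score (best-hit
    convention). Scores at or below ``s_t`` are dropped.

    Raises
    ------
    ParseError
        On negative scores, or if no entries survive filtering ("no
        pseudo-edges; networks incomparable").
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", header=None,
        names=["query_id", "target_id", "score"],
        dtype={"query_id": str, "target_id": str, "score": float},
    )
    if (df["score"] < 0).any():
        bad = df.index[df["score"] < 0][0]
        raise ParseError(f"{path}: negative similarity score at data row {bad + 1}")

    known = df["query_id"].map(query.has_node) & df["target_id"].map(target.has_node)
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("%s: skipped %d row(s) with ids absent from the networks", path, n_unknown)
    df = df[known]

    n_dups = int(df.duplicated(subset=["query_id", "target_id"]).sum())
    if n_dups:
        logger.warning("%s: %d duplicate pair(s); keeping max score", path, n_dups)
        df = df.groupby(["query_id", "target_id"], as_index=False)["score"].max()

    df = df[df["score"] > s_t]
    if df.empty:
        raise ParseError(f"{path}: no pseudo-edges above threshold {s_t}; networks incomparable")

    rows = df["query_id"].map(query.index).to_numpy()
    cols = df["target_id"].map(target.index).to_numpy()
    mat = sp.coo_matrix(
        (df["score"].to_numpy(), (rows, cols)), shape=(query.n, target.n)
    ).tocsr()
    return SimilarityTable(mat, s_t)


def write_similarity(
    sim: SimilarityTable, query: Network, target: Network, path: str | Path
) -> None:
    coo = sim.matrix.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        fh.write("#query_id\ttarget_id\tscore\n")
        for k in order:
            fh.write(
                f"{query.node_ids[coo.row[k]]}\t{target.node_ids[coo.col[k]]}\t"
                f"{coo.data[k]:.6g}\n"
            )


# ---------------------------------------------------------------------------
# annotations and complexes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationTable:
    """Term -> protein annotations with each term's root ontology.

    ``root_sizes`` counts the distinct proteins annotated under each root
    (BP, CC or MF); it is the denominator of the information-content
    calculation.
    """

    term_to_proteins: dict[str, frozenset[str]]
    term_to_root: dict[str, str]
    root_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for term in self.term_to_proteins:
            if term not in self.term_to_root:
                raise ValueError(f"term {term} has no root assignment")


def _annotations_from_pairs(rows: Iterable[tuple[str, str, str]]) -> AnnotationTable:
    term_to_proteins: dict[str, set[str]] = {}
    term_to_root: dict[str, str] = {}
    root_members: dict[str, set[str]] = {}
    for term, protein, root in rows:
        term_to_proteins.setdefault(term, set()).add(protein)
        term_to_root[term] = root
        root_members.setdefault(root, set()).add(protein)
    return AnnotationTable(
        {t: frozenset(s) for t, s in term_to_proteins.items()},
        term_to_root,
        {r: len(s) for r, s in root_members.items()},
    )


def read_annotations_gaf(path: str | Path) -> AnnotationTable:
    """Read a GAF 2.x file, keeping only experimentally supported
    annotations (evidence codes EXP, IDA, IPI, IMP, IGI, IEP)."""
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("!") or not raw.strip():
                continue
            cols = raw.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            protein, term, evidence, aspect = cols[1], cols[4], cols[6], cols[8]
            if evidence not in EXPERIMENTAL_EVIDENCE:
                continue
            root = _ASPECT_TO_ROOT.get(aspect)
            if root is None:
                continue
            rows.append((term, protein, root))
    return _annotations_from_pairs(rows)


def read_annotations(path: str | Path, roots_path: str | Path | None = None) -> AnnotationTable:
    """Read annotations from either a GAF 2.x file (auto-detected) or a
    two-column (term, protein) TSV plus a (term, root) sidecar table."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("!gaf") or len(first.rstrip("\n").split("\t")) >= 15:
        return read_annotations_gaf(path)
    if roots_path is None:
        raise ParseError(f"{path}: two-column annotation format requires a term->root table")
    roots_df = pd.read_csv(roots_path, sep="\t", comment="#", header=None,
                           names=["term", "root"], dtype=str)
    term_root = dict(zip(roots_df["term"], roots_df["root"]))
    ann_df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["term", "protein"], dtype=str)
    rows = []
    for term, protein in zip(ann_df["term"], ann_df["protein"]):
        if term not in term_root:
            raise ParseError(f"{path}: term {term} missing from root table")
        rows.append((term, protein, term_root[term]))
    return _annotations_from_pairs(rows)


@dataclass(frozen=True)
class ComplexSet:
    """Named reference complexes (protein-id sets in target namespace)."""

    complexes: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        for name, members in self.complexes:
            if not members:
                raise ValueError(f"complex {name!r} is empty")

    def __len__(self) -> int:
        return len(self.complexes)

    def items(self):
        return iter(self.complexes)


def read_complexes(path: str | Path, named: bool = True) -> ComplexSet:
    """Read complexes, one per line, tab-separated member ids; the first
    token is the complex name when ``named`` is true. Blank lines skipped."""
    out: list[tuple[str, frozenset[str]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            tokens = [t for t in line.split("\t") if t]
            if named:
                if len(tokens) < 2:
                    raise ParseError(f"{path}:{lineno}: named complex needs >=2 tokens")
                name, members = tokens[0], tokens[1:]
            else:
                name, members = f"complex_{len(out) + 1}", tokens
            out.append((name, frozenset(members)))
    return ComplexSet(tuple(out))


# ---------------------------------------------------------------------------
# query results
# ---------------------------------------------------------------------------

@dataclass
class QueryResult:
    """Final output of a querying run, with intermediate stages kept for
    inspection and a machine-readable event log."""

    final_nodes: frozenset[str]
    final_edges: frozenset[tuple[str, str]]
    seed_nodes: frozenset[str]
    extended_nodes: frozenset[str]
    correspondence_used: dict[str, str]
    log: list[dict] = field(default_factory=list)


def write_result(result: QueryResult, out_prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>.nodes.tsv``, ``<prefix>.edges.tsv`` and
    ``<prefix>.log.json``; output is bit-identical across runs on
    identical inputs."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": prefix.with_suffix(prefix.suffix + ".nodes.tsv"),
        "edges": prefix.with_suffix(prefix.suffix + ".edges.tsv"),
        "log": prefix.with_suffix(prefix.suffix + ".log.json"),
    }
    with open(paths["nodes"], "w") as fh:
        fh.write("#node_id\n")
        for nid in sorted(result.final_nodes):
            fh.write(nid + "\n")
    with open(paths["edges"], "w") as fh:
        fh.write("#node_a\tnode_b\n")
        for a, b in sorted(result.final_edges):
            fh.write(f"{a}\t{b}\n")
    payload = {
        "final_nodes": sorted(result.final_nodes),
        "seed_nodes": sorted(result.seed_nodes),
        "extended_nodes": sorted(result.extended_nodes),
        "correspondence_used": dict(sorted(result.correspondence_used.items())),
        "events": result.log,
    }
    with open(paths["log"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def read_result_nodes(path: str | Path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(ln.strip() for ln in fh if ln.strip() and not ln.startswith("#"))
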