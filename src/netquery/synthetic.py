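"""Synthetic planted-module benchmark instances.

Each instance emulates a realistic querying scenario end to end: a small,
dense, connected query module; a target network consisting of a sparse
random background with a perturbed copy of the module planted inside it
(node deletions, edge deletions and node insertions model evolutionary
divergence between species); and a similarity table whose true homolog
pairs score high while a sprinkling of random non-homolog pairs gets low
positive scores, mimicking spurious BLAST hits. The planted copy is the
ground truth against which a querying result's match score is computed.

All randomness flows from one integer seed through a single generator, so
instances regenerate byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .io import SimilarityTable, write_network, write_similarity
from .network import Network

_MAX_RESAMPLE = 500


@dataclass(frozen=True)
class SynthParams:
    """Generator knobs; defaults define the easy benchmark regime.

    query_size 4-25 matches the size range of curated complexes typically
    used as queries; the easy regime uses an 8-node query against a
    300-node Erdős–Rényi background (p = 0.02, mean degree ≈ 6), no
    perturbation, and homolog scores ten times the noise scale.
    """

    query_size: int = 8
    target_size: int = 300
    background_model: str = "ER"   # "ER" or "BA"
    er_p: float = 0.02
    ba_m: int = 2
    query_edge_prob: float = 0.5   # internal density of the query module
    edge_delete_rate: float = 0.0
    node_delete_rate: float = 0.0
    node_insert_count: int = 0
    homolog_score_mean: float = 100.0
    noise_score_rate: float = 0.05  # fraction of non-truth pairs given noise scores
    attach_prob: float = 0.5        # chance each planted node gets one background edge
    seed: int = 0

    def __post_init__(self) -> None:
        if not 4 <= self.query_size <= 25:
            raise ValueError("query_size must be in [4, 25]")
        for name in ("edge_delete_rate", "node_delete_rate", "noise_score_rate",
                     "attach_prob", "query_edge_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.target_size <= self.query_size:
            raise ValueError("target must be larger than the query")
        if self.background_model not in ("ER", "BA"):
            raise ValueError("background_model must be 'ER' or 'BA'")


@dataclass(frozen=True)
class PlantedInstance:
    query: Network
    target: Network
    similarity: SimilarityTable
    truth_map: dict[str, str]        # query id -> planted target id (survivors)
    planted_nodes: frozenset[str]    # ground-truth module in the target
    params: SynthParams
    seed: int

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "query": out / "query.tsv",
            "target": out / "target.tsv",
            "similarity": out / "similarity.tsv",
            "truth": out / "truth.tsv",
        }
        write_network(self.query, paths["query"])
        write_network(self.target, paths["target"])
        write_similarity(self.similarity, self.query, self.target, paths["similarity"])
        with open(paths["truth"], "w") as fh:
            fh.write("#planted_target_node\tquery_source\n")
            inv = {t: q for q, t in self.truth_map.items()}
            for t in sorted(self.planted_nodes):
                fh.write(f"{t}\t{inv.get(t, '-')}\n")
        return paths


def _connected_gnp(n: int, p: float, rng: np.random.Generator) -> nx.Graph:
    for _ in range(_MAX_RESAMPLE):
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            return g
    raise RuntimeError(f"could not sample a connected G({n}, {p}) module")


def generate(params: SynthParams | None = None, **kwargs) -> PlantedInstance:
    """Generate a planted-module instance.

    Steps: sample a connected query module; copy it into the target with
    node/edge deletions and node insertions, resampling until the perturbed
    module stays connected; embed it in a random background with sparse
    attachment edges; emit similarity scores that are high for surviving
    homolog pairs and low for a random fraction of other pairs.
    """
    if params is None:
        params = SynthParams(**kwargs)
    elif kwargs:
        raise TypeError("pass either params or keyword overrides, not both")
    rng = np.random.default_rng(params.seed)

    q_graph = _connected_gnp(params.query_size, params.query_edge_prob, rng)
    q_ids = [f"q{i}" for i in range(params.query_size)]
    q_pairs = [(q_ids[a], q_ids[b]) for a, b in sorted(q_graph.edges())]
    query = Network.from_edge_pairs(q_pairs, extra_nodes=q_ids)

    # perturbed planted copy, resampled until connected
    planted_edges: list[tuple[str, str]] = []
    for attempt in range(_MAX_RESAMPLE):
        survivors = [i for i in range(params.query_size)
                     if rng.random() >= params.node_delete_rate]
        if len(survivors) < 2:
            continue
        surv = set(survivors)
        edges = [(a, b) for a, b in sorted(q_graph.edges())
                 if a in surv and b in surv and rng.random() >= params.edge_delete_rate]
        module = nx.Graph()
        module.add_nodes_from(survivors)
        module.add_edges_from(edges)
        inserted = []
        for k in range(params.node_insert_count):
            name = f"x{k}"
            wires = rng.choice(survivors, size=min(2, len(survivors)), replace=False)
            inserted.extend((name, int(w)) for w in wires)
        full = module.copy()
        for name, w in inserted:
            full.add_edge(name, w)
        if nx.is_connected(full):
            break
    else:
        raise RuntimeError("perturbation never produced a connected planted module")

    def t_name(v) -> str:
        return f"t{v}" if isinstance(v, (int, np.integer)) else f"t{v}"

    planted_edges = [tuple(sorted((t_name(a), t_name(b)))) for a, b in full.edges()]
    planted_ids = sorted(t_name(v) for v in full.nodes())
    truth_map = {q_ids[i]: t_name(i) for i in survivors}

    # background graph
    n_bg = params.target_size - len(planted_ids)
    if params.background_model == "ER":
        bg = nx.gnp_random_graph(n_bg, params.er_p, seed=int(rng.integers(2**31)))
    else:
        bg = nx.barabasi_albert_graph(n_bg, params.ba_m, seed=int(rng.integers(2**31)))
    bg_ids = [f"b{i}" for i in range(n_bg)]
    t_pairs = list(planted_edges)
    t_pairs += [(bg_ids[a], bg_ids[b]) for a, b in sorted(bg.edges())]
    # sparse attachment of the module to the background
    for pid in planted_ids:
        if n_bg > 0 and rng.random() < params.attach_prob:
            t_pairs.append((pid, bg_ids[int(rng.integers(n_bg))]))
    # edge-list-defined PPI networks have no isolated nodes: wire any
    # degree-zero background node to a random other background node
    touched = {v for pair in t_pairs for v in pair}
    for k, bid in enumerate(bg_ids):
        if bid not in touched and n_bg > 1:
            other = int(rng.integers(n_bg - 1))
            if other >= k:
                other += 1
            t_pairs.append((bid, bg_ids[other]))
    target = Network.from_edge_pairs(t_pairs, extra_nodes=planted_ids + bg_ids)

    # similarity scores: truth pairs high, random non-truth pairs low
    mean = params.homolog_score_mean
    entries: dict[tuple[int, int], float] = {}
    for q, t in sorted(truth_map.items()):
        score = float(np.clip(rng.normal(mean, 0.1 * mean), 0.5 * mean, None))
        entries[(query.index(q), target.index(t))] = score
    n_noise = int(round(params.noise_score_rate * query.n * target.n))
    truth_cells = set(entries)
    placed = 0
    while placed < n_noise:
        qi = int(rng.integers(query.n))
        ti = int(rng.integers(target.n))
        if (qi, ti) in truth_cells or (qi, ti) in entries:
            continue
        entries[(qi, ti)] = float(rng.uniform(0.1, mean / 10.0))
        placed += 1
    similarity = SimilarityTable.from_entries(entries, (query.n, target.n), s_t=0.0)

    return PlantedInstance(
        query=query,
        target=target,
        similarity=similarity,
        truth_map=truth_map,
        planted_nodes=frozenset(planted_ids),
        params=params,
        seed=params.seed,
    )
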