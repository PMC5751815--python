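"""End-to-end querying pipeline: correspondence → seed → extend → prune.

The pipeline is fully deterministic for fixed inputs — every tie in
matching, extension and pruning breaks by a stated node-index order — so
reruns produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import scipy.sparse as sp

from .config import RunConfig
from .correspondence import build_walk, correspondence, stationary
from .evaluate import MetricReport, evaluate_result
from .extend import extend
from .io import (
    QueryResult,
    SimilarityTable,
    read_annotations,
    read_complexes,
    read_network,
    read_result_nodes,
    read_similarity,
    write_result,
)
from .network import Network
from .prune import induce_neighborhood, personalized_pagerank, prune_by_mass
from .seed import induce_seed, match_seed

logger = logging.getLogger(__name__)


def query_networks(
    query: Network,
    target: Network,
    sim: SimilarityTable,
    config: RunConfig | None = None,
) -> QueryResult:
    """Run the full querying pipeline on in-memory inputs."""
    config = config or RunConfig()
    log: list[dict] = []

    walk = build_walk(query, target, sim)
    pi = stationary(walk, tol=config.power_tol, max_iter=config.power_max_iter)
    C = correspondence(walk, pi.pi)
    log.append({"stage": "correspondence", "iterations": pi.iterations,
                "residual": pi.residual, "pseudo_edges": int(C.nnz)})

    matching = match_seed(C)
    corr_used = {
        query.node_ids[q]: target.node_ids[t] for q, t in sorted(matching.items())
    }
    seed = induce_seed(matching, target, C)
    seed_ids = seed.node_ids
    log.append({"stage": "seed", "matched_pairs": len(matching),
                "seed_nodes": sorted(seed_ids)})

    max_size = config.max_size(query.n)
    extend(seed, target, K=config.K, max_size=max_size,
           min_rel_drop=config.min_rel_drop)
    extended_ids = seed.node_ids
    log.append({"stage": "extend", "max_size": max_size,
                "trace": seed.history,
                "extended_nodes": sorted(extended_ids)})

    g_i, seed_in_gi = induce_neighborhood(seed, target)
    ppr = personalized_pagerank(g_i, seed_in_gi, alpha=config.alpha,
                                tol=config.ppr_tol)
    final_ids = prune_by_mass(ppr, g_i, seed_in_gi, mass=config.mass)
    log.append({
        "stage": "prune",
        "induced_size": g_i.n,
        "ppr": {g_i.node_ids[i]: float(ppr.r[i]) for i in range(g_i.n)},
        "final_nodes": sorted(final_ids),
    })

    final_idx = {target.index(v) for v in final_ids}
    final_edges = frozenset(
        (target.node_ids[i], target.node_ids[j])
        for i, j in target.induced_edges(final_idx)
    )
    return QueryResult(
        final_nodes=frozenset(final_ids),
        final_edges=final_edges,
        seed_nodes=seed_ids,
        extended_nodes=extended_ids,
        correspondence_used=corr_used,
        log=log,
    )


def run_query(
    config: RunConfig,
    query_path: str | Path,
    target_path: str | Path,
    sim_path: str | Path,
    out_prefix: str | Path | None = None,
) -> QueryResult:
    """File-level entry point: read inputs, query, optionally write outputs."""
    query = read_network(query_path)
    target = read_network(target_path)
    sim = read_similarity(sim_path, query, target, s_t=config.s_t)
    result = query_networks(query, target, sim, config)
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    result.log.append({"stage": "config", "hash": cfg_hash, "values": asdict(config)})
    if out_prefix is not None:
        write_result(result, out_prefix)
    return result


def run_eval(
    result_path: str | Path,
    complexes_path: str | Path,
    annotations_path: str | Path | None = None,
    annotated_term: str | None = None,
    fdr_pvalue: float | None = None,
    m_t: float = 0.5,
) -> MetricReport:
    """Evaluate a written querying result against reference complexes.

    Specificity needs an annotation table and the best-enriched term;
    hit flags need an externally computed FDR-corrected p-value. Missing
    inputs leave the corresponding metrics as None.
    """
    nodes = read_result_nodes(result_path)
    complexes = read_complexes(complexes_path)
    annotated = None
    if annotations_path is not None and annotated_term is not None:
        ann = read_annotations(annotations_path)
        annotated = ann.term_to_proteins.get(annotated_term, frozenset())
    return evaluate_result(
        nodes, complexes, m_t=m_t,
        annotated_nodes=annotated, fdr_pvalue=fdr_pvalue,
    )


def correspondence_matrix(
    query: Network, target: Network, sim: SimilarityTable,
    config: RunConfig | None = None,
) -> sp.csr_matrix:
    """Compute only the steady-state flow correspondence matrix."""
    config = config or RunConfig()
    walk = build_walk(query, target, sim)
    pi = stationary(walk, tol=config.power_tol, max_iter=config.power_max_iter)
    return correspondence(walk, pi.pi)
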