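"""Scoring of querying results against reference complexes and
annotations.

The match score between a result and a reference complex is the Jaccard
index of their node sets; a specific hit is a result whose best match
reaches the threshold m_t. Term informativeness is measured as
information content, -log2 of the term's annotation frequency relative to
its root ontology, and specificity is the fraction of result nodes carrying
the best-enriched term. Enrichment p-values are consumed from an external
test (FDR-corrected), never computed here.
"""

from __future__ import annotations

import json
import math
import operator
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

from .io import AnnotationTable, ComplexSet

#: default FDR-corrected p-value threshold for calling a hit
HIT_PVALUE_THRESHOLD = 0.01


def match_score(set_x: Iterable[str], set_y: Iterable[str]) -> float:
    """Jaccard similarity |X∩Y| / |X∪Y| between two protein sets."""
    x, y = set(set_x), set(set_y)
    if not x or not y:
        raise ValueError("match_score requires two non-empty sets")
    return len(x & y) / len(x | y)


def specific_hit(
    result_nodes: Iterable[str],
    complexes: ComplexSet,
    m_t: float = 0.5,
    comparator: Callable[[float, float], bool] = operator.ge,
) -> tuple[bool, tuple[str, float]]:
    """Classify a result as a specific hit and report its best match.

    The flag is true when the best match score over all reference complexes
    satisfies ``comparator(score, m_t)`` (>= by default, so a score exactly
    at the threshold counts).
    """
    if len(complexes) == 0:
        raise ValueError("empty complex set")
    result = set(result_nodes)
    best_name, best = None, -1.0
    for name, members in complexes.items():
        s = match_score(result, members)
        if s > best:
            best_name, best = name, s
    return comparator(best, m_t), (best_name, best)


def information_content(ann: AnnotationTable, term: str) -> float:
    """-log2(|g| / |root(g)|) for an annotated term."""
    if term not in ann.term_to_proteins:
        raise KeyError(f"term {term} not in annotation table")
    root = ann.term_to_root[term]
    root_size = ann.root_sizes[root]
    if root_size <= 0:
        raise ValueError(f"root {root} has no annotated proteins")
    return -math.log2(len(ann.term_to_proteins[term]) / root_size)


def informative_terms(ann: AnnotationTable, min_ic: float = 2.0) -> set[str]:
    """Terms whose information content strictly exceeds ``min_ic``."""
    return {
        t for t in ann.term_to_proteins
        if information_content(ann, t) > min_ic
    }


def specificity(result_nodes: Iterable[str], annotated_nodes: Iterable[str]) -> float:
    """Fraction of result nodes annotated with the best-enriched term."""
    result = set(result_nodes)
    if not result:
        raise ValueError("empty result")
    return len(result & set(annotated_nodes)) / len(result)


@dataclass
class MetricReport:
    """All metrics computable for one querying result; optional fields stay
    None when their inputs (annotations, p-values) were not supplied."""

    match_scores: dict[str, float]
    best_match: tuple[str, float]
    is_specific_hit: bool
    specificity: float | None = None
    is_hit: bool | None = None
    is_meaningful_hit: bool | None = None
    extras: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "match_scores": dict(sorted(self.match_scores.items())),
            "best_match": {"complex": self.best_match[0], "score": self.best_match[1]},
            "is_specific_hit": self.is_specific_hit,
            "specificity": self.specificity,
            "is_hit": self.is_hit,
            "is_meaningful_hit": self.is_meaningful_hit,
            **self.extras,
        }
        text = json.dumps(payload, indent=1, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_tsv_row(self) -> str:
        def fmt(v):
            return "NA" if v is None else (f"{v:.6g}" if isinstance(v, float) else str(v))
        return "\t".join([
            self.best_match[0], fmt(self.best_match[1]), fmt(self.is_specific_hit),
            fmt(self.specificity), fmt(self.is_hit), fmt(self.is_meaningful_hit),
        ])


def evaluate_result(
    result_nodes: Iterable[str],
    complexes: ComplexSet,
    m_t: float = 0.5,
    annotated_nodes: Iterable[str] | None = None,
    fdr_pvalue: float | None = None,
    result_connected: bool = True,
    comparator: Callable[[float, float], bool] = operator.ge,
) -> MetricReport:
    """Compute every metric the supplied inputs allow.

    Hit flags need an externally computed FDR-corrected enrichment p-value;
    a meaningful hit additionally requires the result to be connected.
    """
    result = set(result_nodes)
    scores = {name: match_score(result, members) for name, members in complexes.items()}
    flag, best = specific_hit(result, complexes, m_t=m_t, comparator=comparator)
    spec = None
    if annotated_nodes is not None:
        spec = specificity(result, annotated_nodes)
    is_hit = is_meaningful = None
    if fdr_pvalue is not None:
        is_hit = fdr_pvalue < HIT_PVALUE_THRESHOLD
        is_meaningful = bool(is_hit and result_connected)
    return MetricReport(
        match_scores=scores,
        best_match=best,
        is_specific_hit=flag,
        specificity=spec,
        is_hit=is_hit,
        is_meaningful_hit=is_meaningful,
    )
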