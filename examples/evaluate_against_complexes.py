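"""Scoring a querying result against reference complexes and annotations.

Shows the match score / specific-hit classification, term information
content, and the specificity of a result given the best-enriched term's
annotation set.
"""

from netquery import (
    AnnotationTable,
    ComplexSet,
    evaluate_result,
    information_content,
    informative_terms,
)

result_nodes = {"t1", "t2", "t3", "t4"}

complexes = ComplexSet((
    ("proteasome_lid", frozenset({"t1", "t2", "t3", "t4", "t5"})),
    ("unrelated", frozenset({"x1", "x2"})),
))

report = evaluate_result(
    result_nodes,
    complexes,
    annotated_nodes={"t1", "t2", "t3"},  # members of the best-enriched term
    fdr_pvalue=0.004,                    # from an external enrichment test
    result_connected=True,
)
print(f"best match: {report.best_match[0]} "
      f"(match score {report.best_match[1]:.2f})")
print(f"specific hit (m_t = 0.5): {report.is_specific_hit}")
print(f"specificity: {report.specificity:.2f}")
print(f"hit / meaningful hit: {report.is_hit} / {report.is_meaningful_hit}")

# information content separates informative terms from near-root ones
ann = AnnotationTable(
    term_to_proteins={"GO:small": frozenset({"t1"}),
                      "GO:broad": frozenset({f"t{i}" for i in range(1, 9)})},
    term_to_root={"GO:small": "BP", "GO:broad": "BP"},
    root_sizes={"BP": 16},
)
for term in ("GO:small", "GO:broad"):
    print(f"IC({term}) = {information_content(ann, term):.2f}")
print("terms kept by the IC > 2 filter:", informative_terms(ann))
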