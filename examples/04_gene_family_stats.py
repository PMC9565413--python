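"""Gene-annotation statistics on toy tables with planted signal.

Runs the transposon-domain filter (a gene is dropped when strictly more
than half its Pfam domains look transposon-derived), the unsupported-gene
filter, per-domain expansion/contraction z-scores for a focal species, and
hypergeometric term enrichment with Benjamini-Hochberg FDR control.
"""

from orginsert import (
    filter_unsupported_genes,
    flag_transposon_genes,
    hypergeometric_enrichment,
    pfam_zscores,
    simulate_annotation_tables,
)

tables = simulate_annotation_tables(seed=11)

flagged = flag_transposon_genes(tables.domain_annotations)
print(f"transposon filter: {len(flagged)} of {len(tables.domain_annotations)} genes flagged "
      f"(planted: {len(tables.transposon_gene_ids)})")

removed = filter_unsupported_genes(tables.evidence)
print(f"support filter: {len(removed)} genes lack both external support and "
      f"functional annotation (planted: {len(tables.unsupported_gene_ids)})")

zs = pfam_zscores(tables.matrix)  # baseline excludes the focal species
expanded = zs[zs["call"] == "expanded"]
print(f"z-scores: {len(expanded)} domains expanded at |z| > 1.96, e.g.")
print(expanded[["count_focal", "mean", "sd", "z"]].head(3).to_string())

results = hypergeometric_enrichment(
    tables.study_genes, tables.background_genes, tables.term_map
)
top = results[0]
print(
    f"enrichment: top term {top.term_id} with {top.study_hits}/{top.study_size} study "
    f"vs {top.background_hits}/{top.background_size} background genes, "
    f"p_adj = {top.p_adjusted:.2e} ({'significant' if top.significant else 'not significant'})"
)
# A z-score above 1.96 marks a domain family whose copy number in the focal
# species sits outside the 95% band of the cross-species distribution.
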