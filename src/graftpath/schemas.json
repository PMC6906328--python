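{
  "activity_within_subject.tsv": ["pathway_id", "name", "category", "comparison", "statistic", "direction", "p_value", "n_genes_tested", "testable"],
  "activity_between_subject.tsv": ["pathway_id", "name", "category", "comparison", "statistic", "direction", "p_value", "n_genes_tested", "testable"],
  "glpap_pathways.tsv": ["pathway_id", "name", "category"],
  "category_enrichment.tsv": ["category", "p_value", "glpap_in_category", "glpap_not_in_category", "other_in_category", "other_not_in_category"],
  "pathway_network_edges.tsv": ["pathway_a", "pathway_b", "weight"],
  "pathway_network_nodes.tsv": ["pathway_id", "name", "category", "closeness", "degree"],
  "central_pathways.tsv": ["pathway_id", "name", "category", "closeness", "degree"],
  "hypothesis_evaluation.tsv": ["hypothesis", "n_seeds", "coefficient", "p_value", "empirical_p"],
  "hypothesis_evaluation_topk.tsv": ["hypothesis", "top_k", "coefficient", "p_value"]
}
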