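# Example biomarker-drug indication predicates, in the format
# pharmsig.biomarkers.load_predicates expects. Each entry encodes one
# FDA-style indication as a machine-checkable rule; cohort_filter values are
# tumor_site labels in the annotation table (empty / omitted = pan-cancer).
- name: EGFR-mutant lung adenocarcinoma / Erlotinib
  drug: Erlotinib
  rule: mutation_in_genes
  genes: [EGFR]
  cohort_filter: [LUAD]
  expected_direction: marker_more_sensitive
- name: BRAF V600E/K melanoma / Dabrafenib
  drug: Dabrafenib
  rule: variant_match
  genes: [BRAF]
  protein_changes: [V600E, V600K]
  cohort_filter: [SKCM]
  expected_direction: marker_more_sensitive
- name: KRAS wild-type colon cancer / Cetuximab
  drug: Cetuximab
  rule: wildtype_in_genes
  genes: [KRAS]
  cohort_filter: [COAD]
  expected_direction: marker_more_sensitive
- name: EGFR-expressing colon cancer / Cetuximab
  drug: Cetuximab
  rule: expression_above_quantile
  genes: [EGFR]
  quantile: 0.5
  cohort_filter: [COAD]
  expected_direction: marker_more_resistant
- name: HER2-positive breast cancer / Lapatinib
  drug: Lapatinib
  rule: annotation_flag
  flag: her2_positive
  cohort_filter: [BRCA]
  expected_direction: marker_more_sensitive
- name: MGMT-methylated glioblastoma / Temozolomide
  drug: Temozolomide
  rule: annotation_flag
  flag: mgmt_methylated
  cohort_filter: [GBM]
  expected_direction: marker_more_sensitive
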