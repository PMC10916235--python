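{
  "seed": 42,
  "n_genes": 50,
  "n_causal": 5,
  "counts": {
    "genes_in": 50,
    "eqtl_records": 2500,
    "gwas_records": 2500,
    "blocklist_snps": 0,
    "druggable_genes_with_eqtl": 50,
    "genes_with_instruments": 50,
    "instruments_selected": 63,
    "instruments_harmonized": 63,
    "instruments_dropped": 0,
    "genes_tested": 50,
    "genes_mr_significant": 5,
    "genes_colocalized": 5,
    "targets_prioritized": 5,
    "drug_candidates": 5
  }
}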