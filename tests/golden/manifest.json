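{
  "config": {
    "annotation": "sim/annotation.tsv",
    "both_strands": true,
    "correction": "bonferroni",
    "counts": "sim/counts.tsv",
    "first_called_only": false,
    "gene_models": null,
    "genome": null,
    "k": 100,
    "motif": "CTCGAR",
    "mutant_strain": "xbp1",
    "post_ds_timepoints": [
      "18",
      "24",
      "48",
      "Q"
    ],
    "profiles": "sim/profiles.tsv",
    "promoters": "sim/promoters.fa",
    "pseudocount": 0.5,
    "ratio_basis": "size_factors",
    "ratio_mode": "ratio_of_means",
    "screen_seed_genes": [
      "g001",
      "g022",
      "g023"
    ],
    "seed": 5,
    "threshold_fold": 3.0,
    "wildtype_strain": "wt",
    "window": 800
  },
  "config_sha256": "787812e77503f1026ee9568a6e2f7cda37822b2fbf2552100fdbaa13e381a270",
  "outputs": [
    "consensus.tsv",
    "enrichment.tsv",
    "screen.tsv",
    "targets.tsv",
    "timepoint_18.tsv",
    "timepoint_24.tsv",
    "timepoint_48.tsv",
    "timepoint_Q.tsv"
  ],
  "package": "qrepress",
  "seed": 5,
  "summary": {
    "fraction_direct": 0.666667,
    "n_derepressed": 45,
    "n_direct": 30,
    "n_genes": 201,
    "n_indirect": 15,
    "n_underrepresented": 5
  },
  "version": "0.1.0"
}
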