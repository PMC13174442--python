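# Minimal end-to-end configuration: 300 genes, two mini-cohorts of 12.
seed: 7
generator:
  n_genes: 300
  panel_size: 200
  mini_cohorts:
    - [NS-A, nanostring, 12]
    - [RS-A, rnaseq, 12]
  n_planted_pfs_genes: 6
  n_planted_assay_genes: 6
feature_selection:
  B: 50
  top_m: 50
  max_features: 10
double_assay_n: 12
network:
  n_genes: 80
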