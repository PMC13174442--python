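# Full study conditions: six mini-cohorts (140 patients), 770-gene panel.
seed: 1
generator: {}          # generator defaults are the study conditions
feature_selection:
  B: 200
  top_m: 100
  max_features: 25
double_assay_n: 24
network:
  n_genes: 300
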