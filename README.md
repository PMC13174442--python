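# xassay — cross-assay paired log2FC harmonization and recurrence prediction

Small cancer cohorts are scattered across transcriptomic platforms —
bulk RNA-seq, NanoString panels, microarray, single-cell RNA-seq — and no
single platform's cohorts are large enough for reliable biomarker discovery.
`xassay` implements a pipeline for combining such cohorts when patients have
matched pre- and post-chemotherapy samples: working on the paired
fold-change scale removes patient- and much assay-specific bias, and a
double-assay design (the same samples measured by two platforms) lets the
pipeline estimate where each assay stops being trustworthy.

For gene g and patient p the feature is the paired log2 fold-change

    log2FC(g, p) = log2(post(g, p) + c) − log2(pre(g, p) + c)

with pseudocount c (default 1 on the CPM scale). The pipeline:

1. **Harmonizes** RNA-seq and NanoString via per-gene Spearman correlation
   across double-assayed samples, classifies genes as consistently
   concordant (ρ ≥ 0.85 under all preprocessing variants), consistently
   discordant, or preprocessing-dependent, and estimates **limits of
   detection**: expression/range levels where binned median ρ starts
   declining (loose) or falls below 0.7 (strict).
2. **Selects features** by bootstrap stability: patients are resampled
   class-balanced with weights ∝ 1/|mini-cohort|; per draw, the top-m genes
   by one-way ANOVA F-score are recorded; a gene's *predictive frequency* is
   the fraction of draws in which it appears. The top 25 candidates (after
   optional detection-limit filtering) enter modeling.
3. **Models** the progression-free-survival class (PFS > 12 vs ≤ 12 months)
   with LASSO/ridge logistic regression and a linear SVM; leave-one-out
   cross-validation picks the panel size k and architecture; a stratified
   hold-out (max(10, 10 % of patients)) gives the honest AUROC. The same
   machinery probes assay bias by predicting NanoString vs RNA-seq identity
   from log2FC alone.
4. **Validates** externally: per-cohort directionality of class-median
   log2FC differences (microarray cohorts verify, never train), univariate
   Cox proportional hazards and Kaplan-Meier median splits on survival,
   and per-cell-type pseudobulk log2FC against log(PFI + 1).
5. **Contrasts co-expression**: unsigned WGCNA-style networks
   (a_ij = |cor|^β, β = 6) with topological-overlap (TOM) similarity,
   comparing a focal gene's neighborhood pre- vs post-treatment.

Everything runs end to end on a synthetic multi-assay cohort generator with
known ground truth (planted PFS effects, planted assay biases, per-assay
detection floors, microarray dynamic-range compression, single-cell capture
sparsity), so every stage has recovery tests.

## Worked example

```bash
python analysis/01_simulate_cohorts.py
python analysis/04_train_models.py
```

prints (seed 1):

```
Simulated study design:
  patients_per_cohort: {'NS-A': 35, 'NS-B': 17, 'NS-C': 31, 'RS-A': 15, 'RS-B': 20, 'RS-C': 22}
  total_patients: 140
  panel_size: 770
  n_planted_pfs_genes: 12
  ...
PFS model: k=5 (svm), train AUROC=0.962, hold-out AUROC=0.918
Planted-biomarker recovery in candidates: 100%
Assay-identity probe: hold-out AUROC 1.00 unfiltered -> 0.77 after LOD filtering
```

Reading: six mini-cohorts (three NanoString, three RNA-seq, 140 patients)
are combined on a 770-gene panel; the bootstrap recovers all 12 planted PFS
biomarkers into the 25-gene candidate list; LOOCV settles on a 5-gene
linear-SVM model whose hold-out AUROC is 0.92; and the assay-identity classifier —
which initially separates the platforms perfectly by exploiting planted
below-floor bias genes — loses most of its signal once candidates are
filtered by the estimated limits of detection.

The other drivers (`02_harmonize_assays.py`, `03_select_features.py`,
`05_external_validation.py`, `06_tom_networks.py`) run the double-assay
harmonization, frequency-table comparisons, survival validation and network
contrast; all write tables under `results/`.

A config-driven CLI wraps the same stages:

```bash
xassay run-all --config configs/smoke.yaml --outdir results/smoke --seed 7
```

## Layout

```
src/xassay/       library: synth, io, normalize, harmonize, features,
                  model, validate, network, workflows, pipeline, cli
analysis/         numbered narrative drivers (simulate → ... → networks)
tests/            pytest suite incl. statistical acceptance checks
scripts/          acceptance.py
docs/methods.md   model and procedure documentation
configs/          example pipeline configs
```
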