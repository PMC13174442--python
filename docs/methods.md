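# Methods

This note documents the models and procedures implemented in `xassay`, the
defaults they use, and what the synthetic-data experiments do and do not
demonstrate.

## The paired fold-change feature space

All modeling operates on per-patient paired log2 fold-changes,
`log2(post + c) − log2(pre + c)`, computed after counting-mode aggregation
and normalization, in that fixed order (aggregate → normalize → log2FC;
normalizing before aggregating gives different numbers and is not
supported). The default pseudocount is c = 1 on the CPM scale: it keeps
log2FC finite and antisymmetric under swapping timepoints, and bounds the
fold-change a zero count can produce. Count assays (RNA-seq, NanoString)
are CPM-normalized before log2FC; microarray intensities are used directly
(their scale cancels in the ratio); within-assay scaling (percentile by
midrank, or z-score) is available but the pipeline's default is *unscaled*
log2FC, because percentile scaling presumes comparable dynamic ranges
across assays — exactly what the dynamic-range diagnostic shows microarray
violates. Constant genes scale to 0.5 (percentile) or 0 (z-score).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes; it
is the test bed for every downstream stage.

**Abundance model.** Per-gene natural-log mean μ_g ~ N(4, 2) on a CPM-like
scale (heavy-tailed, transcriptome-like). Latent abundance for patient p:
`ln A = μ_g + u_{g,p} + ε_{g,p,t}` with a patient random effect
u ~ N(0, 0.5²) shared by both timepoints (so it cancels in log2FC) and a
per-timepoint residual ε ~ N(0, 0.5²). The residual choice gives a paired
log2FC standard deviation of ≈ 1.0 (IQR ≈ 1.4 log2 units), matching the
spread seen in real pre/post-chemotherapy tumor pairs. Genes are
independent given the patient effect; real co-expression structure is not
emulated (networks are exercised on the correlation the patient effects and
cell-type signatures induce, plus planted modules in tests).

**Study layout.** Defaults: six mini-cohorts — three NanoString (35, 17,
31 patients) and three RNA-seq (15, 20, 22), 140 patients total — sharing a
770-gene panel; every patient contributes exactly one pre and one post
sample. A separate double-assay design measures the same 24 samples with
both RNA-seq (isoform- and exon-level) and NanoString (probe isoform only).

**Planted effects.** PFS classes are assigned balanced within each
mini-cohort (to within one patient). Post-treatment abundance of each of 12
planted PFS genes is multiplied by `2^(±1.5 · m_p)` for long-PFS patients,
where m_p ~ U(0.5, 1.5) is a per-patient effect magnitude; the ±1.5 log2
default is the *strong* preset, per-gene Cohen's d ≈ 1.5 against the log2FC
noise. PFS months are drawn class-consistently — long: 12 + Exp with scale
increasing in the patient's planted-gene signal; short: 12·logistic(signal
+ noise) ∈ (0, 12) — so the planted log2FC is monotonically associated with
PFS while the class balance invariant holds exactly. Twelve planted assay
genes carry a constant per-assay *fold-change* bias (post multiplied by
`2^(±2)` in NanoString cohorts only): a constant expression offset would
cancel in the post/pre ratio and leave nothing for the assay-identity probe
to detect. A config switch places assay genes in a narrow band just below
the detection floor for the bias-probe experiment.

**Measurement models.**

- *Count assays.* `λ = eff · A · gate(A) + bg`, with efficiency 20 counts
  per CPM-unit (sequencing-depth-like), background `bg = eff · floor`, and
  a Hill-type capture gate `gate(A) = A⁴ / (A⁴ + floor⁴)` that collapses
  capture efficiency below the assay's detection floor (default 10) — the
  operational meaning of a detection floor: sub-floor genes are
  background-dominated. Count noise is Gaussian with sd
  `√λ · measurement_noise` (Poisson-like; `measurement_noise = 0` gives the
  exact deterministic identity `measured = eff · A`, used by contract
  tests).
- *Microarray.* The strictly monotone concave transform `A^c` (slope c on
  the log scale; default compression c = 1, diagnostics use 0.5) plus
  log-normal intensity noise of sd 0.05 ln-units (~5 % CV, typical array
  replicate precision — the platform's emulated weakness is dynamic-range
  compression, not imprecision).
- *scRNA-seq.* 200 cells/sample, 4 cell types with Dirichlet(4)
  proportions, per-type log-normal signature multipliers on ~20 % of genes,
  per-cell totals Poisson(2000), and multinomial capture with probability
  ∝ A^(1+0.3) — the +0.3 capture exponent reproduces preferential capture
  of high expressors. Cells carry type labels for pseudobulking.

All randomness flows from one seed through named sub-streams (one per
mini-cohort), so regenerating a cohort subset reproduces identical data.

## Limits of detection

From the double-assay design, per-gene midrank Spearman ρ between the two
platforms is computed across samples for each (counting mode ×
normalization) variant. Genes are placed into 10 quantile bins of median
expression (and, separately, of per-gene IQR); scanning from the
highest-expression bin downward, the *loose* cutoff is the lower edge of
the first bin whose median ρ falls more than 0.05 below the median ρ of the
top three bins, and the *strict* cutoff is the lower edge of the first bin
whose median ρ falls below 0.7. No decline → cutoff 0. The two criteria are
independent; neither bounds the other. Quantile binning makes the below-
cutoff gene set invariant to any strictly monotone rescaling of the
expression axis — which is also how cutoffs are transferred between data
sets with different CPM library factors (quantile mapping), and how
recovery is assessed against the generator's planted floor (bin-index
distance ≤ 1 on the quantile scale).

Candidate filtering removes genes whose median training expression falls
below the *larger* of the strict and loose expression cutoffs: the loose
limit marks where cross-assay correlation starts declining, so genes below
either limit are untrustworthy; a gene below the strict limit is always
excluded.

Concordance classes use the 0.85 threshold: `consistent_high` if ρ ≥ 0.85
under every preprocessing variant, `consistent_low` if below under every
variant, else `preprocessing_dependent`. A counting mode is flagged better
for a gene when it improves ρ by > 0.05 in at least two of the three
normalizations (CPM, RPKM, TPM).

## Feature selection

The per-gene statistic is the one-way ANOVA F on log2FC against the binary
outcome, computed by a vectorised closed form (zero within-class variance
with unequal means yields an +inf sentinel, logged). The *bootstrap*
strategy draws, per replicate, n_min patients with replacement within each
class (n_min = smaller class size, keeping classes balanced), with
per-patient probability ∝ 1/|mini-cohort| normalized within the class —
equalizing expected cohort representation while preserving class balance.
Per draw the top-m genes (m = 100 for transcriptome-scale spaces, 50 for
panel-scale; ties by gene id) are recorded; a gene's predictive frequency
is its inclusion fraction over B = 200 draws. Candidates are the top 25 by
(frequency, mean F, gene id). The *consensus* strategy intersects each
mini-cohort's top-k genes by F-score. All ties everywhere break by
ascending gene id, guaranteeing run-to-run determinism.

## Modeling

Hold-out: max(10, ⌈10 % N⌉) patients chosen by greedy stratified allocation
that minimizes the summed squared deviation of hold-out class, mini-cohort
and PFS-tertile proportions from the cohort proportions; final marginals
match proportional targets to within one patient per stratum. Feature
selection and LOOCV touch training patients only.

Architectures: logistic regression with LASSO (liblinear) or ridge
(Newton-Cholesky) regularization, and a linear-kernel SVM (linear so
coefficients stay comparable across architectures). LOOCV evaluates every
k in 1..25 for every architecture, pooling leave-one-out decision scores
into one AUROC; the maximizer wins, ties preferring smaller k, then
lasso < ridge < svm. Regularization uses the standard default C = 1 during
LOOCV (the API accepts a grid; with n ≈ 126 and k ≤ 25 the (k,
architecture) surface, not C, is the operative choice, and a 3-point grid
triples runtime without changing the winner in our simulations). A
degenerate leave-one-out fold (single-class remainder) scores the held
patient at the prior rate, logged. AUROC uses midrank ties (the
Mann-Whitney U identity is asserted in tests); raw decision scores are
used, with no probability calibration. The PFS dichotomy is fixed at 12
months even when a synthetic cohort's median differs: the threshold, not
the quantile, is the contract.

## External validation

Directionality: per mini-cohort, the difference of class-median log2FC
(long − short) with Welch t-tests (tiers • < 0.1, * < 0.05, ** < 0.01,
*** < 0.001); consistency over cohorts is `all_agree` / `one_disagrees` /
`inconsistent` from the sign vector, invariant to positive per-cohort
rescaling. Microarray cohorts enter only validation, never training.
Survival: univariate Cox proportional hazards per gene (lifelines, Efron
ties) on standardized expression with BH adjustment within cohort;
Kaplan-Meier median splits (ties to the low group) with two-sided log-rank
tests. Cell-state context: per-cell-type pseudobulk log2FC regressed on
log(PFI + 1), reporting Spearman ρ and the OLS slope p. Note the generator
plants *fold-change* effects, so pre-treatment-expression Cox fits on
synthetic microarray cohorts demonstrate calibration (nominal CI coverage,
reciprocal HR under sign flip), not power.

## TOM networks

Unsigned adjacency `a_ij = |Pearson cor|^β` with β = 6 (the standard
soft-threshold default for unsigned networks) on log2(CPM + 1); constant
genes are dropped. Topological overlap
`TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
diagonal 1 (verified against triple-loop brute force to 1e-12). The focal
contrast classifies genes by `Δ = TOM_post − TOM_pre` against the focal
gene and `max TOM`: genes above the 0.9 quantile of max TOM are partners;
partners whose |Δ| stays within the 0.9 quantile of |Δ| over *all* genes
are `shared`, the rest `post_only`/`pre_only` by sign. The |Δ| reference is
all genes so that a single strongly rewired partner cannot set its own
threshold. Single-cell networks use per-cell-type pseudobulk correlation
(a deliberate replacement for metacell construction; documented
divergence), and on synthetic data the bulk focal TOM row correlates best
with the driving cell type's pseudobulk TOM row.

## Pipeline

Stages run simulate → harmonize → select → train → validate → network from
one YAML config (exactly one of generator settings or input paths); one
seed fans out to per-stage sub-streams. Every output file is SHA-256
checksummed into `manifest.json`; rerunning the same config reproduces
identical checksums (gzip members are written with a fixed timestamp).
Reports are emitted as markdown + JSON with numbers identical to the stage
tables.

## Problem sizes and what the tests show

The statistical acceptance tests run at the study's own scale: 140
patients/770-gene panel for biomarker recovery (20 replicates, plus 10
label permutations for the null), 1000 genes/24 samples for detection-floor
recovery (50 replicates), 500 null simulations at n = 100 for Cox CI
coverage, and n = 200 for log-rank power; the acceptance script reports the
same quantities at moderately reduced replicate counts. Passing these shows
the procedures recover what the generator planted under its assumptions —
independent genes, log-normal abundance, the stated measurement models. It
does not certify performance on real cohorts, where co-expression,
batch-by-cohort confounding, and non-log-normal tails are all present and
none is emulated.

## Known limitations

- Genes are independent given patient effects; predictive-frequency
  correlations between outcomes are therefore cleaner than in real data.
- The assay bias is planted as a fold-change offset; purely additive
  expression offsets (which cancel in log2FC) are represented only through
  the detection-floor mechanism.
- The exact strict/loose cutoff values depend on the binning resolution;
  they are estimates of a change point, not of the physical floor itself.
- Survival generation ties hazard to planted log2FC only; baseline
  expression carries no survival signal by construction.
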