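"""Synthetic multi-cohort, multi-assay paired pre/post expression generator.

Emulates the statistical structure the downstream analysis assumes: several
mini-cohorts of unequal size across assays, one pre and one post sample per
patient, log-normal gene baselines with patient random effects, planted
PFS-associated log2 fold-change effects, planted assay-discriminative
fold-change biases, per-assay detection floors with additive measurement
background, microarray dynamic-range compression, and single-cell capture
sparsity.  Every quantity a recovery test needs is recorded in
:class:`SyntheticTruth`.

Measurement model
-----------------
Count assays (RNA-seq, NanoString) measure ``lam = efficiency * A * gate(A)
+ bg`` with ``bg = background_scale * detection_floor``, where ``gate(A) =
A^h / (A^h + floor^h)`` is a Hill-type capture-efficiency collapse below the
assay's detection floor (steepness ``detection_gate_hill``): genes below the
floor are background-dominated, which is what a detection floor means here.
Count noise is Gaussian with standard deviation ``sqrt(lam) *
measurement_noise`` — a Poisson-like model whose noise scale can be set
exactly to zero (then ``measured = efficiency * A``, with no gate or
background, so the identity contract holds).
Microarray applies the strictly monotone concave power transform
``A ** microarray_compression`` on the natural scale (slope
``microarray_compression`` on the log scale) plus log-normal intensity noise.
scRNA-seq draws per-cell multinomial captures with per-gene capture
efficiency proportional to ``abundance ** capture_power``, so high expressors
are preferentially captured; cells carry type labels for later pseudobulking.

Planted effects
---------------
PFS classes are assigned balanced within each mini-cohort (to within one
patient).  Post-treatment abundance of each planted PFS gene is multiplied by
``2 ** (sign * pfs_effect_size * m_p)`` for long-PFS patients, where ``m_p``
is a per-patient effect magnitude; PFS months are then drawn from
class-consistent truncated exponentials whose scale is monotone in the
patient's planted-gene mean log2FC, so the planted signal is monotonically
associated with PFS.  Planted assay genes carry a constant per-assay
fold-change bias: in NanoString cohorts their post sample is multiplied by
``2 ** (sign * assay_offset)``, shifting log2FC by a constant amount in one
assay only (a constant *expression* offset would cancel in the post/pre
ratio and leave nothing for the assay-identity probe to find).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneModel, SampleMeta

log = logging.getLogger(__name__)

LN2 = float(np.log(2.0))

#: Mini-cohort layout of the default study conditions: three NanoString and
#: three RNA-seq cohorts totaling 140 patients.
DEFAULT_MINI_COHORTS: tuple[tuple[str, str, int], ...] = (
    ("NS-A", "nanostring", 35),
    ("NS-B", "nanostring", 17),
    ("NS-C", "nanostring", 31),
    ("RS-A", "rnaseq", 15),
    ("RS-B", "rnaseq", 20),
    ("RS-C", "rnaseq", 22),
)

DEFAULT_DETECTION_FLOOR: dict[str, float] = {
    "rnaseq": 10.0,
    "nanostring": 10.0,
    "microarray": 10.0,
    "scrnaseq": 10.0,
}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    Abundances live on a CPM-like scale with per-gene natural-log means drawn
    from N(4, 2).  All log2-unit parameters (``pfs_effect_size``,
    ``assay_offset``) act multiplicatively as ``2 ** value``.
    """

    n_genes: int = 2000
    mini_cohorts: Sequence[tuple[str, str, int]] = DEFAULT_MINI_COHORTS
    panel_size: int = 770
    n_planted_pfs_genes: int = 12
    pfs_effect_size: float = 1.5
    n_planted_assay_genes: int = 12
    assay_offset: float = 2.0
    detection_floor: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_FLOOR)
    )
    microarray_compression: float = 1.0
    isoforms_per_gene: int = 3
    patient_effect_sd: float = 0.5
    residual_sd: float = 0.5
    seed: int = 0
    # measurement model knobs
    measurement_noise: float = 1.0     # 0 => deterministic measured = eff * A
    efficiency: float = 20.0           # count scale per unit abundance
    background_scale: float = 1.0      # background = efficiency * scale * floor
    detection_gate_hill: float = 4.0   # capture collapse steepness below the floor
    intensity_noise_sd: float = 0.05   # microarray log-intensity noise (x measurement_noise)
    assay_genes_below_floor: bool = False
    # single-cell knobs
    cells_per_sample: int = 200
    umis_per_cell: int = 2000
    n_cell_types: int = 4
    capture_power: float = 0.3
    celltype_signature_sd: float = 0.8
    # isoform usage variability (double-assay design)
    variable_usage_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for name, assay, n in self.mini_cohorts:
            if n < 2:
                raise ValueError(f"mini-cohort {name!r} has fewer than 2 patients")
            if assay not in ("rnaseq", "nanostring", "microarray", "scrnaseq"):
                raise ValueError(f"unknown assay {assay!r} in mini-cohort {name!r}")
        if self.panel_size > self.n_genes:
            raise ValueError("panel_size cannot exceed n_genes")
        if not (0 < self.microarray_compression <= 1):
            raise ValueError("microarray_compression must be in (0, 1]")
        if self.isoforms_per_gene < 1:
            raise ValueError("isoforms_per_gene must be >= 1")
        if self.patient_effect_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_planted_pfs_genes + self.n_planted_assay_genes > self.panel_size:
            raise ValueError("planted gene sets exceed the panel")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort, for recovery tests."""

    planted_pfs_genes: dict[str, float]      # gene -> signed effect (log2 units)
    planted_assay_genes: dict[str, float]    # gene -> signed offset (log2 units)
    true_detection_floor: dict[str, float]   # assay -> abundance threshold
    true_isoform_usage: dict[str, list[float]]
    pfs_class: dict[str, str]                # patient -> long / short
    seed: int
    baseline_log_mean: dict[str, float] = field(default_factory=dict)
    panel_genes: list[str] = field(default_factory=list)
    probe_isoform: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.planted_pfs_genes) & set(self.planted_assay_genes)
        if overlap:
            raise ValueError(f"planted gene sets overlap: {sorted(overlap)[:3]}")
        if any(v == 0 for v in self.planted_pfs_genes.values()):
            raise ValueError("planted PFS effects must be nonzero")
        if any(v == 0 for v in self.planted_assay_genes.values()):
            raise ValueError("planted assay offsets must be nonzero")

    def to_dict(self) -> dict:
        return {
            "planted_pfs_genes": self.planted_pfs_genes,
            "planted_assay_genes": self.planted_assay_genes,
            "true_detection_floor": self.true_detection_floor,
            "true_isoform_usage": self.true_isoform_usage,
            "pfs_class": self.pfs_class,
            "seed": self.seed,
            "panel_genes": self.panel_genes,
            "probe_isoform": self.probe_isoform,
        }


@dataclass
class SyntheticCohort:
    """Everything :func:`generate_cohort` produces."""

    matrices: dict[tuple[str, str], ExpressionMatrix]  # (cohort, timepoint) -> measured
    meta: SampleMeta
    gene_model: GeneModel
    truth: SyntheticTruth
    sc_counts: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = field(default_factory=dict)
    true_abundance: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# assay measurement models


def apply_assay_bias(
    true_abundance: pd.DataFrame,
    assay: str,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    celltype_profiles: np.ndarray | None = None,
):
    """Measure a latent gene × sample abundance matrix with one assay's model.

    With ``rng=None`` (or ``measurement_noise=0`` for count assays) the
    transform is deterministic: identity scaling for count assays, the pure
    compression power for microarray.  For ``assay="scrnaseq"`` returns
    ``(cell_counts, cell_labels)`` instead of a matrix; cells are labeled by
    type for later pseudobulking.
    """
    a = true_abundance.to_numpy(dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")

    if assay in ("rnaseq", "nanostring"):
        if rng is None or config.measurement_noise == 0:
            out = config.efficiency * a
        else:
            floor = config.detection_floor[assay]
            bg = config.efficiency * config.background_scale * floor
            # capture efficiency collapses below the detection floor
            # (Hill gate), so sub-floor genes are background-dominated
            h = config.detection_gate_hill
            with np.errstate(divide="ignore", invalid="ignore"):
                gate = np.where(a > 0, a**h / (a**h + floor**h), 0.0)
            lam_b = config.efficiency * a * gate + bg
            noise = rng.standard_normal(lam_b.shape)
            out = np.clip(lam_b + np.sqrt(lam_b) * config.measurement_noise * noise, 0, None)
        return pd.DataFrame(out, index=true_abundance.index, columns=true_abundance.columns)

    if assay == "microarray":
        out = np.power(np.clip(a, 1e-12, None), config.microarray_compression)
        if rng is not None and config.measurement_noise > 0:
            sd = config.intensity_noise_sd * config.measurement_noise
            out = out * np.exp(rng.standard_normal(out.shape) * sd)
        return pd.DataFrame(out, index=true_abundance.index, columns=true_abundance.columns)

    if assay == "scrnaseq":
        if rng is None:
            raise ValueError("scrnaseq measurement requires an rng")
        return _measure_single_cell(true_abundance, config, rng, celltype_profiles)

    raise ValueError(f"unknown assay {assay!r}")


def make_celltype_profiles(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-(gene, cell type) log-normal signature multipliers.

    A random ~20% of genes per type carry a multiplier with log-sd
    ``celltype_signature_sd``; the rest are 1.
    """
    g, t = config.n_genes, config.n_cell_types
    mask = rng.random((g, t)) < 0.2
    eff = np.exp(rng.standard_normal((g, t)) * config.celltype_signature_sd)
    return np.where(mask, eff, 1.0)


def _measure_single_cell(
    true_abundance: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator,
    celltype_profiles: np.ndarray | None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    genes = true_abundance.index
    if celltype_profiles is None:
        celltype_profiles = make_celltype_profiles(config, rng)
    if celltype_profiles.shape != (len(genes), config.n_cell_types):
        raise ValueError("celltype_profiles shape mismatch")
    type_names = [f"CT{t + 1}" for t in range(config.n_cell_types)]

    blocks, labels = [], []
    for sample in true_abundance.columns:
        a = true_abundance[sample].to_numpy(dtype=float)
        props = rng.dirichlet(np.full(config.n_cell_types, 4.0))
        n_by_type = rng.multinomial(config.cells_per_sample, props)
        for t, n_cells in enumerate(n_by_type):
            if n_cells == 0:
                continue
            weight = a * celltype_profiles[:, t] * np.power(np.clip(a, 1e-12, None),
                                                            config.capture_power)
            p = weight / weight.sum()
            totals = rng.poisson(config.umis_per_cell, size=n_cells)
            counts = np.stack([rng.multinomial(tot, p) for tot in totals], axis=1)
            for j in range(n_cells):
                labels.append((f"{sample}|{type_names[t]}|{j}", sample, type_names[t]))
            blocks.append(counts)
    cells = pd.DataFrame(
        np.concatenate(blocks, axis=1),
        index=genes,
        columns=[c[0] for c in labels],
    )
    label_df = pd.DataFrame(labels, columns=["cell_id", "sample_id", "cell_type"])
    return cells, label_df


# ---------------------------------------------------------------------------
# gene / isoform structure


def _build_gene_model(
    gene_ids: Sequence[str],
    panel_genes: Sequence[str],
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[GeneModel, dict[str, list[float]], dict[str, str]]:
    """Lay genes along one contig, give each isoform 1–3 exons, attach one
    probe (< 200 bp) per panel gene to a randomly chosen 'probe isoform'."""
    isoforms_of: dict[str, tuple[str, ...]] = {}
    exons_of: dict[str, tuple[tuple[str, int, int], ...]] = {}
    probe_of: dict[str, tuple[str, int, int]] = {}
    usage: dict[str, list[float]] = {}
    probe_iso: dict[str, str] = {}
    panel = set(panel_genes)
    pos = 0
    k = config.isoforms_per_gene
    for g in gene_ids:
        isos = tuple(f"{g}.{i + 1}" for i in range(k))
        isoforms_of[g] = isos
        locus_start = pos
        for iso in isos:
            n_exons = int(rng.integers(1, 4))
            exon_starts = np.sort(rng.integers(0, 5000, size=n_exons))
            exons = []
            cursor = locus_start
            for es in exon_starts:
                start = cursor + int(es) // max(n_exons, 1)
                length = int(rng.integers(100, 1500))
                exons.append(("chr1", start, start + length))
                cursor = start + length + 50
            exons_of[iso] = tuple(exons)
        pos += 10000
        u = rng.dirichlet(np.full(k, 5.0)) if k > 1 else np.array([1.0])
        usage[g] = [float(x) for x in u]
        if g in panel:
            chosen = isos[int(rng.integers(0, k))]
            probe_iso[g] = chosen
            exon = exons_of[chosen][int(rng.integers(0, len(exons_of[chosen])))]
            plen = min(int(rng.integers(60, 200)), exon[2] - exon[1])
            probe_of[g] = (exon[0], exon[1], exon[1] + plen)
    gm = GeneModel(isoforms_of=isoforms_of, exons_of=exons_of, probe_of=probe_of)
    return gm, usage, probe_iso


# ---------------------------------------------------------------------------
# main cohort generator


def _plant_genes(
    gene_ids: np.ndarray,
    mu: np.ndarray,
    panel_idx: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, float], dict[str, float]]:
    """Choose disjoint planted PFS and assay gene sets inside the panel.

    PFS genes come from well-expressed panel genes (above the panel's 60th
    abundance percentile) so that planted biomarkers are detectable by
    construction; assay genes are placed below the detection floor when
    ``assay_genes_below_floor`` is set, otherwise above it.
    """
    floor = config.detection_floor["nanostring"]
    panel_mu = mu[panel_idx]
    hi_cut = np.quantile(panel_mu, 0.6)
    pfs_pool = panel_idx[panel_mu >= hi_cut]
    if len(pfs_pool) < config.n_planted_pfs_genes:
        raise ValueError("not enough well-expressed panel genes to plant PFS effects")
    pfs_idx = rng.choice(pfs_pool, size=config.n_planted_pfs_genes, replace=False)

    remaining = np.setdiff1d(panel_idx, pfs_idx)
    rem_mu = mu[remaining]
    if config.assay_genes_below_floor:
        # a narrow band just below the floor: attenuated but not invisible
        pool = remaining[(rem_mu < np.log(0.95 * floor)) & (rem_mu > np.log(0.5 * floor))]
        if len(pool) < config.n_planted_assay_genes:
            pool = remaining[rem_mu < np.log(floor)]
    else:
        pool = remaining[rem_mu >= np.log(floor) + 0.5]
    if len(pool) < config.n_planted_assay_genes:
        raise ValueError("not enough panel genes in the requested abundance band")
    assay_idx = rng.choice(pool, size=config.n_planted_assay_genes, replace=False)

    signs_p = rng.choice([-1.0, 1.0], size=len(pfs_idx))
    signs_a = rng.choice([-1.0, 1.0], size=len(assay_idx))
    planted_pfs = {
        str(gene_ids[i]): float(s * config.pfs_effect_size)
        for i, s in zip(pfs_idx, signs_p)
    } if config.pfs_effect_size != 0 else {}
    planted_assay = {
        str(gene_ids[i]): float(s * config.assay_offset)
        for i, s in zip(assay_idx, signs_a)
    } if config.assay_offset != 0 else {}
    return planted_pfs, planted_assay


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate the full multi-cohort paired pre/post study.

    Deterministic given ``config.seed``; each mini-cohort draws from its own
    spawned random stream, so regenerating a subset of cohorts reproduces the
    same data.
    """
    root = np.random.SeedSequence(config.seed)
    ss_genes, ss_survival, *ss_cohorts = root.spawn(2 + len(config.mini_cohorts))
    rng_genes = np.random.default_rng(ss_genes)
    rng_surv = np.random.default_rng(ss_survival)

    gene_ids = np.array([f"G{i:04d}" for i in range(config.n_genes)])
    mu = 4.0 + 2.0 * rng_genes.standard_normal(config.n_genes)
    panel_idx = np.sort(rng_genes.choice(config.n_genes, size=config.panel_size, replace=False))
    panel_genes = [str(g) for g in gene_ids[panel_idx]]

    planted_pfs, planted_assay = _plant_genes(gene_ids, mu, panel_idx, config, rng_genes)
    gm, usage, probe_iso = _build_gene_model(gene_ids, panel_genes, config, rng_genes)

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    pfs_sign = np.zeros(config.n_genes)
    for g, eff in planted_pfs.items():
        pfs_sign[gene_index[g]] = eff            # signed log2 effect
    assay_sign = np.zeros(config.n_genes)
    for g, off in planted_assay.items():
        assay_sign[gene_index[g]] = off          # signed log2 offset

    matrices: dict[tuple[str, str], ExpressionMatrix] = {}
    true_abund: dict[tuple[str, str], pd.DataFrame] = {}
    sc_counts: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    meta_rows = []
    pfs_class: dict[str, str] = {}

    for (name, assay, n_pat), ss in zip(config.mini_cohorts, ss_cohorts):
        rng = np.random.default_rng(ss)
        patients = [f"{name}-P{j + 1:02d}" for j in range(n_pat)]
        # balanced class assignment (within one patient), shuffled
        classes = np.array(["long", "short"] * ((n_pat + 1) // 2))[:n_pat]
        rng.shuffle(classes)
        m_p = rng.uniform(0.5, 1.5, size=n_pat)  # per-patient effect magnitude

        pat_eff = rng.standard_normal((config.n_genes, n_pat)) * config.patient_effect_sd
        eps_pre = rng.standard_normal((config.n_genes, n_pat)) * config.residual_sd
        eps_post = rng.standard_normal((config.n_genes, n_pat)) * config.residual_sd

        log_pre = mu[:, None] + pat_eff + eps_pre
        shift = pfs_sign[:, None] * (classes == "long")[None, :] * m_p[None, :]
        log_post = mu[:, None] + pat_eff + eps_post + LN2 * shift
        if assay == "nanostring":
            log_post = log_post + LN2 * assay_sign[:, None]

        a_pre = pd.DataFrame(np.exp(log_pre), index=gene_ids,
                             columns=[f"{p}-pre" for p in patients])
        a_post = pd.DataFrame(np.exp(log_post), index=gene_ids,
                              columns=[f"{p}-post" for p in patients])
        if assay in ("nanostring", "microarray"):
            a_pre, a_post = a_pre.loc[panel_genes], a_post.loc[panel_genes]
        true_abund[(name, "pre")] = a_pre
        true_abund[(name, "post")] = a_post

        if assay == "scrnaseq":
            profiles = make_celltype_profiles(config, rng)
            cells_pre, lab_pre = apply_assay_bias(a_pre, assay, config, rng, profiles)
            cells_post, lab_post = apply_assay_bias(a_post, assay, config, rng, profiles)
            cells = pd.concat([cells_pre, cells_post], axis=1)
            labels = pd.concat([lab_pre, lab_post], ignore_index=True)
            sc_counts[name] = (cells, labels)
            for tp, block in (("pre", cells_pre), ("post", cells_post)):
                lab = lab_pre if tp == "pre" else lab_post
                keys = lab.set_index("cell_id").loc[block.columns, "sample_id"]
                bulk = block.T.groupby(keys.to_numpy()).sum().T
                matrices[(name, tp)] = ExpressionMatrix(bulk, "raw_count", "scrnaseq")
        else:
            unit = "intensity" if assay == "microarray" else "raw_count"
            m_pre = apply_assay_bias(a_pre, assay, config, rng)
            m_post = apply_assay_bias(a_post, assay, config, rng)
            matrices[(name, "pre")] = ExpressionMatrix(m_pre, unit, assay)
            matrices[(name, "post")] = ExpressionMatrix(m_post, unit, assay)

        # survival, monotone in the sign-aligned planted-gene mean log2FC
        # (long-PFS patients carry effect * m_p on every planted gene)
        s_p = np.abs(config.pfs_effect_size) * m_p * (classes == "long")
        for j, p in enumerate(patients):
            pfs_class[p] = str(classes[j])
            if classes[j] == "long":
                months = 12.0 + rng_surv.exponential(12.0 * np.exp(0.35 * s_p[j]))
            else:
                months = 12.0 / (1.0 + np.exp(-(0.8 * s_p[j] + rng_surv.standard_normal())))
            event = int(rng_surv.random() < 0.85)
            obs = months if event else months * rng_surv.uniform(0.5, 1.0)
            os_months = obs + rng_surv.exponential(20.0)
            pfi = max(obs * rng_surv.uniform(0.4, 0.8), 0.0)
            for tp in ("pre", "post"):
                sid = f"{p}-{tp}"
                if assay == "scrnaseq":
                    sid = f"{p}-{tp}"  # pseudobulk sample columns use the same ids
                meta_rows.append({
                    "sample_id": sid,
                    "patient_id": p,
                    "mini_cohort": name,
                    "assay": assay,
                    "timepoint": tp,
                    "pfs_months": round(float(obs), 3),
                    "pfs_event": event,
                    "pfi_months": round(float(pfi), 3),
                    "pfi_event": event,
                    "os_months": round(float(os_months), 3),
                    "os_event": int(rng_surv.random() < 0.7),
                    "age": int(rng_surv.integers(45, 80)),
                })

    truth = SyntheticTruth(
        planted_pfs_genes=planted_pfs,
        planted_assay_genes=planted_assay,
        true_detection_floor=dict(config.detection_floor),
        true_isoform_usage=usage,
        pfs_class=pfs_class,
        seed=config.seed,
        baseline_log_mean={str(g): float(m) for g, m in zip(gene_ids, mu)},
        panel_genes=panel_genes,
        probe_isoform=probe_iso,
    )
    meta = SampleMeta(pd.DataFrame(meta_rows))
    return SyntheticCohort(
        matrices=matrices,
        meta=meta,
        gene_model=gm,
        truth=truth,
        sc_counts=sc_counts,
        true_abundance=true_abund,
    )


# ---------------------------------------------------------------------------
# double-assay design (sequential sections measured by both assays)


@dataclass
class DoubleAssayData:
    """One set of samples measured by both RNA-seq and NanoString.

    RNA-seq is emitted at isoform and exon resolution (exon rows are keyed
    ``<isoform>:<exon_index>``) so the counting-mode comparison can run;
    NanoString measures the probe isoform's abundance only.
    """

    rnaseq_isoform: ExpressionMatrix
    rnaseq_exon: ExpressionMatrix
    nanostring: ExpressionMatrix
    gene_model: GeneModel
    truth: SyntheticTruth
    true_abundance: pd.DataFrame  # gene-level latent abundance


def generate_double_assay(
    config: GeneratorConfig, n_samples: int = 24
) -> DoubleAssayData:
    """Generate the double-assay comparison data set (default 24 samples).

    Panel genes only.  A fraction ``variable_usage_frac`` of genes re-draw
    their isoform usage per sample (low-concentration Dirichlet around the
    gene's base usage), so probe-matched counting genuinely differs from
    whole-gene counting for those genes.
    """
    root = np.random.SeedSequence(config.seed).spawn(1)[0]
    rng = np.random.default_rng(root)

    gene_ids = np.array([f"G{i:04d}" for i in range(config.n_genes)])
    mu = 4.0 + 2.0 * rng.standard_normal(config.n_genes)
    panel_idx = np.sort(rng.choice(config.n_genes, size=config.panel_size, replace=False))
    panel_genes = [str(g) for g in gene_ids[panel_idx]]
    gm, usage, probe_iso = _build_gene_model(gene_ids, panel_genes, config, rng)

    samples = [f"D{j + 1:02d}" for j in range(n_samples)]
    mu_p = mu[panel_idx]
    log_a = (
        mu_p[:, None]
        + rng.standard_normal((len(panel_idx), n_samples)) * config.patient_effect_sd
        + rng.standard_normal((len(panel_idx), n_samples)) * config.residual_sd
    )
    abund = pd.DataFrame(np.exp(log_a), index=panel_genes, columns=samples)

    variable = set(
        rng.choice(panel_genes, size=int(config.variable_usage_frac * len(panel_genes)),
                   replace=False)
    )
    k = config.isoforms_per_gene
    iso_rows, iso_names = [], []
    exon_rows, exon_names = [], []
    ns_rows = []
    for g in panel_genes:
        base = np.array(usage[g])
        if g in variable and k > 1:
            u = np.stack(
                [rng.dirichlet(np.clip(base, 1e-3, None) * 3.0) for _ in samples], axis=1
            )
        else:
            u = np.tile(base[:, None], (1, n_samples))
        a_iso = abund.loc[g].to_numpy()[None, :] * u  # isoform x sample
        isos = gm.isoforms_of[g]
        for ii, iso in enumerate(isos):
            iso_rows.append(a_iso[ii])
            iso_names.append(iso)
            lens = np.array([e - s for _, s, e in gm.exons_of[iso]], dtype=float)
            frac = lens / lens.sum()
            for ei, f in enumerate(frac):
                exon_rows.append(a_iso[ii] * f)
                exon_names.append(f"{iso}:{ei}")
        pi = probe_iso[g]
        ns_rows.append(a_iso[isos.index(pi)])

    def _measure(rows, names, assay):
        lat = pd.DataFrame(np.array(rows), index=names, columns=samples)
        measured = apply_assay_bias(lat, assay, config, rng)
        unit = "raw_count"
        return ExpressionMatrix(measured, unit, assay)

    rnaseq_iso = _measure(iso_rows, iso_names, "rnaseq")
    rnaseq_exon = _measure(exon_rows, exon_names, "rnaseq")
    nanostring = _measure(ns_rows, panel_genes, "nanostring")

    truth = SyntheticTruth(
        planted_pfs_genes={},
        planted_assay_genes={},
        true_detection_floor=dict(config.detection_floor),
        true_isoform_usage={g: usage[g] for g in panel_genes},
        pfs_class={},
        seed=config.seed,
        baseline_log_mean={g: float(m) for g, m in zip(panel_genes, mu_p)},
        panel_genes=panel_genes,
        probe_isoform=probe_iso,
    )
    return DoubleAssayData(
        rnaseq_isoform=rnaseq_iso,
        rnaseq_exon=rnaseq_exon,
        nanostring=nanostring,
        gene_model=gm,
        truth=truth,
        true_abundance=abund,
    )
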