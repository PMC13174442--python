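"""High-level study workflows shared by the analysis drivers and tests.

Each function runs one self-contained piece of the study on synthetic data
with known ground truth and returns plain dictionaries of the quantities the
study reports: planted-biomarker recovery and hold-out AUROC for the PFS
model, the assay-identity probe before/after detection-limit filtering, and
detection-floor recovery from the double-assay design.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import features, harmonize, model, synth
from .containers import PairedLog2FC
from .normalize import aggregate_counts, compute_log2fc, normalize

PFS_CUTOFF_MONTHS = 12.0


def combined_log2fc(
    cohort: synth.SyntheticCohort,
    assays: tuple[str, ...] = ("rnaseq", "nanostring"),
    pseudocount: float = 1.0,
) -> tuple[PairedLog2FC, dict[str, PairedLog2FC]]:
    """CPM-normalized paired log2FC per mini-cohort and combined across them."""
    names = sorted({
        k[0] for k in cohort.matrices if cohort.matrices[k].assay in assays
    })
    fcs = {}
    for name in names:
        pre, post = cohort.matrices[(name, "pre")], cohort.matrices[(name, "post")]
        if pre.unit == "raw_count":
            pre, post = normalize(pre, "CPM"), normalize(post, "CPM")
        fcs[name] = compute_log2fc(pre, post, cohort.meta, pseudocount=pseudocount)
    genes = None
    for f in fcs.values():
        genes = f.gene_ids if genes is None else genes.intersection(f.gene_ids)
    data = pd.concat([fcs[n].data.loc[genes] for n in names], axis=1)
    return PairedLog2FC(data, pseudocount, "CPM"), fcs


def pfs_labels(cohort: synth.SyntheticCohort) -> dict[str, str]:
    months = cohort.meta.patient_attr("pfs_months")
    return {p: ("long" if m > PFS_CUTOFF_MONTHS else "short")
            for p, m in months.items() if np.isfinite(m)}


def pfs_study(
    seed: int,
    generator_overrides: dict | None = None,
    B: int = 200,
    top_m: int = 100,
    max_features: int = 25,
    permute_labels: bool = False,
) -> dict:
    """One full PFS-prediction replicate on the default study conditions.

    Generates the six-mini-cohort study, computes combined log2FC, splits a
    stratified hold-out, runs bootstrap predictive-frequency selection on the
    training patients, sizes the panel by LOOCV over all three
    architectures, refits, and evaluates the hold-out AUROC.  Returns the
    planted-gene recovery fraction in the candidate list, the chosen (k,
    architecture) and per-subset AUROCs.
    """
    gcfg = synth.GeneratorConfig(seed=seed, **(generator_overrides or {}))
    cohort = synth.generate_cohort(gcfg)
    comb, _ = combined_log2fc(cohort)
    labels = pfs_labels(cohort)
    if permute_labels:
        rng = np.random.default_rng(seed + 90000)
        keys = sorted(labels)
        vals = [labels[k] for k in keys]
        rng.shuffle(vals)
        labels = dict(zip(keys, vals))
    cohort_of = cohort.meta.patient_attr("mini_cohort").to_dict()
    months = cohort.meta.patient_attr("pfs_months").to_dict()

    train_ids, holdout_ids = model.make_holdout_split(
        list(comb.patient_ids), labels, cohort_of, months, seed=seed + 1
    )
    fc_train = PairedLog2FC(comb.data[train_ids], comb.pseudocount, comb.source_unit)
    fcfg = features.FeatureSelectionConfig(
        B=B, top_m=min(top_m, len(comb.gene_ids)), max_features=max_features,
        seed=seed + 2,
    )
    pft = features.bootstrap_predictive_frequency(fc_train, labels, cohort_of, fcfg)
    candidates = features.rank_candidates(pft, max_features=max_features)

    planted = set(cohort.truth.planted_pfs_genes)
    recovery = len(planted & set(candidates)) / len(planted) if planted else np.nan

    k, arch, c, curve = model.loocv_select_k(
        fc_train, labels, candidates, positive_class="short"
    )
    fitted = model.fit_final(fc_train, labels, candidates[:k], arch,
                             positive_class="short", reg_strength=c)
    subsets = {
        "train_val": fc_train,
        "holdout": PairedLog2FC(comb.data[holdout_ids], comb.pseudocount,
                                comb.source_unit),
    }
    report = model.evaluate(fitted, subsets, labels)
    return {
        "recovery": recovery,
        "holdout_auroc": float(report.subsets.loc["holdout", "auroc"]),
        "train_auroc": float(report.subsets.loc["train_val", "auroc"]),
        "k": k,
        "architecture": arch,
        "candidates": candidates,
        "truth": cohort.truth,
        "model": fitted,
        "loocv_curve": curve,
    }


def assay_probe_study(
    seed: int,
    lod_filter: bool,
    generator_overrides: dict | None = None,
    B: int = 200,
    top_m: int = 100,
    max_features: int = 25,
) -> dict:
    """Assay-identity classifier (NanoString vs RNA-seq) from log2FC alone.

    Planted assay-offset genes sit just below the detection floor
    (``assay_genes_below_floor=True``).  With ``lod_filter``, candidate genes
    whose median training CPM falls below the floor-scale strict cutoff are
    removed before modeling — the bias probe's mitigation.
    """
    overrides = {"assay_genes_below_floor": True, "pfs_effect_size": 0.0}
    overrides.update(generator_overrides or {})
    gcfg = synth.GeneratorConfig(seed=seed, **overrides)
    cohort = synth.generate_cohort(gcfg)
    comb, _ = combined_log2fc(cohort)
    assay_of_patient = cohort.meta.patient_attr("assay").to_dict()
    labels = {p: assay_of_patient[p] for p in comb.patient_ids}
    cohort_of = cohort.meta.patient_attr("mini_cohort").to_dict()
    months = cohort.meta.patient_attr("pfs_months").to_dict()

    train_ids, holdout_ids = model.make_holdout_split(
        list(comb.patient_ids), labels, cohort_of, months, seed=seed + 1
    )
    fc_train = PairedLog2FC(comb.data[train_ids], comb.pseudocount, comb.source_unit)
    fcfg = features.FeatureSelectionConfig(
        B=B, top_m=min(top_m, len(comb.gene_ids)), max_features=max_features,
        seed=seed + 2,
    )
    pft = features.bootstrap_predictive_frequency(fc_train, labels, cohort_of, fcfg)

    lod = expression_level = None
    if lod_filter:
        # median training CPM per gene; cutoff = the assay floor on the CPM
        # scale estimated from the double-assay design
        med = []
        for name in sorted({k[0] for k in cohort.matrices
                            if cohort.matrices[k].assay in ("rnaseq", "nanostring")}):
            pre = normalize(cohort.matrices[(name, "pre")], "CPM")
            med.append(pre.data.reindex(comb.gene_ids).median(axis=1))
        expression_level = pd.concat(med, axis=1).median(axis=1)
        est = estimate_lod_from_double_assay(gcfg)
        # transfer the cutoff between data sets on the quantile scale: CPM
        # library factors differ between the panel-only double-assay design
        # and the whole-transcriptome cohorts, but quantile position is
        # invariant to that monotone rescaling
        strict_q = float((est["median_expression"] < est["limits"].strict_expression).mean())
        loose_q = float((est["median_expression"] < est["limits"].loose_expression).mean())
        lod = harmonize.DetectionLimits(
            strict_expression=float(expression_level.quantile(strict_q)),
            loose_expression=float(expression_level.quantile(loose_q)),
            strict_range=0.0, loose_range=0.0,
        )
    candidates = features.rank_candidates(
        pft, lod=lod, expression_level=expression_level, max_features=max_features
    )
    k, arch, c, _ = model.loocv_select_k(
        fc_train, labels, candidates, positive_class="nanostring"
    )
    fitted = model.fit_final(fc_train, labels, candidates[:k], arch,
                             positive_class="nanostring", reg_strength=c,
                             outcome="assay")
    report = model.evaluate(
        fitted,
        {"holdout": PairedLog2FC(comb.data[holdout_ids], comb.pseudocount,
                                 comb.source_unit)},
        labels,
    )
    planted = set(cohort.truth.planted_assay_genes)
    return {
        "holdout_auroc": float(report.subsets.loc["holdout", "auroc"]),
        "candidates": candidates,
        "planted_in_candidates": len(planted & set(candidates)),
        "k": k,
        "architecture": arch,
        "truth": cohort.truth,
    }


def estimate_lod_from_double_assay(
    gcfg: synth.GeneratorConfig,
    n_samples: int = 24,
    n_bins: int = 10,
) -> dict:
    """Estimate detection limits from the double-assay design.

    Returns the limits, the measured median expression per gene, and the
    bin-index positions of the recovered loose cutoff and of the true floor
    (for recovery checks: quantile bins are invariant to the monotone
    abundance→measurement map, so positions are compared on the quantile
    scale).
    """
    da = synth.generate_double_assay(gcfg, n_samples=n_samples)
    rs = normalize(
        aggregate_counts(da.rnaseq_isoform, da.gene_model, "all_isoforms"), "CPM"
    )
    ns = normalize(da.nanostring, "CPM")
    rho = harmonize.gene_correlations(rs, ns)
    ct = harmonize.build_concordance_table({"cpm": rho, "cpm2": rho}, rs)
    lod = harmonize.estimate_detection_limits(ct, n_bins=n_bins)

    med = rs.data.median(axis=1)
    mu = pd.Series(da.truth.baseline_log_mean)
    floor = da.truth.true_detection_floor["rnaseq"]
    q_true = float((np.exp(mu) < floor).mean())
    q_loose = float((med < lod.loose_expression).mean())
    return {
        "limits": lod,
        "median_expression": med,
        "floor_bin": min(int(q_true * n_bins), n_bins - 1),
        "loose_cutoff_bin": int(round(q_loose * n_bins)),
        "strict_cutoff_quantile": float((med < lod.strict_expression).mean()),
        "truth": da.truth,
    }
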