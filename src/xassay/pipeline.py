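"""End-to-end orchestration: simulate → harmonize → select → train → validate → network.

Driven by a YAML config holding either a generator section (synthetic study)
or explicit input paths, plus per-stage parameters and one seed that fans out
to named sub-streams.  Every stage writes machine-readable tables under the
output directory and registers them, with SHA-256 checksums, in a run
manifest; rerunning the same config and seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features, harmonize, model, network, synth, validate
from .containers import ExpressionMatrix, PairedLog2FC, SampleMeta
from .io import write_expression, write_gene_model_bed, write_metadata, write_mtx_triplet, write_truth_json
from .normalize import aggregate_counts, compute_log2fc, normalize, pseudobulk

log = logging.getLogger(__name__)

STAGES = ("simulate", "harmonize", "select", "train", "validate", "network")
PFS_CUTOFF_MONTHS = 12.0


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def validate_config(cfg: dict) -> dict:
    has_gen = "generator" in cfg
    has_inputs = "inputs" in cfg
    if has_gen == has_inputs:
        raise ValueError("config needs exactly one of 'generator' or 'inputs'")
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", list(STAGES))
    bad = set(cfg["stages"]) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages {sorted(bad)}")
    cfg.setdefault("feature_selection", {})
    cfg.setdefault("model", {})
    cfg.setdefault("lod", {})
    cfg.setdefault("pseudocount", 1.0)
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _generator_config(cfg: dict) -> synth.GeneratorConfig:
    g = dict(cfg.get("generator", {}))
    g.setdefault("seed", cfg["seed"])
    if "mini_cohorts" in g:
        g["mini_cohorts"] = [tuple(mc) for mc in g["mini_cohorts"]]
    return synth.GeneratorConfig(**g)


def _pfs_labels(meta: SampleMeta) -> dict[str, str]:
    months = meta.patient_attr("pfs_months")
    return {
        p: ("long" if m > PFS_CUTOFF_MONTHS else "short")
        for p, m in months.items()
        if np.isfinite(m)
    }


def _cohort_log2fc(
    cohort: synth.SyntheticCohort, names: list[str], pseudocount: float
) -> dict[str, PairedLog2FC]:
    """CPM-normalize count assays (intensity passes through) and compute
    per-cohort paired log2FC on each cohort's own gene space."""
    out = {}
    for name in names:
        pre = cohort.matrices[(name, "pre")]
        post = cohort.matrices[(name, "post")]
        if pre.unit == "raw_count":
            pre, post = normalize(pre, "CPM"), normalize(post, "CPM")
        out[name] = compute_log2fc(pre, post, cohort.meta, pseudocount=pseudocount)
    return out


def _combine_log2fc(fc_by_cohort: dict[str, PairedLog2FC]) -> PairedLog2FC:
    genes = None
    for fc in fc_by_cohort.values():
        genes = fc.gene_ids if genes is None else genes.intersection(fc.gene_ids)
    blocks = [fc_by_cohort[n].data.loc[genes] for n in sorted(fc_by_cohort)]
    any_fc = next(iter(fc_by_cohort.values()))
    return PairedLog2FC(
        data=pd.concat(blocks, axis=1),
        pseudocount=any_fc.pseudocount,
        source_unit=any_fc.source_unit,
    )


def run_pipeline(cfg: dict, outdir: str | Path | None = None) -> dict:
    """Run the configured stages in order; returns the manifest dict.

    Any stage error aborts with :class:`PipelineError` naming the stage; the
    partial manifest is still written to ``manifest.json``.
    """
    cfg = validate_config(dict(cfg))
    outdir = Path(outdir or cfg.get("outdir", "xassay_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg["seed"], "stages": {}, "config": _jsonable(cfg)}

    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in cfg["stages"]:
                continue
            runner = _STAGE_RUNNERS[stage]
            try:
                outputs = runner(cfg, state, outdir)
            except Exception as exc:
                raise PipelineError(stage, exc) from exc
            manifest["stages"][stage] = {
                "outputs": {
                    str(p.relative_to(outdir)): _checksum(p) for p in sorted(outputs)
                }
            }
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# stage runners: each takes (cfg, state, outdir) and returns written paths


def _stage_simulate(cfg: dict, state: dict, outdir: Path) -> list[Path]:
    gcfg = _generator_config(cfg)
    cohort = synth.generate_cohort(gcfg)
    state["cohort"] = cohort
    state["gcfg"] = gcfg
    d = outdir / "data"
    written = []
    for (name, tp), m in sorted(cohort.matrices.items()):
        p = d / f"{name}_{tp}.tsv"
        write_expression(m, p, sidecar=d / f"{name}_{tp}.yaml")
        written += [p, d / f"{name}_{tp}.yaml"]
    write_metadata(cohort.meta, d / "metadata.tsv")
    write_gene_model_bed(cohort.gene_model, d / "annotation.bed")
    write_truth_json(cohort.truth, d / "truth.json")
    written += [d / "metadata.tsv", d / "annotation.bed", d / "truth.json"]
    for name, (cells, labels) in sorted(cohort.sc_counts.items()):
        write_mtx_triplet(cells, d / f"{name}_cells", labels.set_index("cell_id")["cell_type"])
        written += [Path(str(d / f"{name}_cells") + s)
                    for s in (".mtx", "_genes.txt", "_barcodes.txt", "_cells.tsv")]
    return written


def _stage_harmonize(cfg: dict, state: dict, outdir: Path) -> list[Path]:
    gcfg: synth.GeneratorConfig = state["gcfg"]
    lod_cfg = cfg["lod"]
    da = synth.generate_double_assay(gcfg, n_samples=int(cfg.get("double_assay_n", 24)))
    state["double_assay"] = da

    gene_of = da.gene_model.gene_of_isoform()
    lengths_iso = {
        iso: da.gene_model.isoform_length(iso)
        for iso in da.rnaseq_isoform.gene_ids
    }
    ns_cpm = normalize(da.nanostring, "CPM")

    variants: dict[str, pd.Series] = {}
    rho_by_mode: dict[str, pd.DataFrame] = {}
    expr_by_mode: dict[str, pd.Series] = {}
    for mode in ("all_isoforms", "probe_matched_exon"):
        agg = aggregate_counts(
            da.rnaseq_isoform, da.gene_model, mode=mode, exon_level=da.rnaseq_exon
        )
        lengths_gene = {}
        for g in agg.gene_ids:
            isos = da.gene_model.isoforms_of[g]
            lengths_gene[g] = float(np.mean([lengths_iso[i] for i in isos]))
        cols = {}
        for norm in ("CPM", "RPKM", "TPM"):
            normed = normalize(agg, norm, lengths=lengths_gene)
            rho = harmonize.gene_correlations(normed, ns_cpm)
            variants[f"{mode}/{norm}"] = rho
            cols[norm] = rho
            if norm == "CPM":
                expr_by_mode[mode] = normed.data.median(axis=1)
        rho_by_mode[mode] = pd.DataFrame(cols)
    ref = normalize(
        aggregate_counts(da.rnaseq_isoform, da.gene_model, mode="all_isoforms"),
        "CPM",
    )
    ct = harmonize.build_concordance_table(variants, ref)
    lod = harmonize.estimate_detection_limits(
        ct,
        n_bins=int(lod_cfg.get("n_bins", 10)),
        loose_drop=float(lod_cfg.get("loose_drop", 0.05)),
        strict_floor=float(lod_cfg.get("strict_floor", 0.7)),
    )
    classes = harmonize.classify_gene_concordance(ct)
    counting = harmonize.counting_improvement(
        rho_by_mode["all_isoforms"], rho_by_mode["probe_matched_exon"],
        lod=lod,
        expression_isoform=expr_by_mode["all_isoforms"],
        expression_exon=expr_by_mode["probe_matched_exon"],
    )
    state["lod"] = lod
    state["concordance"] = ct

    cohort: synth.SyntheticCohort = state["cohort"]
    bulk = [n for n, a, _ in cohort_layout(cohort) if a in ("rnaseq", "nanostring", "microarray")]
    fc = _cohort_log2fc(cohort, bulk, cfg["pseudocount"])
    state["fc_by_cohort"] = fc
    drt = harmonize.dynamic_range_test(
        {n: np.abs(f.values().ravel()) for n, f in fc.items()}
    )
    assay_of = {n: a for n, a, _ in cohort_layout(cohort)}
    mix = harmonize.pca_overlap({n: f.data for n, f in fc.items()}, assay_of)

    d = outdir / "harmonize"
    d.mkdir(parents=True, exist_ok=True)
    conc = ct.rho.copy()
    conc["median_expression"] = ct.median_expression
    conc["iqr"] = ct.expression_range
    conc["concordance_class"] = classes
    conc.to_csv(d / "concordance.tsv", sep="\t", index_label="gene_id")
    counting.to_csv(d / "counting_modes.tsv", sep="\t", index_label="gene_id")
    with open(d / "detection_limits.json", "w") as fh:
        json.dump(lod.to_dict(), fh, indent=1, sort_keys=True)
    drt.to_csv(d / "dynamic_range.tsv", sep="\t", index=False)
    emb = pd.DataFrame(mix["embedding"][:, :2], columns=["PC1", "PC2"])
    emb["assay"] = mix["assay_labels"]
    emb.to_csv(d / "pca_log2fc.tsv", sep="\t", index=False)
    with open(d / "pca_mixing.json", "w") as fh:
        json.dump({"silhouette_log2fc": mix["silhouette"]}, fh, indent=1)
    return [d / f for f in ("concordance.tsv", "counting_modes.tsv",
                            "detection_limits.json", "dynamic_range.tsv",
                            "pca_log2fc.tsv", "pca_mixing.json")]


def cohort_layout(cohort: synth.SyntheticCohort) -> list[tuple[str, str, int]]:
    t = cohort.meta.table
    out = []
    for name, grp in t.groupby("mini_cohort"):
        out.append((str(name), str(grp["assay"].iloc[0]), grp["patient_id"].nunique()))
    return sorted(out)


def _stage_select(cfg: dict, state: dict, outdir: Path) -> list[Path]:
    cohort: synth.SyntheticCohort = state["cohort"]
    fs = cfg["feature_selection"]
    fcfg = features.FeatureSelectionConfig(
        strategy=fs.get("strategy", "bootstrap"),
        k=int(fs.get("k", 50)),
        B=int(fs.get("B", 200)),
        top_m=int(fs.get("top_m", 100)),
        max_features=int(fs.get("max_features", 25)),
        seed=int(cfg["seed"]) + 1,
    )
    train_names = [n for n, a, _ in cohort_layout(cohort) if a in ("rnaseq", "nanostring")]
    fc_train_cohorts = {n: state["fc_by_cohort"][n] for n in train_names}
    combined = _combine_log2fc(fc_train_cohorts)
    labels = _pfs_labels(cohort.meta)
    cohort_of = cohort.meta.patient_attr("mini_cohort").to_dict()

    patients = [p for p in combined.patient_ids if p in labels]
    pfs_months = cohort.meta.patient_attr("pfs_months").to_dict()
    train_ids, holdout_ids = model.make_holdout_split(
        patients, labels, cohort_of, pfs_months, seed=int(cfg["seed"]) + 2
    )
    fc_train = PairedLog2FC(combined.data[train_ids], combined.pseudocount,
                            combined.source_unit)
    if fcfg.top_m > len(combined.gene_ids):
        fcfg.top_m = len(combined.gene_ids)
    pft = features.bootstrap_predictive_frequency(fc_train, labels, cohort_of, fcfg)

    lod = state.get("lod")
    level = None
    if lod is not None:
        # median CPM of training cohorts per gene, for the LOD filter
        med = []
        for n in train_names:
            pre = cohort.matrices[(n, "pre")]
            if pre.unit == "raw_count":
                pre = normalize(pre, "CPM")
            med.append(pre.data.reindex(combined.gene_ids).median(axis=1))
        level = pd.concat(med, axis=1).median(axis=1)
    candidates = features.rank_candidates(
        pft, lod=lod, expression_level=level, max_features=fcfg.max_features
    )
    consensus = features.consensus_select(
        {n: PairedLog2FC(
            fc_train_cohorts[n].data[[p for p in fc_train_cohorts[n].patient_ids
                                      if p in train_ids]],
            combined.pseudocount, combined.source_unit)
         for n in train_names},
        labels, k=fcfg.k,
    )

    state.update(
        combined_fc=combined, fc_train=fc_train, train_ids=train_ids,
        holdout_ids=holdout_ids, labels=labels, cohort_of=cohort_of,
        candidates=candidates, pft=pft,
    )
    d = outdir / "select"
    d.mkdir(parents=True, exist_ok=True)
    pft.table.to_csv(d / "predictive_frequency.tsv", sep="\t", index_label="gene_id")
    pd.Series(candidates, name="gene_id").to_csv(d / "candidates.tsv", sep="\t", index=False)
    pd.Series(consensus, name="gene_id").to_csv(d / "consensus.tsv", sep="\t", index=False)
    with open(d / "split.json", "w") as fh:
        json.dump({"train": train_ids, "holdout": holdout_ids}, fh, indent=1)
    return [d / f for f in ("predictive_frequency.tsv", "candidates.tsv",
                            "consensus.tsv", "split.json")]


def _stage_train(cfg: dict, state: dict, outdir: Path) -> list[Path]:
    mcfg = cfg["model"]
    archs = tuple(mcfg.get("architectures", model.ARCHITECTURES))
    c_grid = tuple(float(c) for c in mcfg.get("c_grid", (1.0,)))
    fc_train: PairedLog2FC = state["fc_train"]
    labels = state["labels"]
    candidates = state["candidates"]

    k, arch, c, curve = model.loocv_select_k(
        fc_train, labels, candidates, positive_class="short",
        architectures=archs, c_grid=c_grid,
    )
    fitted = model.fit_final(
        fc_train, labels, candidates[:k], arch, positive_class="short",
        reg_strength=c,
    )
    combined: PairedLog2FC = state["combined_fc"]
    subsets = {"train_val": fc_train,
               "holdout": PairedLog2FC(combined.data[state["holdout_ids"]],
                                       combined.pseudocount, combined.source_unit)}
    cohort_of = state["cohort_of"]
    for name in sorted(set(cohort_of.values())):
        pats = [p for p in fc_train.patient_ids if cohort_of[p] == name]
        if len(pats) >= 4:
            subsets[f"cohort:{name}"] = PairedLog2FC(
                combined.data[pats], combined.pseudocount, combined.source_unit)
    report = model.evaluate(fitted, subsets, labels)
    state["model"] = fitted
    state["report"] = report

    d = outdir / "train"
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "model.json", "w") as fh:
        json.dump(fitted.to_dict(), fh, indent=1, sort_keys=True)
    curve.to_csv(d / "loocv_curve.tsv", sep="\t", index=False)
    report.subsets.to_csv(d / "auroc.tsv", sep="\t")
    written = [d / "model.json", d / "loocv_curve.tsv", d / "auroc.tsv"]
    for name, pts in sorted(report.roc_points.items()):
        p = d / f"roc_{name.replace(':', '_')}.csv"
        pts.to_csv(p, index=False)
        written.append(p)
    return written


def _stage_validate(cfg: dict, state: dict, outdir: Path) -> list[Path]:
    cohort: synth.SyntheticCohort = state["cohort"]
    labels = state["labels"]
    fitted: model.FittedModel = state["model"]
    d = outdir / "validate"
    d.mkdir(parents=True, exist_ok=True)
    written = []

    fc_all = {n: fc for n, fc in state["fc_by_cohort"].items()
              if len(fc.patient_ids) >= 4}
    model_fc = {
        n: PairedLog2FC(fc.data.reindex(fitted.genes).dropna(),
                        fc.pseudocount, fc.source_unit)
        for n, fc in fc_all.items()
    }
    model_fc = {n: fc for n, fc in model_fc.items() if len(fc.gene_ids) > 0}
    direction = validate.directionality_concordance(model_fc, labels)
    direction.to_csv(d / "directionality.tsv", sep="\t", index_label="gene_id")
    written.append(d / "directionality.tsv")

    micro = [n for n, a, _ in cohort_layout(cohort) if a == "microarray"]
    for name in micro:
        pre = cohort.matrices[(name, "pre")]
        expr = pre.data.reindex(fitted.genes).dropna()
        meta = cohort.meta.table
        sub = meta[(meta["mini_cohort"] == name) & (meta["timepoint"] == "pre")]
        sid_of = sub.set_index("patient_id")["sample_id"]
        t = sub.set_index("patient_id")["os_months"]
        e = sub.set_index("patient_id")["os_event"]
        expr = expr[sid_of.to_numpy()]
        expr.columns = sid_of.index
        cox = validate.cox_univariate(expr, t, e, cohort=name)
        cox.to_csv(d / f"cox_{name}.tsv", sep="\t")
        written.append(d / f"cox_{name}.tsv")
        gene = cox["p"].idxmin() if cox["p"].notna().any() else expr.index[0]
        km = validate.km_median_split(expr.loc[gene], t, e)
        km_rows = []
        for grp, pts in km["curves"].items():
            pts = pts.assign(group=grp, gene=gene)
            km_rows.append(pts)
        pd.concat(km_rows).to_csv(d / f"km_{name}.tsv", sep="\t", index=False)
        written.append(d / f"km_{name}.tsv")

    sc_names = [n for n, a, _ in cohort_layout(cohort) if a == "scrnaseq"]
    for name in sc_names:
        cells, cell_labels = cohort.sc_counts[name]
        pb = pseudobulk(cells, cell_labels, group="cell_type")
        meta = cohort.meta
        pfi = meta.patient_attr("pfi_months").to_dict()
        fc_by_ct: dict[str, PairedLog2FC] = {}
        cols = pd.DataFrame(
            [c.split("|") for c in pb.sample_ids], columns=["sample_id", "cell_type"]
        )
        for ct_name in sorted(cols["cell_type"].unique()):
            sub_cols = [f"{s}|{ct_name}" for s in cols[cols["cell_type"] == ct_name]["sample_id"]]
            sub = ExpressionMatrix(pb.data[sub_cols].rename(
                columns=lambda c: c.split("|")[0]), "raw_count", "scrnaseq_pseudobulk")
            sub = normalize(sub, "CPM")
            mt = meta.table[meta.table["sample_id"].isin(sub.sample_ids)]
            pats = SampleMeta(mt).paired_patients()
            if len(pats) < 5:
                continue
            pre_cols = [SampleMeta(mt).sample_of(p, "pre") for p in pats]
            post_cols = [SampleMeta(mt).sample_of(p, "post") for p in pats]
            pre_m = ExpressionMatrix(sub.data[pre_cols], sub.unit, sub.assay)
            post_m = ExpressionMatrix(sub.data[post_cols], sub.unit, sub.assay)
            fc_by_ct[ct_name] = compute_log2fc(pre_m, post_m, SampleMeta(mt),
                                               pseudocount=cfg["pseudocount"])
        if fc_by_ct:
            genes = fitted.genes
            fc_by_ct = {
                c: PairedLog2FC(f.data.reindex(genes).dropna(), f.pseudocount, f.source_unit)
                for c, f in fc_by_ct.items()
            }
            corr = validate.celltype_pfi_correlation(fc_by_ct, pfi)
            corr.to_csv(d / f"celltype_pfi_{name}.tsv", sep="\t", index=False)
            written.append(d / f"celltype_pfi_{name}.tsv")
    return written


def _stage_network(cfg: dict, state: dict, outdir: Path) -> list[Path]:
    cohort: synth.SyntheticCohort = state["cohort"]
    beta = float(cfg.get("network", {}).get("beta", 6.0))
    n_top = int(cfg.get("network", {}).get("n_genes", 200))
    rna = [n for n, a, _ in cohort_layout(cohort) if a == "rnaseq"]
    if not rna:
        rna = [n for n, a, _ in cohort_layout(cohort) if a in ("nanostring",)]
    pre_blocks, post_blocks = [], []
    for name in rna:
        for tp, blocks in (("pre", pre_blocks), ("post", post_blocks)):
            m = cohort.matrices[(name, tp)]
            if m.unit == "raw_count":
                m = normalize(m, "CPM")
            blocks.append(np.log2(m.data + 1.0))
    pre_df = pd.concat(pre_blocks, axis=1)
    post_df = pd.concat(post_blocks, axis=1)

    focal = cfg.get("network", {}).get("focal_gene")
    if focal is None:
        fitted: model.FittedModel | None = state.get("model")
        focal = fitted.genes[int(np.argmax(np.abs(fitted.coefficients)))] if fitted else str(pre_df.index[0])
    var = (pre_df.var(axis=1) + post_df.var(axis=1)).sort_values(ascending=False)
    keep = list(var.index[:n_top])
    if focal not in keep:
        keep = [focal] + keep[: n_top - 1]
    pre_net = network.build_network(pre_df.loc[keep], beta=beta, condition="pre")
    post_net = network.build_network(post_df.loc[keep], beta=beta, condition="post")
    delta = network.focal_delta(pre_net, post_net, focal)

    d = outdir / "network"
    d.mkdir(parents=True, exist_ok=True)
    delta.to_csv(d / "focal_delta.tsv", sep="\t", index_label="gene_id")
    for net, tag in ((pre_net, "pre"), (post_net, "post")):
        pd.DataFrame(net.tom, index=net.gene_ids, columns=net.gene_ids).to_csv(
            d / f"tom_{tag}.tsv.gz", sep="\t",
            compression={"method": "gzip", "mtime": 0},  # reproducible bytes
        )
    with open(d / "network_summary.json", "w") as fh:
        json.dump({
            "focal_gene": focal, "beta": beta, "n_genes": len(keep),
            "class_counts": delta["class"].value_counts().to_dict(),
        }, fh, indent=1, sort_keys=True)
    return [d / "focal_delta.tsv", d / "tom_pre.tsv.gz", d / "tom_post.tsv.gz",
            d / "network_summary.json"]


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "harmonize": _stage_harmonize,
    "select": _stage_select,
    "train": _stage_train,
    "validate": _stage_validate,
    "network": _stage_network,
}


def write_report(manifest: dict, outdir: str | Path) -> Path:
    """Human-readable markdown + JSON summary assembled from stage outputs."""
    outdir = Path(outdir)
    summary: dict = {"seed": manifest["seed"]}
    lines = ["# Pipeline report", "", f"seed: {manifest['seed']}", ""]

    lod_p = outdir / "harmonize" / "detection_limits.json"
    if lod_p.exists():
        lod = json.loads(lod_p.read_text())
        summary["detection_limits"] = lod
        lines += ["## Limits of detection", ""]
        lines += [f"- {k}: {v:.4g}" for k, v in sorted(lod.items())] + [""]
    conc_p = outdir / "harmonize" / "concordance.tsv"
    if conc_p.exists():
        conc = pd.read_csv(conc_p, sep="\t")
        counts = conc["concordance_class"].value_counts(normalize=True)
        summary["concordance_fractions"] = {k: float(v) for k, v in counts.items()}
        lines += ["## Concordance classes", ""]
        lines += [f"- {k}: {v:.1%}" for k, v in counts.items()] + [""]
    cand_p = outdir / "select" / "candidates.tsv"
    if cand_p.exists():
        cand = pd.read_csv(cand_p, sep="\t")["gene_id"].tolist()
        summary["candidates"] = cand
        lines += ["## Selected candidates", ""]
        lines.append("(empty candidate set)" if not cand else ", ".join(cand))
        lines.append("")
    auroc_p = outdir / "train" / "auroc.tsv"
    if auroc_p.exists():
        aur = pd.read_csv(auroc_p, sep="\t").set_index("subset")
        summary["auroc"] = {k: (None if pd.isna(v) else float(v))
                            for k, v in aur["auroc"].items()}
        lines += ["## AUROC by subset", ""]
        lines += [f"- {k}: {'masked' if v is None else f'{v:.3f}'}"
                  for k, v in summary["auroc"].items()] + [""]
    net_p = outdir / "network" / "network_summary.json"
    if net_p.exists():
        summary["network"] = json.loads(net_p.read_text())

    (outdir / "report.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (outdir / "report.md").write_text("\n".join(lines))
    return outdir / "report.md"
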