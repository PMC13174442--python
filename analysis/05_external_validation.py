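"""External verification: directionality, survival association, cell types.

Checks model-gene log2FC directionality across mini-cohorts including a
microarray cohort (never used for training), fits univariate Cox models and
a Kaplan-Meier median split on the microarray cohort's pre-treatment
expression, and correlates cell-type pseudobulk log2FC with log(PFI + 1) in
a small single-cell cohort.
"""

from pathlib import Path

import pandas as pd

from xassay import synth, validate, workflows
from xassay.containers import ExpressionMatrix, PairedLog2FC, SampleMeta
from xassay.normalize import compute_log2fc, normalize, pseudobulk

OUT = Path(__file__).resolve().parents[1] / "results" / "validate"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    layout = list(synth.DEFAULT_MINI_COHORTS) + [("MA-A", "microarray", 28)]
    cohort = synth.generate_cohort(synth.GeneratorConfig(
        seed=seed, mini_cohorts=layout))
    labels = workflows.pfs_labels(cohort)
    planted = sorted(cohort.truth.planted_pfs_genes)

    # directionality of planted model genes across every bulk cohort
    fcs = {}
    for (name, tp), m in cohort.matrices.items():
        if tp != "pre" or m.assay == "scrnaseq":
            continue
        pre, post = cohort.matrices[(name, "pre")], cohort.matrices[(name, "post")]
        if pre.unit == "raw_count":
            pre, post = normalize(pre, "CPM"), normalize(post, "CPM")
        fc = compute_log2fc(pre, post, cohort.meta)
        fcs[name] = PairedLog2FC(fc.data.reindex(planted).dropna(),
                                 fc.pseudocount, fc.source_unit)
    direction = validate.directionality_concordance(fcs, labels)
    direction.to_csv(OUT / "directionality.tsv", sep="\t", index_label="gene_id")
    counts = direction["consistency"].value_counts()
    print("Directionality of planted genes across",
          len(fcs), "cohorts:", counts.to_dict())

    # Cox + KM on the microarray cohort's pre-treatment expression vs OS
    meta = cohort.meta.table
    sub = meta[(meta["mini_cohort"] == "MA-A") & (meta["timepoint"] == "pre")]
    expr = cohort.matrices[("MA-A", "pre")].data.reindex(planted).dropna()
    expr = expr[sub["sample_id"].to_numpy()]
    expr.columns = sub["patient_id"].to_numpy()
    t = sub.set_index("patient_id")["pfs_months"]
    e = sub.set_index("patient_id")["pfs_event"]
    cox = validate.cox_univariate(expr, t, e, cohort="MA-A")
    cox.to_csv(OUT / "cox_microarray.tsv", sep="\t")
    sig = cox[cox["adj_p"] < 0.05]
    print(f"Cox (microarray pre-treatment vs PFS): {len(sig)}/{len(cox)} genes "
          f"with adjusted p < 0.05")
    best = cox["p"].idxmin()
    km = validate.km_median_split(expr.loc[best], t, e)
    print(f"KM median split of top gene {best}: log-rank p={km['logrank_p']:.3g} "
          f"(n_low={km['n_low']}, n_high={km['n_high']})")
    rows = [c.assign(group=g, gene=best) for g, c in km["curves"].items()]
    pd.concat(rows).to_csv(OUT / "km_top_gene.tsv", sep="\t", index=False)

    # cell-type pseudobulk log2FC vs log(PFI + 1)
    sc = synth.generate_cohort(synth.GeneratorConfig(
        n_genes=300, panel_size=200, n_planted_pfs_genes=6,
        n_planted_assay_genes=6,
        mini_cohorts=[("SC-A", "scrnaseq", 11)],
        cells_per_sample=120, umis_per_cell=1500, seed=seed + 3))
    cells, cell_labels = sc.sc_counts["SC-A"]
    pb = pseudobulk(cells, cell_labels, group="cell_type")
    pfi = sc.meta.patient_attr("pfi_months").to_dict()
    cols = pd.DataFrame([c.split("|") for c in pb.sample_ids],
                        columns=["sample_id", "cell_type"])
    fc_by_ct = {}
    for ct_name in sorted(cols["cell_type"].unique()):
        sel = [f"{s}|{ct_name}"
               for s in cols[cols["cell_type"] == ct_name]["sample_id"]]
        sub_m = ExpressionMatrix(pb.data[sel].rename(columns=lambda c: c.split("|")[0]),
                                 "raw_count", "scrnaseq_pseudobulk")
        sub_m = normalize(sub_m, "CPM")
        mt = sc.meta.table[sc.meta.table["sample_id"].isin(sub_m.sample_ids)]
        sm = SampleMeta(mt)
        pats = sm.paired_patients()
        if len(pats) < 5:
            continue
        pre_m = ExpressionMatrix(sub_m.data[[sm.sample_of(p, "pre") for p in pats]],
                                 sub_m.unit, sub_m.assay)
        post_m = ExpressionMatrix(sub_m.data[[sm.sample_of(p, "post") for p in pats]],
                                  sub_m.unit, sub_m.assay)
        fc_by_ct[ct_name] = compute_log2fc(pre_m, post_m, sm)
    focal = sorted(sc.truth.planted_pfs_genes)
    fc_by_ct = {c: PairedLog2FC(f.data.reindex(focal).dropna(), f.pseudocount,
                                f.source_unit) for c, f in fc_by_ct.items()}
    corr = validate.celltype_pfi_correlation(fc_by_ct, pfi)
    corr.to_csv(OUT / "celltype_pfi.tsv", sep="\t", index=False)
    top = corr.reindex(corr["rho"].abs().sort_values(ascending=False).index).head(3)
    print("Strongest cell-type log2FC ~ log(PFI+1) correlations:")
    for _, r in top.iterrows():
        print(f"  {r['gene']} in {r['cell_type']}: rho={r['rho']:.2f} "
              f"(p={r['p']:.3f}, n={int(r['n'])})")


if __name__ == "__main__":
    main()
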