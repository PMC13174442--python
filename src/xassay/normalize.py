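"""Normalization, scaling, paired log2FC, pseudobulking and count aggregation.

Order in the pipeline is fixed: aggregate counts (counting mode) first, then
normalize, then compute log2FC.  Normalizing before aggregating gives
different numbers and is deliberately not supported by the drivers.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats

from .containers import ExpressionMatrix, GeneModel, PairedLog2FC, SampleMeta

log = logging.getLogger(__name__)

NORM_METHODS = ("CPM", "RPKM", "TPM")
COUNTING_MODES = (
    "all_isoforms",
    "highest_expressed_isoform",
    "probe_matched_isoform",
    "probe_matched_exon",
)


def normalize(
    m: ExpressionMatrix,
    method: str,
    lengths: Mapping[str, float] | pd.Series | None = None,
) -> ExpressionMatrix:
    """Library-size normalization of raw counts.

    CPM_gs = 1e6 * c_gs / sum_g c_gs; RPKM further divides by gene length in
    kb; TPM renormalizes the per-kilobase rate so every column sums to 1e6.
    """
    if method not in NORM_METHODS:
        raise ValueError(f"unknown method {method!r}")
    if m.unit != "raw_count":
        raise ValueError(f"normalize expects raw_count input, got {m.unit!r}")
    counts = m.values()
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        bad = m.sample_ids[libsize == 0][0]
        raise ValueError(f"zero library size in sample {bad!r}")

    if method == "CPM":
        out = counts / libsize * 1e6
    else:
        if lengths is None:
            raise ValueError(f"{method} requires gene lengths")
        lens = pd.Series(lengths).reindex(m.gene_ids)
        if lens.isna().any():
            missing = lens.index[lens.isna()][0]
            raise ValueError(f"missing length for gene {missing!r}")
        per_kb = counts / (lens.to_numpy()[:, None] / 1e3)
        if method == "RPKM":
            out = per_kb / libsize * 1e6
        else:  # TPM
            out = per_kb / per_kb.sum(axis=0) * 1e6
    return ExpressionMatrix(
        data=pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids),
        unit=method,
        assay=m.assay,
    )


def within_assay_scale(m: ExpressionMatrix, mode: str = "percentile") -> ExpressionMatrix:
    """Per-gene scaling across one assay's samples.

    ``percentile`` maps values to [0, 1] by midrank ((rank-1)/(n-1), ties
    averaged); ``zscore`` centers and scales.  Constant genes map to all-0.5
    (percentile) or all-0 (zscore).
    """
    if mode not in ("percentile", "zscore"):
        raise ValueError(f"unknown mode {mode!r}")
    if m.shape[1] < 2:
        raise ValueError("within-assay scaling needs at least 2 samples")
    x = m.values()
    if mode == "percentile":
        ranks = scipy.stats.rankdata(x, axis=1)  # midranks, 1..n
        n = x.shape[1]
        out = (ranks - 1.0) / (n - 1.0)
        constant = np.ptp(x, axis=1) == 0
        out[constant] = 0.5
    else:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        out = np.where(sd > 0, (x - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    return ExpressionMatrix(
        data=pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids),
        unit="scaled",
        assay=m.assay,
    )


def compute_log2fc(
    pre: ExpressionMatrix,
    post: ExpressionMatrix,
    meta: SampleMeta,
    pseudocount: float = 1.0,
) -> PairedLog2FC:
    """Paired post/pre log2 fold-change, one column per patient.

    Entry = log2(post + pseudocount) - log2(pre + pseudocount).  A zero
    pseudocount is accepted only when every value is strictly positive.
    """
    if pre.unit != post.unit or pre.assay != post.assay:
        raise ValueError(
            f"unit/assay mismatch: pre is {pre.unit}/{pre.assay}, "
            f"post is {post.unit}/{post.assay}"
        )
    genes = pre.gene_ids
    if not genes.equals(post.gene_ids):
        raise ValueError("pre and post gene spaces differ")

    sub = meta.table[meta.table["sample_id"].isin(list(pre.sample_ids) + list(post.sample_ids))]
    patients = sorted(sub["patient_id"].unique())
    pre_cols, post_cols = [], []
    for p in patients:
        rows = sub[sub["patient_id"] == p]
        pre_s = rows[rows["timepoint"] == "pre"]["sample_id"]
        post_s = rows[rows["timepoint"] == "post"]["sample_id"]
        if len(pre_s) != 1 or len(post_s) != 1:
            raise ValueError(f"patient {p!r} is not paired (needs one pre and one post sample)")
        pre_cols.append(pre_s.iloc[0])
        post_cols.append(post_s.iloc[0])

    a = pre.data[pre_cols].to_numpy(dtype=float)
    b = post.data[post_cols].to_numpy(dtype=float)
    if pseudocount == 0 and ((a <= 0).any() or (b <= 0).any()):
        raise ValueError("pseudocount 0 requires strictly positive expression")
    fc = np.log2(b + pseudocount) - np.log2(a + pseudocount)
    return PairedLog2FC(
        data=pd.DataFrame(fc, index=genes, columns=patients),
        pseudocount=pseudocount,
        source_unit=pre.unit,
    )


def pseudobulk(
    sc_counts: pd.DataFrame,
    cell_labels: pd.DataFrame,
    group: str = "cell_type",
) -> ExpressionMatrix:
    """Sum single-cell counts into per-(sample, cell-type) pseudobulk columns.

    Parameters
    ----------
    sc_counts
        Genes × cells integer count matrix.
    cell_labels
        One row per cell with columns ``cell_id``, ``sample_id`` and
        ``cell_type``.
    group
        ``"cell_type"`` produces one column per (sample, cell type), named
        ``<sample>|<cell_type>``; ``"all"`` sums every cell of a sample.
    """
    if group not in ("cell_type", "all"):
        raise ValueError(f"unknown group {group!r}")
    labels = cell_labels.set_index("cell_id")
    unknown = [c for c in sc_counts.columns if c not in labels.index]
    if unknown:
        raise ValueError(f"unlabeled cell {unknown[0]!r}")
    vals = sc_counts.to_numpy()
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("pseudobulk expects integer counts")

    if group == "all":
        keys = labels.loc[sc_counts.columns, "sample_id"]
    else:
        keys = (
            labels.loc[sc_counts.columns, "sample_id"].astype(str)
            + "|"
            + labels.loc[sc_counts.columns, "cell_type"].astype(str)
        )
    out = sc_counts.T.groupby(keys.to_numpy()).sum().T
    empty = out.columns[(out.sum(axis=0) == 0)]
    if len(empty):
        log.info("dropping %d empty pseudobulk groups", len(empty))
        out = out.drop(columns=empty)
    return ExpressionMatrix(data=out, unit="raw_count", assay="scrnaseq_pseudobulk")


def aggregate_counts(
    isoform_level: ExpressionMatrix,
    gm: GeneModel,
    mode: str = "all_isoforms",
    exon_level: ExpressionMatrix | None = None,
) -> ExpressionMatrix:
    """Collapse isoform-level counts to gene level under a counting mode.

    - ``all_isoforms``: sum all isoforms of a gene.
    - ``highest_expressed_isoform``: the isoform with the highest mean count.
    - ``probe_matched_isoform``: the isoform with maximal probe overlap (bp).
    - ``probe_matched_exon``: counts attributable to the single exon with
      maximal probe overlap (requires ``exon_level`` counts whose rows are
      ``<isoform>:<exon_index>``).

    Ties (expression or overlap) break toward the lexicographically smallest
    isoform id.  Probe modes require a probe interval for every gene kept.
    """
    if mode not in COUNTING_MODES:
        raise ValueError(f"unknown counting mode {mode!r}")
    gene_of = gm.gene_of_isoform()
    unresolved = [i for i in isoform_level.gene_ids if i not in gene_of]
    if unresolved:
        raise ValueError(f"isoform {unresolved[0]!r} not in gene model")

    genes = sorted({gene_of[i] for i in isoform_level.gene_ids})
    iso_by_gene: dict[str, list[str]] = {g: [] for g in genes}
    for iso in isoform_level.gene_ids:
        iso_by_gene[gene_of[iso]].append(iso)

    if mode == "probe_matched_exon":
        if exon_level is None:
            raise ValueError("probe_matched_exon requires exon-level counts")
        rows = []
        for g in genes:
            probe = gm.probe_of.get(g)
            if probe is None:
                raise ValueError(f"gene {g!r} has no probe interval")
            best: tuple[int, str, str] | None = None  # (-overlap, key) minimized
            for iso in sorted(iso_by_gene[g]):
                for idx, exon in enumerate(gm.exons_of[iso]):
                    from .containers import interval_overlap

                    ov = interval_overlap(probe, exon)
                    key = f"{iso}:{idx}"
                    if ov > 0 and (best is None or ov > best[0]):
                        best = (ov, key, iso)
            if best is None:
                raise ValueError(f"probe of gene {g!r} overlaps no exon")
            rows.append((g, best[1]))
        data = pd.DataFrame(
            {g: exon_level.data.loc[key] for g, key in rows}
        ).T
        data.columns = exon_level.sample_ids
        return isoform_level.with_data(data.loc[genes])

    out = {}
    for g in genes:
        isos = sorted(iso_by_gene[g])
        block = isoform_level.data.loc[isos]
        if mode == "all_isoforms":
            out[g] = block.sum(axis=0)
        elif mode == "highest_expressed_isoform":
            means = block.mean(axis=1)
            out[g] = block.loc[means.idxmax()]  # idxmax keeps first (smallest id) on ties
        else:  # probe_matched_isoform
            if g not in gm.probe_of:
                raise ValueError(f"gene {g!r} has no probe interval")
            overlaps = {iso: gm.probe_overlap_bp(g, iso) for iso in isos}
            best_ov = max(overlaps.values())
            ties = [i for i in isos if overlaps[i] == best_ov]
            best = min(ties)
            if len(ties) > 1:
                log.info("probe-overlap tie for gene %s; choosing %s", g, best)
            out[g] = block.loc[best]
    data = pd.DataFrame(out).T.loc[genes]
    data.columns = isoform_level.sample_ids
    return isoform_level.with_data(data)
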