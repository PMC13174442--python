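"""Cross-assay concordance, limits of detection, and dynamic-range diagnostics.

The central object is the per-gene concordance table from the double-assay
design (the same samples measured by both RNA-seq and NanoString): per-gene
Spearman correlations under each preprocessing variant, plus median
expression and interquartile range per assay.  Detection limits are the
expression (or range) levels at which the per-quantile-bin median correlation
starts (loose) or clearly (strict) declines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, PairedLog2FC

log = logging.getLogger(__name__)


@dataclass
class ConcordanceTable:
    """Per-gene cross-assay concordance under preprocessing variants.

    ``rho`` has one column per (counting mode × normalization) variant;
    masked (NaN) where fewer than 4 paired samples or a constant gene made
    the correlation undefined.
    """

    rho: pd.DataFrame                      # gene x variant
    median_expression: pd.Series           # per gene (reference assay)
    expression_range: pd.Series            # per gene IQR (reference assay)

    def __post_init__(self) -> None:
        vals = self.rho.to_numpy(dtype=float)
        bad = np.nanmax(np.abs(vals)) if np.isfinite(vals).any() else 0.0
        if bad > 1 + 1e-9:
            raise ValueError("Spearman rho outside [-1, 1]")


@dataclass
class DetectionLimits:
    """Strict/loose expression and range cutoffs with their derivation."""

    strict_expression: float
    loose_expression: float
    strict_range: float
    loose_range: float
    expression_bins: pd.DataFrame = field(default_factory=pd.DataFrame)
    range_bins: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "strict_expression": self.strict_expression,
            "loose_expression": self.loose_expression,
            "strict_range": self.strict_range,
            "loose_range": self.loose_range,
        }


def gene_correlations(
    a: ExpressionMatrix | pd.DataFrame,
    b: ExpressionMatrix | pd.DataFrame,
    paired_samples: list[tuple[str, str]] | None = None,
) -> pd.Series:
    """Per-gene midrank Spearman correlation across paired samples.

    ``paired_samples`` maps columns of ``a`` to columns of ``b``; by default
    the shared column names are paired.  Genes constant in either matrix are
    masked (NaN); fewer than 4 pairs masks everything with a warning.
    """
    da = a.data if isinstance(a, ExpressionMatrix) else a
    db = b.data if isinstance(b, ExpressionMatrix) else b
    genes = da.index.intersection(db.index)
    if paired_samples is None:
        shared = [c for c in da.columns if c in set(db.columns)]
        paired_samples = [(c, c) for c in shared]
    cols_a = [p[0] for p in paired_samples]
    cols_b = [p[1] for p in paired_samples]
    if len(paired_samples) < 4:
        log.warning("fewer than 4 paired samples; correlations masked")
        return pd.Series(np.nan, index=genes)

    xa = da.loc[genes, cols_a].to_numpy(dtype=float)
    xb = db.loc[genes, cols_b].to_numpy(dtype=float)
    ra = scipy.stats.rankdata(xa, axis=1)
    rb = scipy.stats.rankdata(xb, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (ra * rb).sum(axis=1) / denom, np.nan)
    return pd.Series(rho, index=genes, name="rho")


def build_concordance_table(
    variants: dict[str, pd.Series],
    reference_expression: ExpressionMatrix,
) -> ConcordanceTable:
    """Assemble per-variant correlations plus expression level/range.

    ``variants`` maps a variant name (e.g. ``all_isoforms/CPM``) to the
    per-gene rho series from :func:`gene_correlations`; level and IQR come
    from the reference assay's normalized expression.
    """
    rho = pd.DataFrame(variants)
    expr = reference_expression.data.reindex(rho.index)
    med = expr.median(axis=1)
    iqr = expr.quantile(0.75, axis=1) - expr.quantile(0.25, axis=1)
    return ConcordanceTable(rho=rho, median_expression=med, expression_range=iqr)


def _scan_bins(
    level: pd.Series,
    rho: pd.Series,
    n_bins: int,
    loose_drop: float,
    strict_floor: float,
) -> tuple[float, float, pd.DataFrame]:
    """Quantile-bin a level variable, compute per-bin median rho, and scan
    from the highest bin downward for the loose and strict declines."""
    ok = level.notna() & rho.notna()
    lv, rh = level[ok], rho[ok]
    edges = np.unique(np.quantile(lv, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 3:
        raise ValueError("too few distinct levels to bin")
    binned = pd.cut(lv, bins=edges, include_lowest=True)
    med = rh.groupby(binned, observed=False).median()
    lower_edges = np.array([iv.left for iv in med.index])
    lower_edges[0] = edges[0]
    meds = med.to_numpy(dtype=float)

    top_ref = np.nanmedian(meds[-3:])
    # scanning from the highest-expression bin downward, the cutoff is the
    # lower edge of the *first* bin whose median rho declines; absent a
    # decline the cutoff stays 0
    loose_cut = strict_cut = 0.0
    seen_loose = seen_strict = False
    for i in range(len(meds) - 1, -1, -1):
        if np.isnan(meds[i]):
            continue
        if not seen_loose and meds[i] < top_ref - loose_drop:
            loose_cut, seen_loose = float(max(lower_edges[i], 0.0)), True
        if not seen_strict and meds[i] < strict_floor:
            strict_cut, seen_strict = float(max(lower_edges[i], 0.0)), True
    bins_df = pd.DataFrame(
        {"lower_edge": lower_edges, "median_rho": meds,
         "n_genes": rh.groupby(binned, observed=False).size().to_numpy()}
    )
    return strict_cut, loose_cut, bins_df


def estimate_detection_limits(
    ct: ConcordanceTable,
    n_bins: int = 10,
    loose_drop: float = 0.05,
    strict_floor: float = 0.7,
    variant: str | None = None,
) -> DetectionLimits:
    """Estimate strict/loose limits of detection for expression and range.

    Genes are placed into expression (resp. IQR) quantile bins; scanning from
    the highest bin downward, the loose cutoff is the lower edge of the first
    bin whose median rho falls more than ``loose_drop`` below the median rho
    of the top three bins, and the strict cutoff is the lower edge of the
    first bin whose median rho falls below ``strict_floor``.  No decline
    gives cutoff 0.  The strict and loose criteria are independent; neither
    bounds the other.
    """
    if len(ct.rho) < n_bins * 5:
        raise ValueError(f"need at least {n_bins * 5} genes for {n_bins} bins")
    rho = ct.rho[variant] if variant is not None else ct.rho.median(axis=1)
    s_e, l_e, ebins = _scan_bins(ct.median_expression, rho, n_bins, loose_drop, strict_floor)
    s_r, l_r, rbins = _scan_bins(ct.expression_range, rho, n_bins, loose_drop, strict_floor)
    return DetectionLimits(
        strict_expression=s_e, loose_expression=l_e,
        strict_range=s_r, loose_range=l_r,
        expression_bins=ebins, range_bins=rbins,
    )


def classify_gene_concordance(ct: ConcordanceTable, high: float = 0.85) -> pd.Series:
    """Label each gene by the stability of its cross-assay correlation.

    ``consistent_high`` if rho >= ``high`` under every preprocessing variant,
    ``consistent_low`` if below under every variant, otherwise
    ``preprocessing_dependent``.  Requires >= 2 variants.
    """
    if ct.rho.shape[1] < 2:
        raise ValueError("need at least 2 preprocessing variants")
    vals = ct.rho.to_numpy(dtype=float)
    all_hi = np.nanmin(vals, axis=1) >= high
    all_lo = np.nanmax(vals, axis=1) < high
    out = np.where(all_hi, "consistent_high",
                   np.where(all_lo, "consistent_low", "preprocessing_dependent"))
    return pd.Series(out, index=ct.rho.index, name="concordance_class")


def counting_improvement(
    rho_isoform: pd.DataFrame,
    rho_exon: pd.DataFrame,
    lod: DetectionLimits | None = None,
    expression_isoform: pd.Series | None = None,
    expression_exon: pd.Series | None = None,
    delta: float = 0.05,
) -> pd.DataFrame:
    """Flag genes where one counting mode beats the other.

    ``rho_isoform`` and ``rho_exon`` have one column per normalization
    (three expected).  A mode is better when its rho exceeds the other's by
    more than ``delta`` in at least two of the three normalizations.  With
    detection limits and per-mode expression levels given, flagged genes are
    annotated with whether either mode's counts fall below the loose
    expression limit.
    """
    genes = rho_isoform.index
    gains_iso = rho_isoform.to_numpy() - rho_exon.loc[genes].to_numpy()
    iso_better = (gains_iso > delta).sum(axis=1) >= 2
    exon_better = (-gains_iso > delta).sum(axis=1) >= 2
    flag = np.where(iso_better, "isoform_better",
                    np.where(exon_better, "exon_better", "neither"))
    out = pd.DataFrame({"flag": flag}, index=genes)
    if lod is not None and expression_isoform is not None and expression_exon is not None:
        out["isoform_below_limit"] = expression_isoform.reindex(genes) < lod.loose_expression
        out["exon_below_limit"] = expression_exon.reindex(genes) < lod.loose_expression
    return out


def compare_isoform_log2fc(
    fc_a: PairedLog2FC, fc_b: PairedLog2FC, outlier: float = 5.0
) -> dict:
    """Compare per-gene mean log2FC under two counting modes.

    Returns the per-gene means, their differences, an OLS R^2 between them,
    and the genes whose |difference| >= ``outlier``.
    """
    genes = fc_a.gene_ids.intersection(fc_b.gene_ids)
    pats = fc_a.patient_ids.intersection(fc_b.patient_ids)
    ma = fc_a.data.loc[genes, pats].mean(axis=1)
    mb = fc_b.data.loc[genes, pats].mean(axis=1)
    diff = ma - mb
    if np.isclose(ma.std(), 0) or np.isclose(mb.std(), 0):
        r2 = np.nan
    else:
        r2 = float(scipy.stats.pearsonr(ma, mb)[0] ** 2)
    return {
        "mean_a": ma, "mean_b": mb, "difference": diff,
        "r_squared": r2,
        "outliers": sorted(diff.index[diff.abs() >= outlier]),
    }


def cliffs_delta(x, y) -> float:
    """Cliff's delta effect size: P(x > y) - P(x < y) over all pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("cliffs_delta requires nonempty samples")
    # O((n+m) log(n+m)) via ranking rather than the n*m double loop
    greater = np.searchsorted(np.sort(y), x, side="left").sum()
    less = (len(y) - np.searchsorted(np.sort(y), x, side="right")).sum()
    return float((greater - less) / (len(x) * len(y)))


def dynamic_range_test(fc_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Mann-Whitney tests with Cliff's delta over |log2FC| groups.

    Two-sided tests, Benjamini-Hochberg adjusted over all pairs; significance
    labels follow the tiered key: ``***`` adj p < 0.001 with |delta| >= 0.474,
    ``**`` adj p < 0.01 and ``*`` adj p < 0.05 with |delta| >= 0.33.
    """
    names = sorted(fc_by_group)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for n in names:
        if len(fc_by_group[n]) < 2:
            raise ValueError(f"group {n!r} has fewer than 2 values")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = fc_by_group[names[i]], fc_by_group[names[j]]
            stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "p_value": float(p),
                "cliffs_delta": cliffs_delta(a, b),
            })
    out = pd.DataFrame(rows)
    out["adj_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    d = out["cliffs_delta"].abs()
    label = np.full(len(out), "", dtype=object)
    label[(out["adj_p"] < 0.05) & (d >= 0.33)] = "*"
    label[(out["adj_p"] < 0.01) & (d >= 0.33)] = "**"
    label[(out["adj_p"] < 0.001) & (d >= 0.474)] = "***"
    out["label"] = label
    return out


def pca_overlap(
    matrices_by_cohort: dict[str, pd.DataFrame],
    assay_of_cohort: dict[str, str],
    n_components: int = 2,
) -> dict:
    """PCA across cohorts on a shared gene space plus an assay-mixing score.

    Samples (columns) from every cohort are stacked, centered per gene, and
    projected onto the top principal components; the mixing score is the mean
    silhouette of the assay labels in the top-2 PC plane — lower means better
    mixed.  Requires >= 3 samples and >= 2 distinct assays.
    """
    genes = None
    for df in matrices_by_cohort.values():
        genes = df.index if genes is None else genes.intersection(df.index)
    blocks, labels = [], []
    for name in sorted(matrices_by_cohort):
        df = matrices_by_cohort[name].loc[genes]
        blocks.append(df.to_numpy(dtype=float).T)
        labels.extend([assay_of_cohort[name]] * df.shape[1])
    x = np.vstack(blocks)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples for PCA")
    if len(set(labels)) < 2:
        raise ValueError("assay-mixing score undefined for a single assay")
    x = x - x.mean(axis=0, keepdims=True)
    emb = PCA(n_components=min(n_components, min(x.shape) - 1),
              svd_solver="full").fit_transform(x)
    score = float(silhouette_score(emb[:, :2], labels))
    return {"embedding": emb, "assay_labels": labels, "silhouette": score}
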