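"""Consensus and bootstrap ("predictive frequency") feature selection.

Both strategies rank genes by the one-way ANOVA F statistic of their log2
fold-changes against a binary outcome.  The bootstrap strategy resamples
patients with replacement — separately within each outcome class, with
per-patient weights inversely proportional to mini-cohort size so small
cohorts are represented equally in expectation — and records, per draw, the
``top_m`` genes by F-score.  A gene's *predictive frequency* is the fraction
of bootstrap draws in which it entered that top list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import PairedLog2FC
from .harmonize import DetectionLimits

log = logging.getLogger(__name__)


@dataclass
class FeatureSelectionConfig:
    strategy: str = "bootstrap"          # bootstrap | consensus
    k: int = 50                          # per-cohort top size (consensus)
    B: int = 200                         # number of bootstrap draws
    top_m: int = 100                     # genes recorded per draw (50 or 100)
    max_features: int = 25               # candidate-list cap
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in ("bootstrap", "consensus"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.max_features > self.top_m:
            raise ValueError("max_features cannot exceed top_m")
        if min(self.k, self.B, self.top_m, self.max_features) < 1:
            raise ValueError("k, B, top_m, max_features must be positive")


@dataclass
class PredictiveFrequencyTable:
    """Per-gene bootstrap selection frequency with mean F-score and rank."""

    table: pd.DataFrame  # columns: predictive_frequency, mean_f, rank
    B: int
    top_m: int

    def __post_init__(self) -> None:
        f = self.table["predictive_frequency"]
        if ((f < 0) | (f > 1)).any():
            raise ValueError("predictive frequencies outside [0, 1]")
        if f.sum() * self.B > self.B * self.top_m + 1e-9:
            raise ValueError("total selections exceed B * top_m")

    @property
    def frequencies(self) -> pd.Series:
        return self.table["predictive_frequency"]


def f_score(values: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F statistic for one gene: (SSB/df_B) / (SSW/df_W).

    Zero within-class variance with unequal class means returns ``+inf``
    (logged); equal means with zero variance returns 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    f = f_score_matrix(values[None, :], labels)
    return float(f[0])


def f_score_matrix(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorised one-way ANOVA F over genes (rows) for a binary label.

    ``values`` is gene × sample; both classes need >= 2 samples.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    masks = [labels == c for c in classes]
    ns = np.array([m.sum() for m in masks])
    if (ns < 2).any():
        raise ValueError("each class needs at least 2 samples")
    n = ns.sum()
    grand = values.mean(axis=1)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for m, ni in zip(masks, ns):
        cm = values[:, m].mean(axis=1)
        ssb += ni * (cm - grand) ** 2
        ssw += ((values[:, m] - cm[:, None]) ** 2).sum(axis=1)
    df_b, df_w = len(classes) - 1, n - len(classes)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    degenerate = (ssw == 0) & (ssb > 0)
    if degenerate.any():
        log.info("%d genes with zero within-class variance -> +inf F", degenerate.sum())
        f[degenerate] = np.inf
    f[(ssw == 0) & (ssb == 0)] = 0.0
    return f


def _top_m_genes(f: np.ndarray, gene_ids: np.ndarray, top_m: int) -> np.ndarray:
    """Indices of the top_m genes by F, ties broken by ascending gene id."""
    order = np.lexsort((gene_ids, -f))
    return order[:top_m]


def consensus_select(
    fc_by_cohort: Mapping[str, PairedLog2FC],
    labels: Mapping[str, str],
    k: int,
) -> list[str]:
    """Intersection over mini-cohorts of each cohort's top-k genes by F-score.

    One cohort degenerates to that cohort's top-k (logged); cohorts with
    fewer than 2 patients in either class are excluded (warned); an empty
    intersection returns an empty list with a warning.
    """
    if len(fc_by_cohort) == 1:
        log.info("consensus over a single cohort degenerates to its top-k")
    shared: set[str] | None = None
    for name in sorted(fc_by_cohort):
        fc = fc_by_cohort[name]
        lab = np.array([labels[p] for p in fc.patient_ids])
        counts = pd.Series(lab).value_counts()
        if len(counts) < 2 or counts.min() < 2:
            log.warning("cohort %s lacks 2 patients per class; excluded "
                        "from consensus", name)
            continue
        f = f_score_matrix(fc.values(), lab)
        genes = fc.gene_ids.to_numpy().astype(str)
        top = set(genes[_top_m_genes(f, genes, k)])
        shared = top if shared is None else shared & top
    if not shared:
        log.warning("consensus selection is empty")
        return []
    return sorted(shared)


def bootstrap_predictive_frequency(
    fc: PairedLog2FC,
    labels: Mapping[str, str],
    cohort_of: Mapping[str, str],
    cfg: FeatureSelectionConfig,
    rng: np.random.Generator | None = None,
) -> PredictiveFrequencyTable:
    """Bootstrap feature selection with inverse-cohort-size weighting.

    For each of ``cfg.B`` draws: within each label class, sample (with
    replacement) ``n_min`` patients — ``n_min`` being the smaller class size,
    so classes are balanced — with per-patient probability proportional to
    ``1 / |cohort(patient)|`` normalized within the class; compute per-gene
    F-scores on the draw; record the ``top_m`` genes (ties by gene id).
    Deterministic given ``cfg.seed`` (or an explicit ``rng``).
    """
    patients = fc.patient_ids.to_numpy().astype(str)
    lab = np.array([labels[p] for p in patients])
    classes = np.unique(lab)
    if len(classes) != 2:
        raise ValueError(f"need both label classes, got {list(classes)}")
    genes = fc.gene_ids.to_numpy().astype(str)
    if cfg.top_m > len(genes):
        raise ValueError("top_m exceeds the number of genes")

    cohort_sizes: dict[str, int] = {}
    for p in patients:
        cohort_sizes[cohort_of[p]] = cohort_sizes.get(cohort_of[p], 0) + 1
    weights = np.array([1.0 / cohort_sizes[cohort_of[p]] for p in patients])

    class_idx, class_w = [], []
    for c in classes:
        idx = np.flatnonzero(lab == c)
        w = weights[idx]
        class_idx.append(idx)
        class_w.append(w / w.sum())
    n_min = min(len(i) for i in class_idx)

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    values = fc.values()
    hits = np.zeros(len(genes), dtype=np.int64)
    f_sum = np.zeros(len(genes), dtype=float)
    boot_labels = np.repeat(classes, n_min)
    for _ in range(cfg.B):
        cols = np.concatenate([
            rng.choice(idx, size=n_min, replace=True, p=w)
            for idx, w in zip(class_idx, class_w)
        ])
        f = f_score_matrix(values[:, cols], boot_labels)
        top = _top_m_genes(f, genes, cfg.top_m)
        hits[top] += 1
        finite = np.isfinite(f)
        f_sum[finite] += f[finite]

    freq = hits / cfg.B
    mean_f = f_sum / cfg.B
    table = pd.DataFrame(
        {"predictive_frequency": freq, "mean_f": mean_f}, index=genes
    )
    order = np.lexsort((genes, -mean_f, -freq))
    table["rank"] = 0
    table.iloc[order, table.columns.get_loc("rank")] = np.arange(1, len(genes) + 1)
    return PredictiveFrequencyTable(table=table, B=cfg.B, top_m=cfg.top_m)


def rank_candidates(
    pft: PredictiveFrequencyTable,
    lod: DetectionLimits | None = None,
    expression_level: pd.Series | None = None,
    panel: Sequence[str] | None = None,
    max_features: int = 25,
) -> list[str]:
    """Ordered candidate list: filter, then cap at ``max_features``.

    With ``lod`` and per-gene ``expression_level`` given, genes below the
    detection limits are dropped — the threshold is the larger of the strict
    and loose expression cutoffs, since the loose limit marks where
    cross-assay correlation *starts* declining (a gene below the strict limit
    is always excluded).  Genes outside ``panel`` are dropped too.  The
    survivors are ordered by (frequency, mean F, gene id) descending and the
    top ``max_features`` returned.
    """
    t = pft.table
    keep = pd.Series(True, index=t.index)
    if lod is not None:
        if expression_level is None:
            raise ValueError("LOD filtering needs per-gene expression levels")
        cutoff = max(lod.strict_expression, lod.loose_expression)
        keep &= expression_level.reindex(t.index).fillna(0.0) >= cutoff
    if panel is not None:
        keep &= t.index.isin(list(panel))
    t = t[keep]
    if t.empty:
        raise ValueError("all genes filtered out")
    genes = t.index.to_numpy().astype(str)
    order = np.lexsort((genes, -t["mean_f"].to_numpy(), -t["predictive_frequency"].to_numpy()))
    return [str(g) for g in genes[order[:max_features]]]


def compare_frequency_tables(
    t1: PredictiveFrequencyTable, t2: PredictiveFrequencyTable
) -> float:
    """Midrank Spearman correlation of predictive frequencies on shared genes."""
    shared = t1.table.index.intersection(t2.table.index)
    if len(shared) < 4:
        raise ValueError("need at least 4 shared genes")
    import scipy.stats

    rho, _ = scipy.stats.spearmanr(
        t1.table.loc[shared, "predictive_frequency"],
        t2.table.loc[shared, "predictive_frequency"],
    )
    return float(rho)
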