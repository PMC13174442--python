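"""Core in-memory carriers shared by every pipeline stage.

The universal container is :class:`ExpressionMatrix` — a gene × sample table
of non-negative values on a *pre-log* scale, tagged with the measurement unit
and the assay that produced it.  Paired post/pre log2 fold-changes live in
:class:`PairedLog2FC`, the feature space for all downstream modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

UNITS = ("raw_count", "CPM", "RPKM", "TPM", "intensity", "scaled")
ASSAYS = ("rnaseq", "nanostring", "microarray", "scrnaseq", "scrnaseq_pseudobulk")
TIMEPOINTS = ("pre", "post")


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values with unit and assay tags.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with one column per sample id.
        Values must be non-negative (pre-log scales) unless ``unit`` is
        ``"scaled"`` (z-scores may be negative).
    unit
        One of ``raw_count, CPM, RPKM, TPM, intensity, scaled``.
    assay
        One of ``rnaseq, nanostring, microarray, scrnaseq, scrnaseq_pseudobulk``.
    """

    data: pd.DataFrame
    unit: str
    assay: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {ASSAYS}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.unit != "scaled" and (self.data.to_numpy() < 0).any():
            raise ValueError(f"negative values not allowed for unit {self.unit!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, unit: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(data=data, unit=unit or self.unit, assay=self.assay)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        return self.with_data(self.data.loc[list(genes)])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return replace(self, data=self.data[list(samples)])


REQUIRED_META_COLUMNS = ("sample_id", "patient_id", "mini_cohort", "assay", "timepoint")
OPTIONAL_META_COLUMNS = (
    "pfs_months", "pfs_event", "pfi_months", "pfi_event",
    "os_months", "os_event", "age",
)


@dataclass
class SampleMeta:
    """Per-sample clinical and design metadata.

    Wraps a DataFrame with one row per sample.  Required columns:
    ``sample_id, patient_id, mini_cohort, assay, timepoint``; survival
    endpoints (``pfs_months``/``pfi_months``/``os_months`` with matching
    ``*_event`` flags) and ``age`` are optional.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        bad_tp = set(self.table["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoints {sorted(bad_tp)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        key = self.table[["mini_cohort", "patient_id", "timepoint"]]
        if key.duplicated().any():
            row = key[key.duplicated()].iloc[0]
            raise ValueError(
                f"(patient_id, timepoint) not unique within mini-cohort: {tuple(row)}"
            )

    def for_samples(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        t = self.table.set_index("sample_id")
        return t.loc[list(sample_ids)].reset_index()

    def paired_patients(self, mini_cohort: str | None = None) -> list[str]:
        """Patients with exactly one pre and one post sample."""
        t = self.table
        if mini_cohort is not None:
            t = t[t["mini_cohort"] == mini_cohort]
        counts = t.pivot_table(
            index="patient_id", columns="timepoint", values="sample_id", aggfunc="count"
        ).reindex(columns=list(TIMEPOINTS), fill_value=0).fillna(0)
        ok = counts[(counts["pre"] == 1) & (counts["post"] == 1)].index
        return sorted(ok)

    def sample_of(self, patient_id: str, timepoint: str) -> str:
        t = self.table
        hit = t[(t["patient_id"] == patient_id) & (t["timepoint"] == timepoint)]
        if len(hit) != 1:
            raise KeyError(f"no unique {timepoint} sample for patient {patient_id}")
        return hit["sample_id"].iloc[0]

    def patient_attr(self, column: str) -> pd.Series:
        """One value per patient (taken from the pre row when duplicated)."""
        t = self.table.sort_values("timepoint", ascending=False)  # 'pre' after 'post'
        return t.drop_duplicates("patient_id").set_index("patient_id")[column]


Interval = tuple[str, int, int]  # contig, start, end — 0-based half-open


def interval_overlap(a: Interval, b: Interval) -> int:
    """Overlap in bp between two 0-based half-open intervals (0 if different contig)."""
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


@dataclass
class GeneModel:
    """Gene → isoform → exon structure with an optional probe interval per gene.

    Coordinates are 0-based half-open throughout (BED convention); strand is
    ignored because probes and exons are attached to the same gene by
    construction.
    """

    isoforms_of: Mapping[str, tuple[str, ...]]          # gene -> isoform ids
    exons_of: Mapping[str, tuple[Interval, ...]]        # isoform -> sorted exons
    probe_of: Mapping[str, Interval] = field(default_factory=dict)  # gene -> probe

    def __post_init__(self) -> None:
        for iso, exons in self.exons_of.items():
            prev_end = None
            for contig, start, end in exons:
                if end <= start:
                    raise ValueError(f"empty/inverted exon in isoform {iso}")
                if prev_end is not None and start < prev_end:
                    raise ValueError(f"exons of isoform {iso} unsorted or overlapping")
                prev_end = end
        for gene, probe in self.probe_of.items():
            isos = self.isoforms_of.get(gene, ())
            if not any(
                interval_overlap(probe, exon)
                for iso in isos
                for exon in self.exons_of[iso]
            ):
                raise ValueError(f"probe of gene {gene} overlaps no exon of any isoform")

    @property
    def genes(self) -> list[str]:
        return sorted(self.isoforms_of)

    def gene_of_isoform(self) -> dict[str, str]:
        return {iso: g for g, isos in self.isoforms_of.items() for iso in isos}

    def isoform_length(self, isoform: str) -> int:
        return sum(e - s for _, s, e in self.exons_of[isoform])

    def probe_overlap_bp(self, gene: str, isoform: str) -> int:
        """Total bp of probe overlap with an isoform's exons (0 without a probe)."""
        probe = self.probe_of.get(gene)
        if probe is None:
            return 0
        return sum(interval_overlap(probe, exon) for exon in self.exons_of[isoform])


@dataclass
class PairedLog2FC:
    """Gene × patient matrix of post/pre log2 fold-changes.

    ``data`` is indexed by gene id with one column per patient.  Entries are
    ``log2(post + pseudocount) - log2(pre + pseudocount)`` and are finite by
    construction (the pseudocount guarantees it for non-negative input).
    """

    data: pd.DataFrame
    pseudocount: float
    source_unit: str

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("log2FC matrix contains non-finite values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def patient_ids(self) -> pd.Index:
        return self.data.columns

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)
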