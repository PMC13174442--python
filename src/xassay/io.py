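"""Reading and writing the pipeline's on-disk formats.

Expression travels as plain TSV (genes as rows, header = sample ids) or as an
MTX triplet with sidecar row/column id files; unit and assay tags come from a
small YAML sidecar.  Gene structure is written BED-like (0-based half-open).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .containers import ExpressionMatrix, GeneModel, SampleMeta


def read_expression(
    path: str | Path,
    format: str = "tsv_matrix",
    unit: str = "raw_count",
    assay: str = "rnaseq",
    row_ids: str | Path | None = None,
    col_ids: str | Path | None = None,
    sidecar: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or MTX triplet.

    A YAML ``sidecar`` (keys ``unit``, ``assay``) overrides the keyword tags.
    Count-like units reject negative values; duplicated gene ids are an error.
    """
    path = Path(path)
    if sidecar is not None:
        with open(sidecar) as fh:
            tags = yaml.safe_load(fh) or {}
        unit = tags.get("unit", unit)
        assay = tags.get("assay", assay)

    if format == "tsv_matrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.isna().any().any():
            raise ValueError(f"{path}: ragged rows or missing values")
    elif format == "mtx_triplet":
        if row_ids is None or col_ids is None:
            raise ValueError("mtx_triplet requires row_ids and col_ids files")
        mat = scipy.io.mmread(str(path))
        genes = [line.strip() for line in Path(row_ids).read_text().splitlines() if line.strip()]
        samples = [line.strip() for line in Path(col_ids).read_text().splitlines() if line.strip()]
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
        if dense.shape != (len(genes), len(samples)):
            raise ValueError(
                f"{path}: MTX shape {dense.shape} does not match id files "
                f"({len(genes)} genes, {len(samples)} samples)"
            )
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {format!r}")

    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    if unit in ("raw_count", "CPM", "RPKM", "TPM") and (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative values invalid for unit {unit!r}")
    return ExpressionMatrix(data=df, unit=unit, assay=assay)


def write_expression(m: ExpressionMatrix, path: str | Path, sidecar: str | Path | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    m.data.to_csv(path, sep="\t", index_label="gene_id")
    if sidecar is not None:
        with open(sidecar, "w") as fh:
            yaml.safe_dump({"unit": m.unit, "assay": m.assay}, fh)


def write_mtx_triplet(
    counts: pd.DataFrame, prefix: str | Path, labels: pd.Series | None = None
) -> None:
    """Write a genes × cells count matrix as ``<prefix>.mtx`` + id files.

    ``labels`` (cell id -> cell type), when given, is written as
    ``<prefix>_cells.tsv`` with columns cell_id, cell_type, sample_id parsed
    from the cell id prefix.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(counts.to_numpy())
    scipy.io.mmwrite(str(prefix) + ".mtx", sparse)
    Path(str(prefix) + "_genes.txt").write_text("\n".join(counts.index) + "\n")
    Path(str(prefix) + "_barcodes.txt").write_text("\n".join(counts.columns) + "\n")
    if labels is not None:
        lab = labels.rename("cell_type").rename_axis("cell_id").reset_index()
        lab.to_csv(str(prefix) + "_cells.tsv", sep="\t", index=False)


def read_metadata(path: str | Path) -> SampleMeta:
    return SampleMeta(pd.read_csv(path, sep="\t"))


def write_metadata(meta: SampleMeta, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    meta.table.to_csv(path, sep="\t", index=False)


def write_gene_model_bed(gm: GeneModel, path: str | Path) -> None:
    """BED6-like export: one row per exon plus one per probe (feature column)."""
    rows = []
    gene_of = gm.gene_of_isoform()
    for iso in sorted(gm.exons_of):
        for contig, start, end in gm.exons_of[iso]:
            rows.append((contig, start, end, f"{gene_of[iso]}|{iso}", "exon"))
    for gene in sorted(gm.probe_of):
        contig, start, end = gm.probe_of[gene]
        rows.append((contig, start, end, gene, "probe"))
    df = pd.DataFrame(rows, columns=["contig", "start", "end", "name", "feature"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, header=False)


def read_gene_model_bed(path: str | Path) -> GeneModel:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["contig", "start", "end", "name", "feature"],
    )
    isoforms_of: dict[str, list[str]] = {}
    exons_of: dict[str, list[tuple[str, int, int]]] = {}
    probe_of: dict[str, tuple[str, int, int]] = {}
    for _, r in df.iterrows():
        iv = (str(r["contig"]), int(r["start"]), int(r["end"]))
        if r["feature"] == "probe":
            probe_of[r["name"]] = iv
        else:
            gene, iso = r["name"].split("|", 1)
            isoforms_of.setdefault(gene, [])
            if iso not in isoforms_of[gene]:
                isoforms_of[gene].append(iso)
            exons_of.setdefault(iso, []).append(iv)
    return GeneModel(
        isoforms_of={g: tuple(v) for g, v in isoforms_of.items()},
        exons_of={i: tuple(sorted(v, key=lambda e: e[1])) for i, v in exons_of.items()},
        probe_of=probe_of,
    )


def write_truth_json(truth, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
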