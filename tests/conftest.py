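import numpy as np
import pandas as pd
import pytest

from xassay import synth
from xassay.containers import ExpressionMatrix, PairedLog2FC, SampleMeta


@pytest.fixture(scope="session")
def small_cohort():
    """Two-cohort study (NanoString + RNA-seq), 300 genes, 12 patients each."""
    cfg = synth.GeneratorConfig(
        n_genes=300,
        panel_size=200,
        mini_cohorts=[("NS-A", "nanostring", 12), ("RS-A", "rnaseq", 12)],
        n_planted_pfs_genes=6,
        n_planted_assay_genes=6,
        seed=7,
    )
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def sc_cohort():
    """One small scRNA-seq mini-cohort for pseudobulk / cell-type tests."""
    cfg = synth.GeneratorConfig(
        n_genes=120,
        panel_size=80,
        mini_cohorts=[("SC-A", "scrnaseq", 8)],
        n_planted_pfs_genes=4,
        n_planted_assay_genes=4,
        cells_per_sample=60,
        umis_per_cell=800,
        seed=13,
    )
    return synth.generate_cohort(cfg)


def make_expression(values, genes=None, samples=None, unit="raw_count", assay="rnaseq"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        data=pd.DataFrame(values, index=genes, columns=samples), unit=unit, assay=assay
    )


def make_fc(values, genes=None, patients=None, pseudocount=1.0):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    patients = patients or [f"p{j}" for j in range(values.shape[1])]
    return PairedLog2FC(
        data=pd.DataFrame(values, index=genes, columns=patients),
        pseudocount=pseudocount,
        source_unit="CPM",
    )


def make_paired_meta(patients, cohort="C1", assay="rnaseq"):
    rows = []
    for p in patients:
        for tp in ("pre", "post"):
            rows.append({
                "sample_id": f"{p}-{tp}", "patient_id": p, "mini_cohort": cohort,
                "assay": assay, "timepoint": tp,
            })
    return SampleMeta(pd.DataFrame(rows))
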