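"""I/O, normalization, scaling, paired log2FC, pseudobulk and counting modes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xassay.containers import ExpressionMatrix, GeneModel
from xassay.io import (
    read_expression,
    read_gene_model_bed,
    write_expression,
    write_gene_model_bed,
    write_mtx_triplet,
)
from xassay.normalize import (
    aggregate_counts,
    compute_log2fc,
    normalize,
    pseudobulk,
    within_assay_scale,
)

from .conftest import make_expression, make_fc, make_paired_meta


class TestReadExpression:
    def test_tsv_round_trip_preserves_order_and_tags(self, tmp_path):
        m = make_expression([[1, 2], [3, 4]], genes=["gB", "gA"], unit="CPM",
                            assay="nanostring")
        write_expression(m, tmp_path / "m.tsv", sidecar=tmp_path / "m.yaml")
        back = read_expression(tmp_path / "m.tsv", sidecar=tmp_path / "m.yaml")
        assert list(back.gene_ids) == ["gB", "gA"]
        assert back.unit == "CPM" and back.assay == "nanostring"
        np.testing.assert_allclose(back.values(), m.values())

    def test_mtx_triplet_fills_implicit_zeros(self, tmp_path):
        counts = pd.DataFrame([[1, 0], [2, 3]], index=["g1", "g2"],
                              columns=["c1", "c2"])
        write_mtx_triplet(counts, tmp_path / "sc")
        back = read_expression(
            tmp_path / "sc.mtx", format="mtx_triplet",
            row_ids=tmp_path / "sc_genes.txt", col_ids=tmp_path / "sc_barcodes.txt",
        )
        np.testing.assert_allclose(back.values(), counts.to_numpy())

    def test_duplicate_gene_named_in_error(self, tmp_path):
        (tmp_path / "dup.tsv").write_text("gene_id\ts1\ngX\t1\ngX\t2\n")
        with pytest.raises(ValueError, match="gX"):
            read_expression(tmp_path / "dup.tsv")

    def test_negative_counts_rejected(self, tmp_path):
        (tmp_path / "neg.tsv").write_text("gene_id\ts1\ngX\t-1\n")
        with pytest.raises(ValueError, match="negative"):
            read_expression(tmp_path / "neg.tsv", unit="raw_count")

    def test_gene_model_bed_round_trip(self):
        gm = GeneModel(
            isoforms_of={"g1": ("g1.1", "g1.2")},
            exons_of={"g1.1": (("chr1", 0, 100), ("chr1", 200, 300)),
                      "g1.2": (("chr1", 0, 150),)},
            probe_of={"g1": ("chr1", 10, 90)},
        )
        import io as _io
        import tempfile
        with tempfile.TemporaryDirectory() as d:
            write_gene_model_bed(gm, d + "/a.bed")
            back = read_gene_model_bed(d + "/a.bed")
        assert back.isoforms_of == {"g1": ("g1.1", "g1.2")}
        assert back.probe_of == {"g1": ("chr1", 10, 90)}
        assert back.exons_of["g1.1"] == (("chr1", 0, 100), ("chr1", 200, 300))


class TestNormalize:
    def test_cpm_closed_form(self):
        m = make_expression([[1], [1], [2]])
        out = normalize(m, "CPM")
        np.testing.assert_allclose(out.values().ravel(), [250000, 250000, 500000])
        assert out.unit == "CPM"

    def test_rpkm_closed_form(self):
        counts = np.zeros((2, 1))
        counts[0, 0] = 10
        counts[1, 0] = 1e6 - 10
        m = make_expression(counts)
        out = normalize(m, "RPKM", lengths={"g0": 1000, "g1": 1000})
        assert out.data.iloc[0, 0] == pytest.approx(10.0)

    def test_tpm_columns_sum_to_million(self):
        rng = np.random.default_rng(0)
        m = make_expression(rng.integers(0, 500, (30, 5)))
        lengths = {f"g{i}": float(l) for i, l in
                   enumerate(rng.integers(200, 5000, 30))}
        out = normalize(m, "TPM", lengths=lengths)
        np.testing.assert_allclose(out.values().sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_library_and_missing_length_rejected(self):
        with pytest.raises(ValueError, match="zero library"):
            normalize(make_expression([[0], [0]]), "CPM")
        with pytest.raises(ValueError, match="missing length"):
            normalize(make_expression([[1], [2]]), "RPKM", lengths={"g0": 100})

    def test_non_count_input_rejected(self):
        m = make_expression([[1.0]], unit="CPM")
        with pytest.raises(ValueError, match="raw_count"):
            normalize(m, "CPM")


class TestScaling:
    def test_percentile_rank_map(self):
        m = make_expression([[3, 1, 2]])
        out = within_assay_scale(m, "percentile")
        np.testing.assert_allclose(out.values().ravel(), [1.0, 0.0, 0.5])

    def test_constant_gene_conventions(self):
        m = make_expression([[5, 5, 5]])
        assert (within_assay_scale(m, "percentile").values() == 0.5).all()
        assert (within_assay_scale(m, "zscore").values() == 0.0).all()

    def test_zscore_idempotent_on_standardized_gene(self):
        x = np.array([[-1.0, 0.0, 1.0]]) * np.sqrt(1.5)  # zero mean, unit variance
        m = ExpressionMatrix(pd.DataFrame(x, index=["g0"], columns=["a", "b", "c"]),
                             "scaled", "rnaseq")
        out = within_assay_scale(m, "zscore")
        np.testing.assert_allclose(out.values(), x, atol=1e-12)

    @given(st.lists(st.floats(0.1, 1e4), min_size=3, max_size=8, unique=True))
    @settings(max_examples=30, deadline=None)
    def test_percentile_invariant_to_monotone_transform(self, vals):
        m1 = make_expression([vals], unit="CPM")
        m2 = make_expression([list(np.log1p(vals))], unit="CPM")
        np.testing.assert_allclose(
            within_assay_scale(m1, "percentile").values(),
            within_assay_scale(m2, "percentile").values(),
        )


class TestLog2FC:
    def _pair(self, pre_vals, post_vals, patients=("p1", "p2")):
        meta = make_paired_meta(patients)
        pre = make_expression(pre_vals, samples=[f"{p}-pre" for p in patients],
                              unit="CPM")
        post = make_expression(post_vals, samples=[f"{p}-post" for p in patients],
                               unit="CPM")
        return pre, post, meta

    def test_equal_pre_post_gives_zero(self):
        pre, post, meta = self._pair([[4, 9]], [[4, 9]])
        fc = compute_log2fc(pre, post, meta)
        np.testing.assert_allclose(fc.values(), 0.0)

    def test_doubling_with_zero_pseudocount(self):
        pre, post, meta = self._pair([[4, 9]], [[8, 18]])
        fc = compute_log2fc(pre, post, meta, pseudocount=0.0)
        np.testing.assert_allclose(fc.values(), 1.0)

    def test_zero_pre_with_pseudocount_epsilon(self):
        eps = 0.25
        pre, post, meta = self._pair([[0.0, 0.0]], [[eps, eps]])
        fc = compute_log2fc(pre, post, meta, pseudocount=eps)
        np.testing.assert_allclose(fc.values(), 1.0)  # log2(2*eps / eps)

    def test_unit_mismatch_and_unpaired_rejected(self):
        pre, post, meta = self._pair([[1, 2]], [[1, 2]])
        bad_post = ExpressionMatrix(post.data, "TPM", post.assay)
        with pytest.raises(ValueError, match="mismatch"):
            compute_log2fc(pre, bad_post, meta)
        half = ExpressionMatrix(post.data.iloc[:, :1], post.unit, post.assay)
        with pytest.raises(ValueError, match="not paired"):
            compute_log2fc(pre, half, meta)

    @given(
        st.lists(st.floats(0.0, 1e4), min_size=4, max_size=4),
        st.lists(st.floats(0.0, 1e4), min_size=4, max_size=4),
    )
    @settings(max_examples=40, deadline=None)
    def test_antisymmetry_under_timepoint_swap(self, a, b):
        """Swapping the pre and post measurements negates every entry exactly."""
        pre, post, meta = self._pair(
            np.array(a).reshape(2, 2), np.array(b).reshape(2, 2)
        )
        fwd = compute_log2fc(pre, post, meta).values()
        # rebuild with the measurements swapped but the sample ids kept
        pre2 = ExpressionMatrix(
            pd.DataFrame(post.values(), index=pre.gene_ids, columns=pre.sample_ids),
            pre.unit, pre.assay)
        post2 = ExpressionMatrix(
            pd.DataFrame(pre.values(), index=post.gene_ids, columns=post.sample_ids),
            post.unit, post.assay)
        rev = compute_log2fc(pre2, post2, meta).values()
        np.testing.assert_allclose(rev, -fwd)


class TestPseudobulk:
    def test_sums_and_group_all_consistency(self):
        counts = pd.DataFrame(
            [[1, 3, 5], [2, 4, 6]], index=["g1", "g2"], columns=["c1", "c2", "c3"]
        )
        labels = pd.DataFrame({
            "cell_id": ["c1", "c2", "c3"],
            "sample_id": ["s1", "s1", "s1"],
            "cell_type": ["T", "T", "B"],
        })
        per_type = pseudobulk(counts, labels, group="cell_type")
        np.testing.assert_allclose(per_type.data["s1|T"], [4, 6])
        np.testing.assert_allclose(per_type.data["s1|B"], [5, 6])
        total = pseudobulk(counts, labels, group="all")
        np.testing.assert_allclose(
            total.data["s1"],
            per_type.data[["s1|T", "s1|B"]].sum(axis=1),
        )

    def test_single_cell_group_equals_that_cell(self):
        counts = pd.DataFrame([[7], [9]], index=["g1", "g2"], columns=["c1"])
        labels = pd.DataFrame({"cell_id": ["c1"], "sample_id": ["s1"],
                               "cell_type": ["NK"]})
        out = pseudobulk(counts, labels)
        np.testing.assert_allclose(out.data["s1|NK"], [7, 9])

    def test_unlabeled_cell_rejected(self):
        counts = pd.DataFrame([[1]], index=["g1"], columns=["c1"])
        labels = pd.DataFrame({"cell_id": ["other"], "sample_id": ["s1"],
                               "cell_type": ["T"]})
        with pytest.raises(ValueError, match="unlabeled"):
            pseudobulk(counts, labels)


class TestAggregateCounts:
    def _two_isoform_model(self):
        return GeneModel(
            isoforms_of={"g1": ("g1.A", "g1.B")},
            exons_of={"g1.A": (("chr1", 0, 500),),
                      "g1.B": (("chr1", 600, 800), ("chr1", 900, 1000))},
            probe_of={"g1": ("chr1", 610, 700)},  # probe on isoform B only
        )

    def test_single_isoform_all_modes_agree(self):
        gm = GeneModel(
            isoforms_of={"g1": ("g1.A",)},
            exons_of={"g1.A": (("chr1", 0, 300),)},
            probe_of={"g1": ("chr1", 10, 100)},
        )
        iso = make_expression([[5, 7]], genes=["g1.A"])
        exon = make_expression([[5, 7]], genes=["g1.A:0"])
        results = [
            aggregate_counts(iso, gm, mode=m, exon_level=exon).values()
            for m in ("all_isoforms", "highest_expressed_isoform",
                      "probe_matched_isoform", "probe_matched_exon")
        ]
        for r in results[1:]:
            np.testing.assert_allclose(r, results[0])

    def test_probe_matched_vs_highest_expressed(self):
        gm = self._two_isoform_model()
        # isoform A carries the higher counts; probe sits on isoform B
        iso = make_expression([[100, 120], [10, 12]], genes=["g1.A", "g1.B"])
        probe = aggregate_counts(iso, gm, mode="probe_matched_isoform")
        highest = aggregate_counts(iso, gm, mode="highest_expressed_isoform")
        np.testing.assert_allclose(probe.data.loc["g1"], [10, 12])
        np.testing.assert_allclose(highest.data.loc["g1"], [100, 120])
        summed = aggregate_counts(iso, gm, mode="all_isoforms")
        np.testing.assert_allclose(summed.data.loc["g1"], [110, 132])

    def test_probe_overlap_tie_breaks_to_smallest_isoform_id(self):
        gm = GeneModel(
            isoforms_of={"g1": ("g1.B", "g1.A")},
            exons_of={"g1.A": (("chr1", 0, 100),), "g1.B": (("chr1", 0, 100),)},
            probe_of={"g1": ("chr1", 10, 60)},  # equal overlap with both
        )
        iso = make_expression([[3, 4], [7, 8]], genes=["g1.B", "g1.A"])
        out = aggregate_counts(iso, gm, mode="probe_matched_isoform")
        np.testing.assert_allclose(out.data.loc["g1"], [7, 8])  # g1.A wins the tie

    def test_probe_mode_requires_probe(self):
        gm = GeneModel(isoforms_of={"g1": ("g1.A",)},
                       exons_of={"g1.A": (("chr1", 0, 100),)})
        iso = make_expression([[1, 2]], genes=["g1.A"])
        with pytest.raises(ValueError, match="probe"):
            aggregate_counts(iso, gm, mode="probe_matched_isoform")
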