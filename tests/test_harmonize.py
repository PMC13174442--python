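"""Concordance, detection limits, effect sizes and dynamic-range diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xassay import harmonize
from xassay.harmonize import (
    ConcordanceTable,
    classify_gene_concordance,
    cliffs_delta,
    compare_isoform_log2fc,
    counting_improvement,
    dynamic_range_test,
    estimate_detection_limits,
    gene_correlations,
    pca_overlap,
)

from .conftest import make_expression, make_fc


class TestGeneCorrelations:
    def test_identical_matrices_give_rho_one(self):
        rng = np.random.default_rng(0)
        a = make_expression(rng.uniform(1, 100, (10, 6)), unit="CPM")
        rho = gene_correlations(a, a)
        np.testing.assert_allclose(rho, 1.0)

    def test_rank_reversal_gives_minus_one(self):
        a = make_expression([[1, 2, 3, 4, 5]], unit="CPM")
        b = make_expression([[9, 8, 7, 6, 5]], unit="CPM")
        assert gene_correlations(a, b).iloc[0] == pytest.approx(-1.0)

    def test_constant_gene_masked(self):
        a = make_expression([[2, 2, 2, 2]], unit="CPM")
        b = make_expression([[1, 2, 3, 4]], unit="CPM")
        assert np.isnan(gene_correlations(a, b).iloc[0])

    def test_fewer_than_four_pairs_masked(self):
        a = make_expression([[1, 2, 3]], unit="CPM")
        assert gene_correlations(a, a).isna().all()


def _table_from_bins(bin_medians_high_to_low, genes_per_bin=20, seed=0):
    """Build a ConcordanceTable whose per-decile median rho is controlled.

    ``bin_medians_high_to_low`` runs from the highest-expression bin down.
    """
    rng = np.random.default_rng(seed)
    n_bins = len(bin_medians_high_to_low)
    rhos, levels = [], []
    for i, med in enumerate(reversed(bin_medians_high_to_low)):  # low -> high
        rhos += [med] * genes_per_bin
        levels += list(100.0 * (i + 1) + rng.uniform(0, 50, genes_per_bin))
    idx = [f"g{i}" for i in range(n_bins * genes_per_bin)]
    rho = pd.Series(rhos, index=idx)
    level = pd.Series(levels, index=idx)
    return ConcordanceTable(
        rho=pd.DataFrame({"v1": rho, "v2": rho}),
        median_expression=level,
        expression_range=level / 2.0,
    )


class TestDetectionLimits:
    def test_strict_cutoff_at_first_bin_below_floor(self):
        """Medians (0.90, 0.90, 0.88, 0.50, 0.30) from the top bin down with
        strict floor 0.7: the strict cutoff is the lower edge of bin 4."""
        ct = _table_from_bins([0.90, 0.90, 0.88, 0.50, 0.30], genes_per_bin=20)
        lod = estimate_detection_limits(ct, n_bins=5, strict_floor=0.7)
        bins = lod.expression_bins
        assert lod.strict_expression == pytest.approx(bins["lower_edge"].iloc[1])
        # bin 4 counting from the top of 5 bins = ascending index 1
        below = ct.median_expression < lod.strict_expression
        assert below.mean() == pytest.approx(0.2)

    def test_uniformly_high_rho_gives_zero_cutoffs(self):
        ct = _table_from_bins([0.9] * 10, genes_per_bin=10)
        lod = estimate_detection_limits(ct, n_bins=10)
        assert lod.strict_expression == 0.0
        assert lod.loose_expression == 0.0
        assert lod.strict_range == 0.0 and lod.loose_range == 0.0

    def test_loose_cutoff_triggers_on_small_decline(self):
        ct = _table_from_bins([0.92, 0.92, 0.92, 0.80, 0.78], genes_per_bin=20)
        lod = estimate_detection_limits(ct, n_bins=5, loose_drop=0.05, strict_floor=0.7)
        # first declining bin scanning down is the 4th of 5: lower edge at q=0.2
        assert (ct.median_expression < lod.loose_expression).mean() == pytest.approx(0.2)
        assert lod.strict_expression == 0.0  # never below 0.7

    def test_insufficient_genes_rejected(self):
        ct = _table_from_bins([0.9, 0.8], genes_per_bin=3)
        with pytest.raises(ValueError, match="at least"):
            estimate_detection_limits(ct, n_bins=10)

    def test_invariant_to_monotone_rescaling(self):
        """Quantile binning makes the below-cutoff gene set invariant to any
        strictly monotone transform of the expression axis."""
        ct = _table_from_bins([0.95, 0.93, 0.91, 0.6, 0.3, 0.2], genes_per_bin=15)
        lod1 = estimate_detection_limits(ct, n_bins=6)
        ct2 = ConcordanceTable(
            rho=ct.rho,
            median_expression=np.log1p(ct.median_expression) ** 2,
            expression_range=ct.expression_range,
        )
        lod2 = estimate_detection_limits(ct2, n_bins=6)
        below1 = ct.median_expression < lod1.strict_expression
        below2 = ct2.median_expression < lod2.strict_expression
        pd.testing.assert_series_equal(below1, below2)


class TestConcordanceClasses:
    @pytest.mark.parametrize(
        "rhos,expected",
        [
            ((0.9, 0.92, 0.88), "consistent_high"),
            ((0.5, 0.6, 0.7), "consistent_low"),
            ((0.9, 0.7, 0.9), "preprocessing_dependent"),
        ],
    )
    def test_threshold_085_classes(self, rhos, expected):
        ct = ConcordanceTable(
            rho=pd.DataFrame([rhos], index=["g1"],
                             columns=[f"v{i}" for i in range(len(rhos))]),
            median_expression=pd.Series([1.0], index=["g1"]),
            expression_range=pd.Series([1.0], index=["g1"]),
        )
        assert classify_gene_concordance(ct).loc["g1"] == expected

    def test_single_variant_rejected(self):
        ct = ConcordanceTable(
            rho=pd.DataFrame({"v1": [0.9]}, index=["g1"]),
            median_expression=pd.Series([1.0], index=["g1"]),
            expression_range=pd.Series([1.0], index=["g1"]),
        )
        with pytest.raises(ValueError, match="2 preprocessing"):
            classify_gene_concordance(ct)


class TestCountingImprovement:
    @pytest.mark.parametrize(
        "gains,expected",
        [
            ((0.06, 0.06, 0.01), "isoform_better"),
            ((0.04, 0.04, 0.04), "neither"),
            ((0.06, 0.04, 0.06), "isoform_better"),
            ((-0.06, -0.06, 0.0), "exon_better"),
        ],
    )
    def test_two_of_three_rule(self, gains, expected):
        base = np.array([0.5, 0.5, 0.5])
        rho_iso = pd.DataFrame([base + np.array(gains)], index=["g1"],
                               columns=["CPM", "RPKM", "TPM"])
        rho_exon = pd.DataFrame([base], index=["g1"], columns=["CPM", "RPKM", "TPM"])
        out = counting_improvement(rho_iso, rho_exon)
        assert out.loc["g1", "flag"] == expected

    def test_below_limit_annotation(self):
        from xassay.harmonize import DetectionLimits

        rho_iso = pd.DataFrame([[0.9, 0.9, 0.9]], index=["g1"],
                               columns=["CPM", "RPKM", "TPM"])
        rho_exon = pd.DataFrame([[0.5, 0.5, 0.5]], index=["g1"],
                                columns=["CPM", "RPKM", "TPM"])
        out = counting_improvement(
            rho_iso, rho_exon,
            lod=DetectionLimits(10.0, 50.0, 0.0, 0.0),
            expression_isoform=pd.Series([100.0], index=["g1"]),
            expression_exon=pd.Series([5.0], index=["g1"]),
        )
        assert out.loc["g1", "flag"] == "isoform_better"
        assert not out.loc["g1", "isoform_below_limit"]
        assert out.loc["g1", "exon_below_limit"]


class TestIsoformLog2FCComparison:
    def test_identical_inputs(self):
        fc = make_fc(np.random.default_rng(0).normal(size=(20, 5)))
        out = compare_isoform_log2fc(fc, fc)
        assert out["r_squared"] == pytest.approx(1.0)
        assert out["outliers"] == []

    def test_shifted_gene_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(20, 5))
        b = a.copy()
        b[3] += 6.0
        out = compare_isoform_log2fc(make_fc(a), make_fc(b))
        assert out["outliers"] == ["g3"]

    def test_r2_equals_squared_pearson(self):
        import scipy.stats

        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(30, 4)), rng.normal(size=(30, 4))
        out = compare_isoform_log2fc(make_fc(a), make_fc(b))
        r = scipy.stats.pearsonr(a.mean(axis=1), b.mean(axis=1))[0]
        assert out["r_squared"] == pytest.approx(r**2)


def brute_force_cliffs(x, y):
    g = sum(1 for xi in x for yj in y if xi > yj)
    l = sum(1 for xi in x for yj in y if xi < yj)
    return (g - l) / (len(x) * len(y))


class TestCliffsDelta:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2], [3, 4], -1.0),
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([1, 3], [2, 4], -0.5),
        ],
    )
    def test_hand_enumerated_values(self, x, y, expected):
        assert cliffs_delta(x, y) == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cliffs_delta([], [1.0])

    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=12),
        st.lists(st.integers(-5, 5), min_size=1, max_size=12),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_pairwise_enumeration_and_antisymmetry(self, x, y):
        d = cliffs_delta(x, y)
        assert d == pytest.approx(brute_force_cliffs(x, y))
        assert cliffs_delta(y, x) == pytest.approx(-d)

    def test_magnitude_one_iff_disjoint_supports(self):
        assert cliffs_delta([5, 6], [1, 2]) == 1.0
        assert abs(cliffs_delta([1, 3], [2, 4])) < 1.0


class TestDynamicRange:
    def test_identical_groups_unlabeled(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=200)
        out = dynamic_range_test({"a": g, "b": g.copy()})
        row = out.iloc[0]
        assert row["cliffs_delta"] == pytest.approx(0.0)
        assert row["adj_p"] > 0.5
        assert row["label"] == ""

    def test_three_groups_give_three_pairs(self):
        rng = np.random.default_rng(1)
        out = dynamic_range_test({k: rng.normal(size=30) for k in "abc"})
        assert len(out) == 3
        assert set(zip(out["group_a"], out["group_b"])) == {
            ("a", "b"), ("a", "c"), ("b", "c")
        }

    def test_compressed_assay_flagged(self):
        """Microarray-style compression (0.5) shrinks |log2FC| enough to hit
        the |delta| >= 0.33 effect-size tier against RNA-seq."""
        rng = np.random.default_rng(2)
        base = np.abs(rng.normal(0, 1.0, 300))
        out = dynamic_range_test({"microarray": 0.5 * base,
                                  "rnaseq": np.abs(rng.normal(0, 1.0, 300))})
        row = out.iloc[0]
        assert abs(row["cliffs_delta"]) >= 0.33
        assert row["label"] != ""

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            dynamic_range_test({"a": np.array([1.0]), "b": np.ones(5)})


class TestPCAOverlap:
    def test_identically_generated_assays_mix(self):
        rng = np.random.default_rng(3)
        shared = rng.normal(size=(50, 40))
        mats = {"c1": pd.DataFrame(shared[:, :20]),
                "c2": pd.DataFrame(shared[:, 20:], columns=range(20, 40))}
        out = pca_overlap(mats, {"c1": "rnaseq", "c2": "nanostring"})
        assert abs(out["silhouette"]) < 0.1

    def test_offset_assay_separates(self):
        rng = np.random.default_rng(4)
        a = pd.DataFrame(rng.normal(size=(50, 15)))
        b = pd.DataFrame(rng.normal(size=(50, 15)) + 10.0, columns=range(15, 30))
        out = pca_overlap({"c1": a, "c2": b}, {"c1": "rnaseq", "c2": "microarray"})
        assert out["silhouette"] > 0.5

    def test_single_assay_rejected(self):
        mats = {"c1": pd.DataFrame(np.random.default_rng(0).normal(size=(10, 5)))}
        with pytest.raises(ValueError, match="single assay"):
            pca_overlap(mats, {"c1": "rnaseq"})
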