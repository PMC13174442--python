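"""F-scores, consensus selection and the predictive-frequency bootstrap."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from xassay.features import (
    FeatureSelectionConfig,
    bootstrap_predictive_frequency,
    compare_frequency_tables,
    consensus_select,
    f_score,
    f_score_matrix,
    rank_candidates,
)
from xassay.harmonize import DetectionLimits

from .conftest import make_fc


class TestFScore:
    def test_hand_computed_anova(self):
        # SSB = 13.5, SSW = 4, df = (1, 4) -> F = 13.5
        assert f_score([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1]) == pytest.approx(13.5)

    def test_identical_distributions_give_zero(self):
        assert f_score([1, 2, 1, 2], [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_degenerate_separation_gives_infinity(self):
        assert f_score([1, 1, 2, 2], [0, 0, 1, 1]) == np.inf

    def test_all_constant_gives_zero(self):
        assert f_score([3, 3, 3, 3], [0, 0, 1, 1]) == 0.0

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            f_score([1, 2, 3], [0, 0, 1])

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(50, 24))
        labels = np.array([0] * 10 + [1] * 14)
        ours = f_score_matrix(x, labels)
        ref = scipy.stats.f_oneway(x[:, labels == 0], x[:, labels == 1], axis=1)
        np.testing.assert_allclose(ours, ref.statistic, rtol=1e-10)


class TestConsensus:
    def _fc_with_ranking(self, patients, effect_genes, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(20, len(patients)))
        half = len(patients) // 2
        for rank, g in enumerate(effect_genes):
            x[g, half:] += 10.0 - rank  # effects far above the noise floor
        return make_fc(x, patients=patients)

    def test_identical_rankings_intersect_to_top_k(self):
        labels = {f"p{j}": ("a" if j < 4 else "b") for j in range(8)}
        labels.update({f"q{j}": ("a" if j < 4 else "b") for j in range(8)})
        fc1 = self._fc_with_ranking([f"p{j}" for j in range(8)], [0, 1, 2, 3, 4], 1)
        fc2 = self._fc_with_ranking([f"q{j}" for j in range(8)], [0, 1, 2, 3, 4], 2)
        out = consensus_select({"c1": fc1, "c2": fc2}, labels, k=5)
        assert set(out) == {"g0", "g1", "g2", "g3", "g4"}

    def test_disjoint_top_k_gives_empty(self):
        labels = {f"p{j}": ("a" if j < 4 else "b") for j in range(8)}
        labels.update({f"q{j}": ("a" if j < 4 else "b") for j in range(8)})
        fc1 = self._fc_with_ranking([f"p{j}" for j in range(8)], [0, 1], 1)
        fc2 = self._fc_with_ranking([f"q{j}" for j in range(8)], [10, 11], 2)
        assert consensus_select({"c1": fc1, "c2": fc2}, labels, k=2) == []

    def test_single_cohort_degenerates_to_its_top_k(self):
        labels = {f"p{j}": ("a" if j < 4 else "b") for j in range(8)}
        fc1 = self._fc_with_ranking([f"p{j}" for j in range(8)], [3, 7], 1)
        out = consensus_select({"c1": fc1}, labels, k=2)
        assert set(out) == {"g3", "g7"}


def replay_bootstrap(fc, labels, cohort_of, cfg):
    """Independent re-implementation replaying the identical RNG stream."""
    patients = list(fc.patient_ids)
    lab = np.array([labels[p] for p in patients])
    classes = sorted(set(lab))
    genes = list(fc.gene_ids)
    sizes = {}
    for p in patients:
        sizes[cohort_of[p]] = sizes.get(cohort_of[p], 0) + 1
    w = np.array([1.0 / sizes[cohort_of[p]] for p in patients])
    idx_by_class, w_by_class = [], []
    for c in classes:
        ii = [i for i, l in enumerate(lab) if l == c]
        ww = w[ii] / w[ii].sum()
        idx_by_class.append(np.array(ii))
        w_by_class.append(ww)
    n_min = min(len(i) for i in idx_by_class)
    rng = np.random.default_rng(cfg.seed)
    hits = {g: 0 for g in genes}
    boot_labels = np.repeat(classes, n_min)
    vals = fc.values()
    for _ in range(cfg.B):
        cols = np.concatenate([
            rng.choice(ii, size=n_min, replace=True, p=ww)
            for ii, ww in zip(idx_by_class, w_by_class)
        ])
        # per-gene two-group ANOVA, computed the slow way
        fs = []
        for gi in range(len(genes)):
            v = vals[gi, cols]
            groups = [v[boot_labels == c] for c in classes]
            grand = v.mean()
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            if ssw == 0:
                fs.append(np.inf if ssb > 0 else 0.0)
            else:
                fs.append((ssb / 1) / (ssw / (len(v) - 2)))
        order = sorted(range(len(genes)), key=lambda i: (-fs[i], genes[i]))
        for i in order[: cfg.top_m]:
            hits[genes[i]] += 1
    return pd.Series({g: hits[g] / cfg.B for g in genes})


class TestBootstrap:
    def _setup(self, n_genes=10, n_patients=12, seed=5):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n_genes, n_patients))
        patients = [f"p{j}" for j in range(n_patients)]
        labels = {p: ("a" if j % 2 == 0 else "b") for j, p in enumerate(patients)}
        cohort_of = {p: ("c1" if j < 4 else "c2") for j, p in enumerate(patients)}
        return make_fc(x, patients=patients), labels, cohort_of

    def test_exact_replay_oracle(self):
        """Frequencies match an independent replay of the identical draws."""
        fc, labels, cohort_of = self._setup()
        cfg = FeatureSelectionConfig(B=20, top_m=3, max_features=3, seed=17)
        ours = bootstrap_predictive_frequency(fc, labels, cohort_of, cfg)
        theirs = replay_bootstrap(fc, labels, cohort_of, cfg)
        pd.testing.assert_series_equal(
            ours.frequencies.sort_index(), theirs.sort_index(),
            check_names=False, check_exact=True,
        )

    def test_every_draw_records_exactly_top_m(self):
        fc, labels, cohort_of = self._setup(n_genes=30)
        cfg = FeatureSelectionConfig(B=40, top_m=7, max_features=5, seed=3)
        pft = bootstrap_predictive_frequency(fc, labels, cohort_of, cfg)
        # sum of frequencies * B = total selections = B * top_m exactly
        assert pft.frequencies.sum() * cfg.B == pytest.approx(cfg.B * cfg.top_m)

    def test_inverse_size_weighting_equalizes_cohorts(self):
        """Cohorts of 10 and 30 patients: the small cohort supplies ~half of
        the drawn patients (inverse-size weights equalize in expectation)."""
        rng = np.random.default_rng(0)
        n = 40
        patients = [f"p{j}" for j in range(n)]
        labels = {p: ("a" if j % 2 == 0 else "b") for j, p in enumerate(patients)}
        cohort_of = {p: ("small" if j < 10 else "big") for j, p in enumerate(patients)}
        fc = make_fc(rng.normal(size=(5, n)), patients=patients)

        # count drawn-patient cohort shares over many draws using the same
        # sampling scheme exposed through the bootstrap
        sizes = {"small": 10, "big": 30}
        w = np.array([1.0 / sizes[cohort_of[p]] for p in patients])
        share = []
        rng2 = np.random.default_rng(123)
        for c in ("a", "b"):
            idx = np.array([i for i, p in enumerate(patients) if labels[p] == c])
            ww = w[idx] / w[idx].sum()
            draws = rng2.choice(idx, size=(2000, len(idx)), replace=True, p=ww)
            share.append(np.mean([cohort_of[patients[i]] == "small"
                                  for i in draws.ravel()]))
        assert np.mean(share) == pytest.approx(0.5, abs=0.05)

    def test_label_permutation_null_frequency(self):
        """With shuffled labels every gene's selection frequency centers on
        top_m / n_genes."""
        rng = np.random.default_rng(9)
        n_genes, n = 40, 24
        patients = [f"p{j}" for j in range(n)]
        labels = {p: ("a" if j < 12 else "b") for j, p in enumerate(patients)}
        cohort_of = {p: "c1" for p in patients}
        fc = make_fc(rng.normal(size=(n_genes, n)), patients=patients)
        cfg = FeatureSelectionConfig(B=500, top_m=8, max_features=8, seed=31)
        pft = bootstrap_predictive_frequency(fc, labels, cohort_of, cfg)
        p_null = cfg.top_m / n_genes
        # every draw records exactly top_m genes, so the across-gene mean
        # frequency is pinned at top_m / n_genes; under a permuted labeling
        # the selections also spread over many genes rather than a clique
        assert pft.frequencies.mean() == pytest.approx(p_null)
        assert (pft.frequencies > 0).mean() > 0.5

    def test_planted_gene_dominates(self):
        rng = np.random.default_rng(4)
        n = 30
        patients = [f"p{j}" for j in range(n)]
        labels = {p: ("a" if j < 15 else "b") for j, p in enumerate(patients)}
        cohort_of = {p: "c1" for p in patients}
        x = rng.normal(size=(20, n))
        x[7, 15:] += 4.0
        fc = make_fc(x, patients=patients)
        cfg = FeatureSelectionConfig(B=200, top_m=1, max_features=1, seed=8)
        pft = bootstrap_predictive_frequency(fc, labels, cohort_of, cfg)
        assert pft.frequencies["g7"] >= 0.95

    def test_missing_class_and_oversized_top_m_rejected(self):
        fc, labels, cohort_of = self._setup()
        one_class = {p: "a" for p in labels}
        cfg = FeatureSelectionConfig(B=5, top_m=3, max_features=3)
        with pytest.raises(ValueError, match="both label classes|2 classes"):
            bootstrap_predictive_frequency(fc, one_class, cohort_of, cfg)
        cfg_big = FeatureSelectionConfig(B=5, top_m=100, max_features=3)
        with pytest.raises(ValueError, match="top_m"):
            bootstrap_predictive_frequency(fc, labels, cohort_of, cfg_big)


class TestRankCandidates:
    def _pft(self, n_genes=30, seed=0):
        rng = np.random.default_rng(seed)
        from xassay.features import PredictiveFrequencyTable

        freq = rng.uniform(0, 1, n_genes)
        table = pd.DataFrame({
            "predictive_frequency": freq,
            "mean_f": rng.uniform(0, 10, n_genes),
            "rank": np.arange(1, n_genes + 1),
        }, index=[f"g{i:02d}" for i in range(n_genes)])
        return PredictiveFrequencyTable(table=table, B=100, top_m=n_genes)

    def test_cap_at_25(self):
        out = rank_candidates(self._pft(30), max_features=25)
        assert len(out) == 25

    def test_lod_filter_excludes_low_genes(self):
        pft = self._pft(30)
        level = pd.Series(100.0, index=pft.table.index)
        top_gene = pft.frequencies.idxmax()
        level[top_gene] = 1.0  # below the strict cutoff
        lod = DetectionLimits(strict_expression=10.0, loose_expression=5.0,
                              strict_range=0.0, loose_range=0.0)
        out = rank_candidates(pft, lod=lod, expression_level=level)
        assert top_gene not in out

    def test_panel_filter_and_all_filtered_error(self):
        pft = self._pft(10)
        out = rank_candidates(pft, panel=["g00", "g01"], max_features=25)
        assert set(out) <= {"g00", "g01"}
        with pytest.raises(ValueError, match="filtered out"):
            rank_candidates(pft, panel=["absent"])

    def test_deterministic_tie_break(self):
        from xassay.features import PredictiveFrequencyTable

        table = pd.DataFrame({
            "predictive_frequency": [0.5, 0.5, 0.5],
            "mean_f": [2.0, 2.0, 3.0],
            "rank": [1, 2, 3],
        }, index=["gB", "gA", "gC"])
        pft = PredictiveFrequencyTable(table=table, B=10, top_m=3)
        out = rank_candidates(pft, max_features=3)
        assert out == ["gC", "gA", "gB"]  # mean F first, then gene id


class TestCompareFrequencyTables:
    def test_identical_tables_give_rho_one(self):
        pft = TestRankCandidates()._pft(20)
        assert compare_frequency_tables(pft, pft) == pytest.approx(1.0)

    def test_independent_tables_near_zero(self):
        rhos = [
            compare_frequency_tables(
                TestRankCandidates()._pft(1000, seed=2 * s),
                TestRankCandidates()._pft(1000, seed=2 * s + 1),
            )
            for s in range(20)
        ]
        assert np.mean(np.abs(np.array(rhos)) < 0.1) >= 0.95

    def test_insufficient_overlap_rejected(self):
        a = TestRankCandidates()._pft(3)
        with pytest.raises(ValueError, match="4 shared"):
            compare_frequency_tables(a, a)


def test_noise_genes_never_improve_planted_rank():
    """Appending pure-noise genes cannot move a planted gene up in rank."""
    rng = np.random.default_rng(6)
    n = 20
    patients = [f"p{j}" for j in range(n)]
    labels = np.array([0] * 10 + [1] * 10)
    x = rng.normal(size=(30, n))
    x[5, 10:] += 2.0
    f_small = f_score_matrix(x, labels)
    rank_small = 1 + (f_small > f_small[5]).sum()
    x_big = np.vstack([x, rng.normal(size=(50, n))])
    f_big = f_score_matrix(x_big, labels)
    rank_big = 1 + (f_big > f_big[5]).sum()
    assert f_big[5] == pytest.approx(f_small[5])
    assert rank_big >= rank_small
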