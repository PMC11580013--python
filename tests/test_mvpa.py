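"""Outcome labeling, feature assembly, LOOCV SVM, permutation inference."""

import numpy as np
import pytest

from netstates import mvpa as mv
from netstates import synthcohort as sc


def feature_table(blocks, labels, set_tag="sfc", k=11):
    """Assemble a FeatureTable from raw planted blocks."""
    n = labels.size
    ids = [f"P{i:03d}" for i in range(n)]

    def as_matrix(row):
        m = np.zeros((k, k))
        m[np.triu_indices(k, 1)] = row
        return m + m.T

    sfc = {s: as_matrix(blocks["sfc"][i]) for i, s in enumerate(ids)}
    if set_tag == "sfc":
        return mv.assemble_features(ids, "sfc", sfc=sfc)
    dmean = {s: as_matrix(blocks["dfc_mean"][i]) for i, s in enumerate(ids)}
    dsd = {s: as_matrix(blocks["dfc_sd"][i]) for i, s in enumerate(ids)}
    temp = {s: blocks["temporal"][i] for i, s in enumerate(ids)}
    return mv.assemble_features(ids, set_tag, sfc=sfc, dfc_mean=dmean,
                                dfc_sd=dsd, temporal=temp)


FAST = mv.MvpaConfig(lasso_lambda=0.2, n_permutations=100)


class TestLabelOutcomes:
    def _patient(self, pre, post):
        return sc.ClinicalRecord("P", "patient", 50.0, "F", 12.0,
                                 joa_pre=pre, joa_post=post)

    def test_threshold_split(self):
        recs = [self._patient(11, 11 + 0.9 * 6), self._patient(11, 11 + 0.5 * 6)]
        labels, rates = mv.label_outcomes(recs, cutoff=0.75)
        assert labels.tolist() == [1, 0]
        np.testing.assert_allclose(rates, [0.9, 0.5])

    def test_boundary_rate_counts_as_good(self):
        recs = [self._patient(11, 11 + 0.75 * 6), self._patient(11, 11)]
        labels, _ = mv.label_outcomes(recs, cutoff=0.75)
        assert labels.tolist() == [1, 0]

    def test_single_class_flagged(self):
        recs = [self._patient(11, 17), self._patient(9, 17)]
        with pytest.warns(UserWarning, match="single-class"):
            mv.label_outcomes(recs, cutoff=0.75)

    def test_ceiling_pre_score_propagates_error(self):
        recs = [self._patient(17, 17)]
        with pytest.raises(ValueError):
            mv.label_outcomes(recs)


class TestAssembleFeatures:
    def setup_method(self):
        self.blocks, self.labels = sc.generate_prognosis_features(
            n_good=6, n_poor=6, seed=0
        )

    def test_sfc_has_55_features(self):
        assert feature_table(self.blocks, self.labels, "sfc").values.shape[1] == 55

    def test_dfc_has_115_features(self):
        table = feature_table(self.blocks, self.labels, "dfc_fls")
        assert table.values.shape[1] == 115
        # 55 means + 55 SDs + 5 temporal properties
        assert sum(n.startswith("dfc_mean") for n in table.feature_names) == 55
        assert sum(n.startswith("dfc_sd") for n in table.feature_names) == 55

    def test_fusion_has_170_features(self):
        table = feature_table(self.blocks, self.labels, "fusion_dcc")
        assert table.values.shape[1] == 170
        assert table.feature_names[0] == "sfc_IC01-IC02"
        assert table.feature_names[-1] == "n_transitions"

    def test_missing_subject_reported(self):
        ids = ["A", "B"]
        with pytest.raises(ValueError, match="B"):
            mv.assemble_features(ids, "sfc", sfc={"A": np.zeros((11, 11))})

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            mv.assemble_features([], "banana")


class TestRocAuc:
    def test_perfectly_ordered_scores(self):
        _, auc = mv.roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = mv.roc_auc(np.zeros(6), np.array([0, 1, 0, 1, 0, 1]))
        assert auc == 0.5

    def test_hand_enumerated_mixed_case(self):
        # pair enumeration: wins 0.9>0.85, 0.9>0.1, 0.8>0.1; loss 0.8<0.85
        scores = np.array([0.9, 0.8, 0.85, 0.1])
        labels = np.array([1, 1, 0, 0])
        _, auc = mv.roc_auc(scores, labels)
        assert auc == pytest.approx(3.0 / 4)

    def test_half_win_counted_for_tied_pair(self):
        scores = np.array([0.9, 0.8, 0.8, 0.1])
        labels = np.array([1, 1, 0, 0])
        _, auc = mv.roc_auc(scores, labels)
        assert auc == pytest.approx(3.5 / 4)

    def test_matches_exhaustive_pair_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            labels = np.r_[np.ones(2, int), np.zeros(2, int),
                           rng.integers(0, 2, n - 4)]
            scores = np.round(rng.standard_normal(n), 1)  # force ties
            _, auc = mv.roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            brute = np.mean([
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p in pos for q in neg
            ])
            assert auc == pytest.approx(brute, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mv.roc_auc(np.arange(4.0), np.ones(4, int))


class TestLoocv:
    def test_separable_signal_classified_perfectly(self):
        blocks, labels = sc.generate_prognosis_features(
            n_good=20, n_poor=20, sfc_effect=4.0, n_signal_pairs=8, seed=1
        )
        table = feature_table(blocks, labels, "sfc")
        res = mv.loocv_classify(table, labels, FAST, seed=0)
        assert res.accuracy == 1.0
        assert res.auc == 1.0

    def test_chance_level_on_shuffled_labels(self):
        """At the study's sample size the null LOOCV accuracy stays within
        5 points of the majority-class rate."""
        accs = []
        rng = np.random.default_rng(0)
        for rep in range(30):
            blocks, labels = sc.generate_prognosis_features(
                n_good=20, n_poor=20, sfc_effect=2.0, seed=100 + rep, n_networks=5
            )
            table = feature_table(blocks, labels, "sfc", k=5)
            shuffled = rng.permutation(labels)
            res = mv.loocv_classify(table, shuffled, FAST, seed=rep)
            accs.append(res.accuracy)
        majority = 0.5
        assert abs(np.mean(accs) - majority) < 0.05

    def test_no_leakage_from_label_equal_feature(self):
        """A feature equal to the true labels is found by in-fold selection
        (near-perfect accuracy), but once labels are shuffled the same
        feature cannot help: any residual above-chance accuracy would
        reveal leakage of test-fold information."""
        rng = np.random.default_rng(3)
        n = 40
        labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        X = rng.standard_normal((n, 10))
        X[:, 0] = labels
        table = mv.FeatureTable([f"s{i}" for i in range(n)],
                                [f"f{j}" for j in range(10)], X, "sfc")
        res = mv.loocv_classify(table, labels, FAST, seed=0)
        assert res.accuracy >= 0.9  # selection does find the planted feature
        accs = []
        for rep in range(20):
            shuffled = rng.permutation(labels)
            accs.append(mv.loocv_classify(table, shuffled, FAST, seed=rep).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_determinism_with_fixed_seed(self):
        blocks, labels = sc.generate_prognosis_features(n_good=8, n_poor=8, seed=2)
        table = feature_table(blocks, labels, "fusion_fls")
        r1 = mv.loocv_classify(table, labels, FAST, seed=5)
        r2 = mv.loocv_classify(table, labels, FAST, seed=5)
        assert r1.accuracy == r2.accuracy and r1.auc == r2.auc
        np.testing.assert_array_equal(r1.scores, r2.scores)

    def test_single_class_rejected(self):
        blocks, labels = sc.generate_prognosis_features(n_good=4, n_poor=4, seed=0)
        table = feature_table(blocks, labels, "sfc")
        with pytest.raises(ValueError):
            mv.loocv_classify(table, np.ones_like(labels), FAST)


class TestPermutationTest:
    def _small_table(self, seed=0):
        blocks, labels = sc.generate_prognosis_features(
            n_good=5, n_poor=5, n_networks=4, seed=seed
        )
        return feature_table(blocks, labels, "sfc", k=4), labels

    def test_counting_definition_and_floor(self):
        table, labels = self._small_table()
        p, null = mv.permutation_test(table, labels, FAST, observed_accuracy=1.01, seed=0)
        # nothing can reach 1.01, so the count is 0 and p floors at 1/n
        assert p == pytest.approx(1 / 100)
        assert null.size == 100

    def test_observed_below_null_median_gives_large_p(self):
        table, labels = self._small_table(seed=1)
        p, null = mv.permutation_test(table, labels, FAST, observed_accuracy=0.0, seed=0)
        assert p > 0.5
        assert p == pytest.approx(np.sum(null >= 0.0) / 100)
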