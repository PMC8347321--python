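"""Metrics, applicability domain, similarity-binned performance, importances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cypclass as cc
from cypclass.consensus import ConsensusLabel, ConsensusPrediction
from cypclass.evaluate import (
    ConfusionCounts,
    jaccard_from_counts,
    mcc_from_counts,
    similarity_binned_performance,
)


def brute_force_auc(scores, truth):
    """Pair-counting oracle: ties between a positive and a negative count half."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


class TestClassificationMetrics:
    @pytest.mark.parametrize(
        "counts,mcc,jac",
        [
            (ConfusionCounts(50, 50, 0, 0), 1.0, 1.0),
            (ConfusionCounts(0, 0, 50, 50), -1.0, 0.0),
            (ConfusionCounts(25, 25, 25, 25), 0.0, 1 / 3),
        ],
    )
    def test_bounds_and_toy_values(self, counts, mcc, jac):
        report = cc.classification_metrics(counts)
        assert report.mcc == pytest.approx(mcc)
        assert report.jaccard == pytest.approx(jac)

    def test_zero_denominator_convention(self):
        assert mcc_from_counts(ConfusionCounts(10, 0, 0, 5)) == 0.0

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            cc.classification_metrics(ConfusionCounts(0, 0, 0, 0))

    @given(
        tp=st.integers(0, 30), tn=st.integers(0, 30),
        fp=st.integers(0, 30), fn=st.integers(0, 30),
    )
    @settings(derandomize=True, max_examples=300)
    def test_mcc_symmetric_under_class_swap(self, tp, tn, fp, fn):
        a = mcc_from_counts(ConfusionCounts(tp, tn, fp, fn))
        b = mcc_from_counts(ConfusionCounts(tn, tp, fn, fp))
        assert a == pytest.approx(b)

    def test_mcc_equals_pearson_phi_on_expanded_labels(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 20, size=4)
            y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            mine = mcc_from_counts(ConfusionCounts(tp, tn, fp, fn))
            if len(set(y_true)) < 2 or len(set(y_pred)) < 2:
                assert mine == 0.0
                continue
            phi = np.corrcoef(y_true, y_pred)[0, 1]
            assert mine == pytest.approx(phi)


class TestAuc:
    def test_perfect_and_inverted_rankings(self):
        assert cc.auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert cc.auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_toy_ranking_against_pair_counting(self):
        scores = [0.9, 0.7, 0.7, 0.5, 0.3, 0.1]
        truth = [1, 0, 1, 1, 0, 0]
        assert cc.auc(scores, truth) == pytest.approx(
            brute_force_auc(scores, truth)
        )

    def test_random_rankings_match_oracle_up_to_n_200(self):
        rng = np.random.default_rng(1)
        for n in (10, 50, 200):
            scores = np.round(rng.random(n), 2)  # coarse grid forces ties
            truth = rng.integers(0, 2, n)
            if len(np.unique(truth)) < 2:
                continue
            assert cc.auc(scores, truth) == pytest.approx(
                brute_force_auc(scores, truth)
            )

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            cc.auc([0.2, 0.4], [1, 1])


class TestTanimoto:
    def bits(self, idx, n=16):
        v = np.zeros(n, dtype=np.uint8)
        v[list(idx)] = 1
        return v

    def test_identity_disjoint_and_half_overlap(self):
        a = self.bits({1, 2, 3})
        assert cc.tanimoto(a, a) == 1.0
        assert cc.tanimoto(a, self.bits({5, 6})) == 0.0
        assert cc.tanimoto(a, self.bits({2, 3, 4})) == 0.5  # 2 shared / 4 union

    def test_both_empty_defined_zero(self):
        assert cc.tanimoto(self.bits(set()), self.bits(set())) == 0.0

    def test_length_mismatch_error(self):
        with pytest.raises(ValueError):
            cc.tanimoto(self.bits({1}), self.bits({1}, n=8))


class TestNearestTrainingSimilarity:
    def test_identical_query_is_reliable(self):
        train = np.zeros((3, 32), dtype=np.uint8)
        train[0, :5] = 1
        train[1, 10:20] = 1
        train[2, 25:30] = 1
        sim, reliable = cc.nearest_training_similarity(train[1], train)
        assert sim == 1.0 and reliable

    def test_threshold_inclusive_at_exactly_0_7(self):
        # max similarity exactly 7/10 -> reliable; 69/100 -> not
        train = np.zeros((1, 128), dtype=np.uint8)
        train[0, :7] = 1
        query = np.zeros(128, dtype=np.uint8)
        query[:10] = 1
        sim, reliable = cc.nearest_training_similarity(query, train)
        assert sim == pytest.approx(0.7) and reliable

        train2 = np.zeros((1, 128), dtype=np.uint8)
        train2[0, :69] = 1
        query2 = np.zeros(128, dtype=np.uint8)
        query2[:100] = 1
        sim2, reliable2 = cc.nearest_training_similarity(query2, train2)
        assert sim2 == pytest.approx(0.69) and not reliable2

    def test_empty_training_set_error(self):
        with pytest.raises(ValueError):
            cc.nearest_training_similarity(np.ones(8), np.empty((0, 8)))


class TestCoverage:
    def pred(self, label):
        return ConsensusPrediction(label=label, probability=None)

    def test_direct_counting(self):
        S, N, A = (ConsensusLabel.SUBSTRATE, ConsensusLabel.NON_SUBSTRATE,
                   ConsensusLabel.ABSTAIN)
        preds = [self.pred(x) for x in (S, A, S, N, A, N)]
        y = [1, 1, 1, 0, 0, 0]
        cov_sub, cov_non = cc.coverage(preds, y)
        assert cov_sub == pytest.approx(2 / 3)
        assert cov_non == pytest.approx(2 / 3)

    def test_absent_class_reports_none(self):
        preds = [self.pred(ConsensusLabel.SUBSTRATE)]
        assert cc.coverage(preds, [1]) == (1.0, None)


class TestSimilarityBinnedPerformance:
    def _monotone_case(self, reverse=False):
        # three bins with accuracy rising (or falling) across bins
        rng = np.random.default_rng(0)
        sims, truth, pred = [], [], []
        accs = [0.55, 0.75, 0.95]
        centers = [0.25, 0.55, 0.85]
        if reverse:
            accs = accs[::-1]
        for acc, center in zip(accs, centers):
            for _ in range(60):
                t = int(rng.random() < 0.5)
                p = t if rng.random() < acc else 1 - t
                truth.append(t)
                pred.append(p)
                sims.append(center + rng.uniform(-0.04, 0.04))
        return pred, truth, sims

    def test_monotone_accuracy_gives_perfect_rank_correlation(self):
        profile = similarity_binned_performance(*self._monotone_case())
        assert profile.spearman_r == pytest.approx(1.0)

    def test_reversed_construction_gives_negative_correlation(self):
        profile = similarity_binned_performance(*self._monotone_case(reverse=True))
        assert profile.spearman_r == pytest.approx(-1.0)

    def test_three_bin_toy_rank_correlation_by_hand(self):
        # bin MCCs will order as (low, high, mid) -> ranks (1,3,2) against
        # midpoints (1,2,3): Spearman rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 0.5
        pred = [1, 0, 1, 1, 0, 1, 1, 0, 0, 1, 1, 0]
        truth = [1, 1, 0, 1, 0, 1, 1, 0, 1, 1, 1, 0]
        sims = [0.15, 0.15, 0.15, 0.15, 0.45, 0.45, 0.45, 0.45,
                0.75, 0.75, 0.75, 0.75]
        profile = similarity_binned_performance(
            pred, truth, sims, bin_edges=(0.0, 0.3, 0.6, 0.9)
        )
        defined = [m for m in profile.bin_mcc if m is not None]
        assert len(defined) == 3
        ranks = np.argsort(np.argsort(defined)) + 1
        d2 = np.sum((ranks - np.array([1, 2, 3])) ** 2)
        rho_hand = 1 - 6 * d2 / (3 * 8)
        assert profile.spearman_r == pytest.approx(rho_hand)

    def test_fewer_than_two_defined_bins_reports_absent(self):
        profile = similarity_binned_performance(
            [1, 1], [1, 0], [0.95, 0.96], bin_edges=(0.0, 0.5, 1.0)
        )
        assert profile.spearman_r is None

    def test_degenerate_bins_reported_undefined(self):
        profile = similarity_binned_performance(
            [1, 1, 1, 0], [1, 1, 1, 0], [0.1, 0.1, 0.9, 0.9],
            bin_edges=(0.0, 0.5, 1.0),
        )
        assert profile.bin_mcc[0] is None      # single-class bin
        assert profile.bin_mcc[1] == pytest.approx(1.0)


class TestFeatureImportance:
    def test_importances_normalized_and_planted_feature_ranks_first(
        self, small_rf_model
    ):
        report = cc.feature_importance_report(small_rf_model["model"])
        total = sum(report.importances.values())
        assert total == pytest.approx(1.0)
        assert all(v >= 0 for v in report.importances.values())
        top = report.top(5)
        assert len(top) == 5 and top[0][1] >= top[-1][1]

    def test_single_informative_feature_takes_all_importance(self):
        from cypclass.curate import CypIsozyme
        from cypclass.train import Algorithm, train_final

        y = np.array([0, 1] * 20)
        rng = np.random.default_rng(0)
        X = np.column_stack([y.astype(float), np.full(40, 3.0)])
        spec = cc.SingleClassifierSpec(
            cyp=CypIsozyme("1A2"), algorithm=Algorithm.RF,
            feature_set=cc.FeatureSet.PHYSCHEM2D, n_estimators=20,
        )
        model = train_final(
            spec, X, y, {"min_samples_split": 2, "max_features": "sqrt",
                         "percentile": 100},
            feature_names=["planted", "flat"],
        )
        report = cc.feature_importance_report(model)
        assert report.importances == {"planted": pytest.approx(1.0)}

    def test_svm_model_unsupported(self, small_rf_model):
        model = small_rf_model["model"]
        svm_like = cc.TrainedClassifier(
            spec=cc.SingleClassifierSpec(
                cyp=model.spec.cyp, algorithm=cc.Algorithm.SVM,
                feature_set=model.spec.feature_set,
            ),
            params={}, preprocessor=model.preprocessor, learner=model.learner,
            feature_names=model.feature_names,
            train_fingerprints=model.train_fingerprints,
        )
        with pytest.raises(ValueError):
            cc.feature_importance_report(svm_like)
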