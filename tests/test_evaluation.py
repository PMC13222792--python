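"""Metrics, aggregation, significance tests, seed summaries, attribution."""

import math

import numpy as np
import pytest

from dysarthria_ssm.evaluation import (aggregate_speaker, binary_mcc,
                                       bootstrap_ci, channel_attribution,
                                       confusion_matrix, metrics,
                                       multiclass_mcc,
                                       paired_permutation_test, seed_summary)


def brute_force_macro(truth, pred, n_classes=5):
    """Independent per-class counting oracle for the macro metrics."""
    f1s, recalls, specs = [], [], []
    total = len(truth)
    for k in range(n_classes):
        if not np.any(truth == k):
            continue
        tp = int(np.sum((truth == k) & (pred == k)))
        fn = int(np.sum((truth == k) & (pred != k)))
        fp = int(np.sum((truth != k) & (pred == k)))
        tn = total - tp - fn - fp
        rec = tp / (tp + fn) if tp + fn else 0.0
        prec = tp / (tp + fp) if tp + fp else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
        recalls.append(rec)
        specs.append(spec)
    acc = 100.0 * np.mean(truth == pred)
    return acc, np.mean(f1s), np.mean(recalls), np.mean(specs)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3, 4] * 4)
        rep = metrics(y, y)
        assert rep.accuracy == 100.0
        assert rep.macro_f1 == 1.0
        assert rep.mcc == pytest.approx(1.0, abs=1e-12)

    def test_binary_mcc_hand_value(self):
        """TP=2, TN=3, FP=1, FN=4 gives (2*3-1*4)/sqrt(3*6*4*7) = 2/sqrt(504)."""
        assert binary_mcc(2, 3, 1, 4) == pytest.approx(2 / math.sqrt(504))

    def test_multiclass_mcc_reduces_to_binary(self):
        truth = np.array([1] * 6 + [0] * 4)            # P=6, N=4
        pred = np.array([1] * 2 + [0] * 4 + [1] * 1 + [0] * 3)
        # TP=2, FN=4, FP=1, TN=3
        assert multiclass_mcc(truth, pred, n_classes=2) == pytest.approx(
            binary_mcc(2, 3, 1, 4))

    def test_degenerate_prediction_mcc_zero(self):
        truth = np.array([0, 1, 2, 3, 4])
        pred = np.zeros(5, dtype=int)
        assert multiclass_mcc(truth, pred) == 0.0

    def test_macro_metrics_match_brute_force_oracle(self):
        """Implementation equals independent per-class counting on 200
        random 5-class instances, exactly."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(10, 60)
            truth = rng.integers(0, 5, n)
            pred = rng.integers(0, 5, n)
            rep = metrics(truth, pred)
            acc, f1, rec, spec = brute_force_macro(truth, pred)
            assert rep.accuracy == pytest.approx(acc, abs=1e-12)
            assert rep.macro_f1 == pytest.approx(f1, abs=1e-12)
            assert rep.macro_recall == pytest.approx(rec, abs=1e-12)
            assert rep.macro_specificity == pytest.approx(spec, abs=1e-12)

    def test_agreement_with_sklearn(self):
        from sklearn.metrics import (f1_score, matthews_corrcoef,
                                     recall_score, roc_auc_score)

        rng = np.random.default_rng(1)
        truth = rng.integers(0, 5, 300)
        proba = rng.dirichlet(np.ones(5), 300)
        pred = np.argmax(proba, axis=1)
        rep = metrics(truth, pred, proba)
        assert rep.macro_f1 == pytest.approx(
            f1_score(truth, pred, average="macro"), abs=1e-12)
        assert rep.macro_recall == pytest.approx(
            recall_score(truth, pred, average="macro"), abs=1e-12)
        assert rep.mcc == pytest.approx(matthews_corrcoef(truth, pred),
                                        abs=1e-12)
        assert rep.roc_auc_ovr_macro == pytest.approx(
            roc_auc_score(truth, proba, multi_class="ovr", average="macro"),
            abs=1e-12)

    def test_absent_class_excluded_with_warning(self, caplog):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([0, 1, 1, 1])
        rep = metrics(truth, pred)
        assert np.isfinite(rep.macro_f1)
        assert rep.confusion.shape == (5, 5)


class TestAggregation:
    def test_majority(self):
        spk = ["a", "a", "a"]
        pred = np.array([0, 0, 1])
        proba = np.tile([0.5, 0.3, 0.1, 0.05, 0.05], (3, 1))
        _, labels, _ = aggregate_speaker(spk, pred, proba, "majority")
        assert labels[0] == 0

    def test_tie_broken_by_mean_posterior(self):
        spk = ["a", "a"]
        pred = np.array([0, 1])
        proba = np.array([[0.60, 0.40, 0, 0, 0],
                          [0.60, 0.55, 0, 0, 0]])  # mean: 0.60 vs 0.475
        _, labels, _ = aggregate_speaker(spk, pred, proba, "majority")
        assert labels[0] == 0

    def test_mean_prob_rule(self):
        spk = ["a", "a"]
        pred = np.array([0, 1])
        proba = np.array([[0.6, 0.4, 0, 0, 0], [0.2, 0.8, 0, 0, 0]])
        _, labels, mean_p = aggregate_speaker(spk, pred, proba, "mean_prob")
        assert labels[0] == 1  # mean p = (0.4, 0.6, ...)
        np.testing.assert_allclose(mean_p[0][:2], [0.4, 0.6])

    def test_order_invariance_and_duplication(self):
        rng = np.random.default_rng(2)
        spk = np.array(["a", "b", "a", "b", "a"])
        pred = rng.integers(0, 5, 5)
        proba = rng.dirichlet(np.ones(5), 5)
        sids1, lab1, _ = aggregate_speaker(spk, pred, proba, "majority")
        perm = rng.permutation(5)
        sids2, lab2, _ = aggregate_speaker(spk[perm], pred[perm], proba[perm],
                                           "majority")
        np.testing.assert_array_equal(lab1, lab2)
        # exact duplication of every segment leaves the majority unchanged
        sids3, lab3, _ = aggregate_speaker(np.tile(spk, 2), np.tile(pred, 2),
                                           np.tile(proba, (2, 1)), "majority")
        np.testing.assert_array_equal(lab1, lab3)


class TestPermutationTest:
    def test_identical_scores_p_one(self):
        p, d = paired_permutation_test([0.5] * 6, [0.5] * 6)
        assert p == 1.0 and d == 0.0

    def test_consistent_positive_differences_significant(self):
        a = np.linspace(0.8, 0.9, 10)
        b = a - 0.05
        p, d = paired_permutation_test(a, b, n_perm=10000, seed=0)
        assert d == pytest.approx(0.05)
        assert p < 0.01  # exhaustive sign flips: 2/2^10 two-sided floor

    def test_requires_pairs(self):
        with pytest.raises(ValueError):
            paired_permutation_test([1.0], [0.5])


class TestBootstrap:
    def test_all_correct_zero_width(self):
        lo, hi = bootstrap_ci(np.ones(20) * 100.0, n_boot=200, seed=0)
        assert lo == hi == 100.0

    def test_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        x = rng.normal(80, 5, 40)
        lo, hi = bootstrap_ci(x, n_boot=500, seed=1)
        assert lo <= np.mean(x) <= hi

    def test_needs_ten_speakers(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.ones(5))

    def test_coverage_on_bernoulli_accuracy(self):
        """95% interval covers the true accuracy in 90-99% of replicates."""
        rng = np.random.default_rng(4)
        covered = 0
        reps = 200
        for i in range(reps):
            outcomes = (rng.random(60) < 0.9).astype(float) * 100
            lo, hi = bootstrap_ci(outcomes, n_boot=400, seed=i)
            covered += lo <= 90.0 <= hi
        assert 0.90 * reps <= covered <= 0.99 * reps


class TestSeedSummary:
    @pytest.mark.parametrize("values,expect", [
        ((93.8, 95.0, 95.1), (94.6, 0.7)),
        ((98.6, 99.1, 99.0), (98.9, 0.3)),
        ((95.6, 96.0, 96.1), (95.9, 0.3)),
        ((92.1, 93.0, 93.3), (92.8, 0.6)),
        ((7.0, 7.0, 7.0), (7.0, 0.0)),
    ])
    def test_mean_and_sample_sd(self, values, expect):
        assert seed_summary(values) == expect

    def test_single_value_sd_missing(self):
        mean, sd = seed_summary([42.0])
        assert mean == 42.0 and math.isnan(sd)


class TestChannelAttribution:
    def test_ignored_channel_scores_zero(self):
        from dysarthria_ssm.nn import CNNMambaClassifier, ModelConfig

        model = CNNMambaClassifier(ModelConfig.small(), seed=0)
        # zero out all first-layer weights reading channel 5
        model.blocks[0].conv.weight.data[:, 5] = 0.0
        model.eval()
        rng = np.random.default_rng(5)
        X = rng.standard_normal((8, 14, 32, 32))
        y = rng.integers(0, 5, 8)
        names = [f"ch{i}" for i in range(14)]
        imp = channel_attribution(model, X, y, X, names)
        assert imp["ch5"] == pytest.approx(0.0, abs=1e-12)
        assert len(imp) == 14
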