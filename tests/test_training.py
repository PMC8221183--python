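"""LOSO protocol, metrics, early stopping and paired model comparison."""

import numpy as np
import pytest

from sognn.model import SOGNNConfig
from sognn.training import (
    TrainConfig,
    evaluate,
    loso_split,
    run_loso,
    signed_rank_compare,
    train_sognn,
)


class StubModel:
    """Fixed-probability predictor for metric arithmetic tests."""

    def __init__(self, proba, n_classes=3):
        self.proba = np.asarray(proba, dtype=float)
        self.config = SOGNNConfig.tiny_preset(n_classes=n_classes)

    def predict_proba(self, X, batch_size=64):
        return self.proba


def feature_stub(label, subject_id, seed=0):
    from sognn.features import BandFeatureTensor

    rng = np.random.default_rng(seed)
    return BandFeatureTensor(
        values=rng.normal(size=(16, 5, 40)), subject_id=subject_id,
        trial_id=f"{subject_id}_{seed}", label=label,
    )


class TestLosoSplit:
    def test_fifteen_subjects_give_fifteen_folds(self):
        ids = np.repeat([f"S{i:02d}" for i in range(15)], 45)
        assert len(loso_split(ids)) == 15

    def test_two_subjects_complementary(self):
        folds = loso_split(["a", "a", "b"])
        assert len(folds) == 2
        (tr0, va0), (tr1, va1) = folds
        assert sorted(va0.tolist() + va1.tolist()) == [0, 1, 2]
        assert sorted(tr0) == sorted(va1)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_validation_sets_partition_dataset(self, seed):
        rng = np.random.default_rng(seed)
        ids = rng.choice([f"S{i}" for i in range(6)], size=40)
        folds = loso_split(ids)
        union = np.concatenate([va for _, va in folds])
        assert sorted(union.tolist()) == list(range(40))
        for _, va in folds:
            assert len(set(ids[va])) == 1  # exactly one subject per fold

    def test_no_leakage_between_train_and_validation(self):
        ids = np.repeat(["a", "b", "c"], 5)
        for train, val in loso_split(ids):
            assert set(ids[train]).isdisjoint(set(ids[val]))

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match=">= 2 subjects"):
            loso_split(["only", "only"])


class TestEvaluate:
    def test_perfect_predictor_on_balanced_classes(self):
        y = np.repeat([0, 1, 2], 4)
        proba = np.eye(3)[y]
        samples = [feature_stub(int(lbl), "S01", seed=i) for i, lbl in enumerate(y)]
        res = evaluate(StubModel(proba), samples)
        assert res.accuracy == 1.0
        assert res.macro_F1 == 1.0
        assert res.macro_AUC == 1.0
        assert np.array_equal(res.confusion, np.diag([4, 4, 4]))

    def test_hand_built_confusion_matrix_metrics(self):
        # target confusion: [[8,1,1],[2,7,1],[0,2,8]] -> accuracy 23/30
        confusion = np.array([[8, 1, 1], [2, 7, 1], [0, 2, 8]])
        y_true, y_pred = [], []
        for t in range(3):
            for p in range(3):
                y_true += [t] * confusion[t, p]
                y_pred += [p] * confusion[t, p]
        proba = np.eye(3)[y_pred] * 0.9 + 0.05
        samples = [
            feature_stub(int(lbl), "S01", seed=i) for i, lbl in enumerate(y_true)
        ]
        res = evaluate(StubModel(proba), samples)
        assert res.accuracy == pytest.approx(23 / 30)
        assert np.array_equal(res.confusion, confusion)
        # closed-form per-class F1 from precision/recall
        for c in range(3):
            tp = confusion[c, c]
            precision = tp / confusion[:, c].sum()
            recall = tp / confusion[c, :].sum()
            expected = 2 * precision * recall / (precision + recall)
            assert res.per_class_F1[c] == pytest.approx(expected)

    def test_constant_predictor_accuracy_equals_prevalence(self):
        y = [0] * 6 + [1] * 3 + [2] * 1
        proba = np.tile([0.8, 0.1, 0.1], (10, 1))
        samples = [feature_stub(lbl, "S01", seed=i) for i, lbl in enumerate(y)]
        res = evaluate(StubModel(proba), samples)
        assert res.accuracy == pytest.approx(0.6)

    def test_metrics_invariant_to_sample_order(self, rng):
        y = rng.integers(0, 3, 12)
        proba = rng.dirichlet(np.ones(3), size=12)
        samples = [feature_stub(int(lbl), "S01", seed=i) for i, lbl in enumerate(y)]
        perm = rng.permutation(12)
        res_a = evaluate(StubModel(proba), samples)
        res_b = evaluate(StubModel(proba[perm]), [samples[i] for i in perm])
        assert res_a.accuracy == res_b.accuracy
        assert res_a.macro_F1 == res_b.macro_F1
        assert res_a.macro_AUC == pytest.approx(res_b.macro_AUC)

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            evaluate(StubModel(np.ones((1, 3)) / 3), [])


class TestTrainSognn:
    def test_defaults_follow_protocol(self):
        tc = TrainConfig()
        assert tc.learning_rate == pytest.approx(1e-5)
        assert tc.weight_decay == pytest.approx(1e-4)
        assert tc.batch_size == 16
        assert tc.auc_stop_threshold == pytest.approx(0.99)

    def test_same_seed_gives_identical_first_epoch_loss(self, tiny_dataset):
        _, padded = tiny_dataset
        subset = padded[:20]
        cfg = SOGNNConfig.tiny_preset()
        tc = TrainConfig(learning_rate=1e-3, max_epochs=1, seed=7)
        _, log_a = train_sognn(subset, cfg, tc)
        _, log_b = train_sognn(subset, cfg, tc)
        assert log_a[0]["loss"] == log_b[0]["loss"]
        assert log_a[0]["train_auc"] == log_b[0]["train_auc"]

    def test_separable_data_stops_early_with_high_auc(self, tiny_dataset, study_train_config):
        _, padded = tiny_dataset
        subset = [s for s in padded if s.subject_id != "S01"]
        model, log = train_sognn(subset, SOGNNConfig.tiny_preset(), study_train_config)
        assert len(log) < study_train_config.max_epochs
        assert log[-1]["train_auc"] >= study_train_config.auc_stop_threshold

    def test_too_few_samples_rejected(self, tiny_dataset):
        _, padded = tiny_dataset
        with pytest.raises(ValueError, match="batch size"):
            train_sognn(padded[:4], SOGNNConfig.tiny_preset(), TrainConfig())

    def test_single_class_rejected(self, tiny_dataset):
        _, padded = tiny_dataset
        one_class = [s for s in padded if s.label == 0][:16]
        with pytest.raises(ValueError, match="fewer than 2 classes"):
            train_sognn(one_class, SOGNNConfig.tiny_preset(), TrainConfig())

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError, match="auc_stop_threshold"):
            TrainConfig(auc_stop_threshold=0.3)


class TestRunLoso:
    def test_report_aggregates_fold_accuracies(self, tiny_loso):
        report, _ = tiny_loso
        assert len(report.folds) == 6
        accs = [f.accuracy for f in report.folds]
        assert report.mean_accuracy == pytest.approx(np.mean(accs))
        assert report.std_accuracy == pytest.approx(np.std(accs))
        held_out = [f.held_out_subject for f in report.folds]
        assert sorted(held_out) == [f"S{i:02d}" for i in range(1, 7)]

    def test_fold_metrics_bounded(self, tiny_loso):
        report, _ = tiny_loso
        for f in report.folds:
            assert 0 <= f.accuracy <= 1
            assert 0 <= f.macro_F1 <= 1
            assert 0 <= f.macro_AUC <= 1
            assert f.confusion.sum() == 12  # 12 trials per held-out subject


class TestSignedRank:
    def test_identical_vectors_no_difference(self):
        res = signed_rank_compare([0.5] * 6, [0.5] * 6)
        assert res["verdict"] == "no difference"
        assert res["p_value"] == 1.0

    def test_six_positive_differences_exact_p(self):
        a = [0.9, 0.8, 0.85, 0.7, 0.95, 0.75]
        b = [0.6, 0.5, 0.65, 0.4, 0.55, 0.45]
        res = signed_rank_compare(a, b)
        # exhaustive enumeration over 2^6 sign assignments gives 2/64
        assert res["p_value"] == pytest.approx(2 / 64)
        assert res["W_plus"] == pytest.approx(21.0)
        assert res["statistic"] == pytest.approx(21.0)

    def test_swap_flips_statistic_sign_keeps_p(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0.4, 0.9, 8)
        b = rng.uniform(0.4, 0.9, 8)
        res_ab = signed_rank_compare(a, b)
        res_ba = signed_rank_compare(b, a)
        assert res_ab["statistic"] == pytest.approx(-res_ba["statistic"])
        assert res_ab["p_value"] == pytest.approx(res_ba["p_value"])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 5 pairs"):
            signed_rank_compare([1, 2, 3], [3, 2, 1])


class TestShuffledControl:
    def test_label_shuffle_drops_to_chance(self, tiny_dataset, study_train_config):
        from dataclasses import replace

        ds, padded = tiny_dataset
        rng = np.random.default_rng(99)
        labels = np.array([s.label for s in padded])
        perm = rng.permutation(len(labels))
        shuffled = [replace(s, label=int(labels[perm[i]])) for i, s in enumerate(padded)]
        report = run_loso(shuffled, SOGNNConfig.tiny_preset(), study_train_config)
        n_total = sum(f.confusion.sum() for f in report.folds)
        # 3-sigma binomial band around chance for the pooled prediction count
        sigma = np.sqrt((1 / 3) * (2 / 3) / n_total)
        assert abs(report.mean_accuracy - 1 / 3) < 3 * sigma + 0.02
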