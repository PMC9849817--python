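import numpy as np
import pytest

from orchard_vqa.corpus import VQARecord
from orchard_vqa.engine import (
    FeatureSet, TrainConfig, binary_confusion, confusion_indicators,
    confusion_stats, evaluate, kfold_cross_validate, partition_folds, predict,
    select_answer, train,
)
from orchard_vqa.errors import InvalidInputError
from orchard_vqa.model import ModelConfig, VQAModel


# Published per-run cross-validation rows (percent): sensitivity,
# specificity, precision, accuracy, F1 — the aggregation-mode input fixture.
PER_RUN_ROWS = [
    dict(sensitivity=91.25, specificity=93.11, precision=92.98, accuracy=92.12, f1=92.23),
    dict(sensitivity=94.29, specificity=92.39, precision=93.38, accuracy=93.34, f1=93.34),
    dict(sensitivity=92.04, specificity=93.73, precision=92.53, accuracy=93.09, f1=92.42),
    dict(sensitivity=93.10, specificity=91.38, precision=91.24, accuracy=92.24, f1=92.23),
    dict(sensitivity=94.93, specificity=94.19, precision=94.09, accuracy=94.56, f1=94.55),
    dict(sensitivity=93.69, specificity=92.09, precision=92.21, accuracy=92.89, f1=92.88),
    dict(sensitivity=94.12, specificity=92.34, precision=92.47, accuracy=93.23, f1=93.22),
    dict(sensitivity=94.55, specificity=96.35, precision=96.28, accuracy=95.45, f1=95.44),
    dict(sensitivity=91.75, specificity=92.75, precision=92.66, accuracy=92.15, f1=92.15),
    dict(sensitivity=95.08, specificity=94.38, precision=95.06, accuracy=94.73, f1=95.24),
]


class _StubModel:
    """Fixed-logit model for evaluation-path tests."""

    def __init__(self, logits):
        self.logits = np.asarray(logits, dtype=float)

    def eval(self):
        return self

    def __call__(self, grids, q_seqs, q_mask):
        class _Out:
            pass
        out = _Out()
        out.data = self.logits
        return out


def _tiny_featureset(labels, types, vocab, candidates=None):
    n = len(labels)
    records = [VQARecord(image_id=f"i{j}", image_path="x.png",
                         question_id=f"q{j}", question="q",
                         question_type=types[j],
                         answers=[vocab[labels[j]]] * 3,
                         candidates=None if candidates is None else candidates[j])
               for j in range(n)]
    g = np.random.default_rng(0)
    return FeatureSet(records=records, grids=g.normal(size=(n, 4, 8)),
                      q_seqs=g.normal(size=(n, 26, 16)),
                      q_mask=np.ones((n, 26), dtype=bool),
                      labels=np.asarray(labels), answer_vocab=list(vocab))


class TestTrain:
    def test_zero_epochs_returns_untrained(self, yesno_features):
        cfg = ModelConfig.tiny(len(yesno_features.answer_vocab))
        model = VQAModel(cfg)
        before = model.state_dict()
        model, history = train(model, yesno_features,
                               TrainConfig(max_epochs=0))
        assert history == {"train_loss": [], "val_accuracy": [],
                           "best_epoch": None}
        for a, b in zip(before, model.state_dict()):
            np.testing.assert_array_equal(a, b)

    def test_fixed_seed_reproducible_loss_curve(self, yesno_features):
        cfg = ModelConfig.tiny(len(yesno_features.answer_vocab), seed=1)
        tcfg = TrainConfig(learning_rate=3e-3, batch_size=8, max_epochs=4,
                           seed=5)
        _, h1 = train(VQAModel(cfg), yesno_features, tcfg)
        _, h2 = train(VQAModel(cfg), yesno_features, tcfg)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_accuracy"] == h2["val_accuracy"]

    def test_divergence_raises(self, yesno_features):
        cfg = ModelConfig.tiny(len(yesno_features.answer_vocab))
        bad = yesno_features.subset(np.arange(len(yesno_features)))
        bad.grids = bad.grids.copy()
        bad.grids[0] = np.nan
        with pytest.raises(RuntimeError, match="diverged"):
            train(VQAModel(cfg), bad, TrainConfig(max_epochs=1))

    def test_empty_split_rejected(self, yesno_features):
        cfg = ModelConfig.tiny(len(yesno_features.answer_vocab))
        with pytest.raises(InvalidInputError):
            train(VQAModel(cfg), yesno_features.subset([]),
                  TrainConfig(max_epochs=1))

    def test_early_stopping_keeps_best_epoch(self, yesno_features):
        cfg = ModelConfig.tiny(len(yesno_features.answer_vocab), seed=0)
        model, history = train(
            VQAModel(cfg), yesno_features,
            TrainConfig(learning_rate=3e-3, batch_size=8, max_epochs=12,
                        seed=0))
        best = history["best_epoch"]
        assert history["val_accuracy"][best] == max(history["val_accuracy"])
        # restored checkpoint reproduces the best accuracy
        preds = predict(model, yesno_features)
        acc = float(np.mean(preds == yesno_features.labels))
        np.testing.assert_allclose(acc, max(history["val_accuracy"]), atol=1e-12)


class TestPredict:
    def test_unique_max(self):
        assert select_answer(np.array([0.1, 5.0, 0.3]), ["a", "b", "c"]) == 1

    def test_tie_breaks_to_lowest_index(self):
        assert select_answer(np.array([2.0, 2.0, 1.0]), ["a", "b", "c"]) == 0

    def test_multiple_choice_restricts_to_candidates(self):
        logits = np.array([9.0, 1.0, 3.0, 2.0])
        vocab = ["a", "b", "c", "d"]
        # global argmax 'a' is not among the candidates
        assert select_answer(logits, vocab, candidates=["b", "c"]) == 2

    def test_multiple_choice_flag_in_predict(self):
        vocab = ["a", "b", "c"]
        feats = _tiny_featureset([0], ["yesno"], vocab,
                                 candidates=[["b", "c"]])
        stub = _StubModel(np.array([[10.0, 2.0, 1.0]]))
        assert predict(stub, feats, multiple_choice=True)[0] == 1
        assert predict(stub, feats)[0] == 0


class TestEvaluate:
    def test_all_correct(self):
        vocab = ["a", "b"]
        feats = _tiny_featureset([0, 1, 0], ["yesno", "number", "other"], vocab)
        stub = _StubModel(np.array([[9, 0], [0, 9], [9, 0]], dtype=float))
        report = evaluate(stub, feats)
        assert report.accuracy_overall == 1.0
        assert report.accuracy_per_type["yesno"] == 1.0

    def test_half_correct(self):
        vocab = ["a", "b"]
        feats = _tiny_featureset([0, 0, 1, 1],
                                 ["yesno", "yesno", "number", "number"], vocab)
        stub = _StubModel(np.array([[9, 0], [0, 9], [0, 9], [9, 0]], float))
        report = evaluate(stub, feats)
        assert report.accuracy_overall == 0.5

    def test_per_type_recombines_to_overall(self, rng):
        vocab = ["a", "b", "c"]
        types = list(np.random.default_rng(1).choice(
            ["yesno", "number", "whatwhere", "other"], size=40))
        labels = list(np.random.default_rng(2).integers(0, 3, size=40))
        feats = _tiny_featureset(labels, types, vocab)
        logits = np.random.default_rng(3).normal(size=(40, 3))
        report = evaluate(_StubModel(logits), feats)
        total = sum(report.accuracy_per_type[t] * report.n_per_type[t]
                    for t in report.n_per_type if report.n_per_type[t])
        np.testing.assert_allclose(report.accuracy_overall,
                                   total / len(feats), atol=1e-12)

    def test_unlabeled_split_rejected(self):
        vocab = ["a"]
        feats = _tiny_featureset([0], ["yesno"], vocab)
        feats.labels = np.array([-1])
        with pytest.raises(InvalidInputError, match="predict"):
            evaluate(_StubModel(np.zeros((1, 1))), feats)

    def test_empty_split_rejected(self):
        vocab = ["a"]
        feats = _tiny_featureset([0], ["yesno"], vocab).subset([])
        with pytest.raises(InvalidInputError):
            evaluate(_StubModel(np.zeros((0, 1))), feats)


class TestKFold:
    def test_each_fold_single_record(self):
        folds = partition_folds(10, 10, seed=0)
        assert all(len(f) == 1 for f in folds)
        assert sorted(np.concatenate(folds)) == list(range(10))

    def test_uneven_fold_sizes(self):
        folds = partition_folds(103, 10, seed=1)
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {10, 11}
        flat = np.concatenate(folds)
        assert len(np.unique(flat)) == 103     # disjoint and covering

    def test_seed_controls_partition(self):
        a = partition_folds(20, 4, seed=3)
        b = partition_folds(20, 4, seed=3)
        c = partition_folds(20, 4, seed=4)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(InvalidInputError):
            partition_folds(5, 10, seed=0)
        with pytest.raises(InvalidInputError):
            partition_folds(5, 1, seed=0)

    def test_cross_validate_smoke(self, yesno_features):
        cfg = ModelConfig.tiny(len(yesno_features.answer_vocab))
        reports = kfold_cross_validate(
            yesno_features, cfg,
            TrainConfig(max_epochs=1, batch_size=16, learning_rate=1e-3),
            k=2, runs=2, seed=0)
        assert len(reports) == 2
        assert all(len(run) == 2 for run in reports)
        for run in reports:
            for rep in run:
                assert 0.0 <= rep.accuracy_overall <= 1.0


class TestConfusionStats:
    def test_published_sensitivity_mean(self):
        stats = confusion_stats(PER_RUN_ROWS)
        assert round(stats.mean["sensitivity"], 2) == 93.48

    def test_published_accuracy_mean(self):
        stats = confusion_stats(PER_RUN_ROWS)
        assert round(stats.mean["accuracy"], 2) == 93.38

    def test_sample_sd_closed_form(self):
        stats = confusion_stats(PER_RUN_ROWS)
        vals = [r["sensitivity"] for r in PER_RUN_ROWS]
        np.testing.assert_allclose(stats.mean["sensitivity"], np.mean(vals))
        np.testing.assert_allclose(stats.sd["sensitivity"],
                                   np.std(vals, ddof=1))

    def test_undefined_specificity_excluded_with_warning(self):
        # TP=FN=5, TN=FP=0: sensitivity 0.5, specificity undefined
        y_true = np.ones(10, dtype=bool)
        y_pred = np.array([True] * 5 + [False] * 5)
        row = confusion_indicators(*binary_confusion(y_true, y_pred))
        assert row["sensitivity"] == 0.5
        assert row["specificity"] is None
        with pytest.warns(UserWarning, match="specificity"):
            stats = confusion_stats([(y_true, y_pred)])
        assert np.isnan(stats.mean["specificity"])

    def test_binary_confusion_counts(self):
        y_true = np.array([1, 1, 0, 0, 1])
        y_pred = np.array([1, 0, 1, 0, 1])
        assert binary_confusion(y_true, y_pred) == (2, 1, 1, 1)

    def test_f1_formula(self):
        row = confusion_indicators(8, 2, 7, 3)
        p, s = 8 / 10, 8 / 11
        np.testing.assert_allclose(row["f1"], 2 * p * s / (p + s))

    def test_mixed_input_modes(self):
        y = np.array([1, 0, 1, 0])
        stats = confusion_stats([(y, y), dict(sensitivity=0.9, specificity=0.8,
                                              precision=0.85, accuracy=0.88,
                                              f1=0.87)])
        assert len(stats.rows) == 2
        np.testing.assert_allclose(stats.mean["sensitivity"], (1.0 + 0.9) / 2)
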