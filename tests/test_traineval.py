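"""Training loop contracts and the accuracy/precision/recall/F1 arithmetic."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score

from seedqc import arch, synthgen, traineval
from seedqc.traineval import (
    ConfusionCounts,
    TrainConfig,
    confusion,
    evaluate,
    metrics,
    train,
)


class TestConfusion:
    def test_all_correct_defective(self):
        c = confusion(["defective"] * 5, ["defective"] * 5)
        assert (c.TP, c.TN, c.FP, c.FN) == (5, 0, 0, 0)

    def test_all_false_positive(self):
        c = confusion(["good"] * 4, ["defective"] * 4)
        assert (c.TP, c.TN, c.FP, c.FN) == (0, 0, 4, 0)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(["good", "defective"], size=1000)
        preds = rng.choice(["good", "defective"], size=1000)
        c = confusion(labels, preds)
        tally = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}
        for t, p in zip(labels, preds):
            key = ("T" if t == p else "F") + ("P" if p == "defective" else "N")
            tally[key] += 1
        assert (c.TP, c.TN, c.FP, c.FN) == tuple(tally[k] for k in ("TP", "TN", "FP", "FN"))
        assert c.total == 1000

    def test_length_mismatch_and_unknown_label(self):
        with pytest.raises(ValueError):
            confusion(["good"], [])
        with pytest.raises(ValueError):
            confusion(["good"], ["cracked"])


class TestMetrics:
    def test_worked_example(self):
        rep = metrics(ConfusionCounts(TP=50, TN=40, FP=10, FN=0))
        assert rep.accuracy == pytest.approx(90.0, abs=0.005)
        assert rep.precision == pytest.approx(83.33, abs=0.005)
        assert rep.recall == pytest.approx(100.0, abs=0.005)
        assert rep.f1 == pytest.approx(90.91, abs=0.005)

    def test_perfect_classifier(self):
        rep = metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (100.0,) * 4

    def test_matches_sklearn_on_random_tuples(self):
        """Independent oracle: reconstruct label vectors, score with sklearn."""
        rng = np.random.default_rng(1)
        for _ in range(300):
            tp, tn, fp, fn = rng.integers(0, 40, size=4)
            if tp + tn + fp + fn == 0:
                continue
            y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
            y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
            rep = metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
            assert rep.accuracy == pytest.approx(100 * accuracy_score(y_true, y_pred), abs=1e-9)
            assert rep.precision == pytest.approx(
                100 * precision_score(y_true, y_pred, zero_division=0), abs=1e-9
            )
            assert rep.recall == pytest.approx(
                100 * recall_score(y_true, y_pred, zero_division=0), abs=1e-9
            )
            assert rep.f1 == pytest.approx(
                100 * f1_score(y_true, y_pred, zero_division=0), abs=1e-9
            )

    def test_zero_denominators_return_zero(self, caplog):
        rep = metrics(ConfusionCounts(TP=0, TN=10, FP=0, FN=0))
        assert rep.precision == 0.0 and rep.recall == 0.0 and rep.f1 == 0.0
        assert rep.accuracy == 100.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(TP=0, TN=0, FP=0, FN=0))

    def test_accuracy_invariant_under_class_relabelling(self):
        c = ConfusionCounts(TP=30, TN=50, FP=12, FN=8)
        swapped = ConfusionCounts(TP=c.TN, TN=c.TP, FP=c.FN, FN=c.FP)
        assert metrics(c).accuracy == metrics(swapped).accuracy


class TestTrainContracts:
    def test_zero_learning_rate_freezes_loss(self, crop_data, tiny_model_config):
        """With lr = 0 and one full-dataset batch per epoch the loss repeats."""
        X, y = crop_data
        X, y = X[:40], y[:40]
        assert len(np.unique(y)) == 2
        model = arch.build_model(tiny_model_config)
        config = TrainConfig(batch_size=len(y), learning_rate=0.0, epochs=3, rng_seed=0)
        history = train(model, None, config, train_arrays=(X, y))
        # per-epoch shuffling reorders the summation, so equality holds only
        # to floating-point accumulation error
        assert np.allclose(history["loss"], history["loss"].iloc[0], rtol=1e-5)

    def test_determinism_across_runs(self, crop_data, tiny_model_config):
        X, y = crop_data
        runs = []
        for _ in range(2):
            model = arch.build_model(tiny_model_config)
            config = TrainConfig(batch_size=16, epochs=2, rng_seed=5)
            h = train(model, None, config, train_arrays=(X[:64], y[:64]))
            runs.append(h)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_history_shape_and_finite_loss(self, crop_data, tiny_model_config):
        X, y = crop_data
        model = arch.build_model(tiny_model_config)
        config = TrainConfig(batch_size=16, epochs=3, rng_seed=1)
        h = train(model, None, config, train_arrays=(X[:64], y[:64]))
        assert list(h.columns) == ["epoch", "loss", "test_accuracy"]
        assert len(h) == 3
        assert np.isfinite(h["loss"]).all()

    def test_single_class_rejected(self, crop_data, tiny_model_config):
        X, y = crop_data
        mask = y == "good"
        model = arch.build_model(tiny_model_config)
        with pytest.raises(ValueError):
            train(
                model,
                None,
                TrainConfig(batch_size=8, epochs=1),
                train_arrays=(X[mask][:16], y[mask][:16]),
            )

    def test_oversized_batch_rejected(self, crop_data, tiny_model_config):
        X, y = crop_data
        model = arch.build_model(tiny_model_config)
        with pytest.raises(ValueError):
            train(
                model,
                None,
                TrainConfig(batch_size=512, epochs=1),
                train_arrays=(X[:32], y[:32]),
            )

    def test_sgd_optimizer_supported(self, crop_data, tiny_model_config):
        X, y = crop_data
        model = arch.build_model(tiny_model_config)
        config = TrainConfig(batch_size=16, epochs=1, optimizer="sgd", rng_seed=0)
        h = train(model, None, config, train_arrays=(X[:48], y[:48]))
        assert len(h) == 1


class TestEvaluate:
    def test_memorisation_capacity(self, tiny_model_config):
        """A tiny balanced set is memorised to 100% train accuracy."""
        X, y = synthgen.make_crop_dataset(8, crop_size=64, rng_seed=21)
        model = arch.build_model(tiny_model_config)
        config = TrainConfig(batch_size=8, epochs=40, rng_seed=2, stop_accuracy=None)
        train(model, None, config, train_arrays=(X, y))
        rep, counts, _ = evaluate(model, test_arrays=(X, y))
        assert rep.accuracy == 100.0

    def test_order_invariance(self, trained_model, crop_data):
        X, y = crop_data
        X, y = X[-40:], y[-40:]
        rep1, _, _ = evaluate(trained_model, test_arrays=(X, y))
        perm = np.random.default_rng(0).permutation(len(y))
        rep2, _, _ = evaluate(trained_model, test_arrays=(X[perm], y[perm]))
        assert rep1 == rep2

    def test_consistency_with_confusion_pipeline(self, trained_model, crop_data):
        """evaluate() == metrics(confusion(labels, argmax predictions))."""
        X, y = crop_data
        X, y = X[-60:], y[-60:]
        rep, counts, table = evaluate(trained_model, test_arrays=(X, y))
        recomputed = metrics(confusion(list(table["true"]), list(table["predicted"])))
        assert rep == recomputed
        assert counts.total == len(y)
        assert (table["confidence"] >= 0.5).all()  # two-class argmax bound
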