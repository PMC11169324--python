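"""Training contract, early stopping, and bootstrap evaluation."""

import numpy as np
import pytest

from camval import ModelSpec, TrainConfig, evaluate, train
from camval.classifier import EarlyStopper, build_model
from camval.errors import ConfigurationError, DataError


def _separable_data(n=24, size=16, seed=0):
    # positives carry a bright square; trivially learnable
    rng = np.random.default_rng(seed)
    x = rng.random((n, 1, size, size)) * 0.2
    y = np.arange(n) % 2
    for i in np.flatnonzero(y):
        x[i, 0, 4:10, 4:10] += 0.7
    return np.clip(x, 0, 1), y


class TestEarlyStopping:
    def test_strictly_increasing_loss_stops_after_patience(self):
        s = EarlyStopper(patience=1)
        assert not s.update(1.0)  # epoch 1: first value is the best
        assert s.update(1.1)  # epoch 2: no improvement -> stop
        assert s.best_epoch == 1
        assert s.epoch == 2

    def test_recovery_resets_counter(self):
        s = EarlyStopper(patience=2)
        for loss, stop in [(1.0, False), (1.1, False), (0.9, False),
                           (0.95, False), (0.91, True)]:
            assert s.update(loss) == stop
        assert s.best_epoch == 3

    def test_train_restores_best_epoch_weights(self):
        x, y = _separable_data()
        spec = ModelSpec(input_size=(16, 16), seed=0)
        cfg = TrainConfig(seed=0, max_epochs=6, patience=2, val_fraction=0.25,
                          batch_size=8)
        res = train(spec, cfg, x=x, y=y)
        best = res.log.loc[res.log["epoch"] == res.best_epoch, "val_loss"].item()
        assert best == res.log["val_loss"].min()


class TestTrain:
    def test_deterministic_training_curves(self):
        x, y = _separable_data()
        spec = ModelSpec(input_size=(16, 16), seed=1)
        cfg = TrainConfig(seed=1, max_epochs=3, patience=3, val_fraction=0.25,
                          batch_size=8)
        a = train(spec, cfg, x=x, y=y)
        b = train(spec, cfg, x=x, y=y)
        assert a.log.equals(b.log)
        for wa, wb in zip(a.model.get_weights(), b.model.get_weights()):
            assert np.array_equal(wa, wb)

    def test_loss_decreases_on_learnable_task(self):
        x, y = _separable_data(n=40, seed=3)
        spec = ModelSpec(input_size=(16, 16), seed=3)
        cfg = TrainConfig(seed=3, learning_rate=1e-2, max_epochs=15,
                          patience=15, val_fraction=0.2, batch_size=8)
        res = train(spec, cfg, x=x, y=y)
        assert res.log["train_loss"].iloc[-1] < res.log["train_loss"].iloc[0]

    def test_single_class_rejected(self):
        x, _ = _separable_data()
        with pytest.raises(DataError):
            train(ModelSpec(input_size=(16, 16)), TrainConfig(),
                  x=x, y=np.zeros(len(x), dtype=int))

    def test_softmax_outputs_sum_to_one(self):
        model = build_model(ModelSpec(input_size=(16, 16), seed=2))
        x = np.random.default_rng(0).random((5, 1, 16, 16))
        p = model.predict_proba(x)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(backbone="resnet200")
        with pytest.raises(ConfigurationError):
            ModelSpec(input_size=(17, 16))


class _FixedScoreModel:
    """Stub returning preset positive-class scores (for metric tests)."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, dtype=float)

    def predict_proba(self, x, batch_size=64):
        s = self.scores[: len(x)]
        return np.column_stack([1 - s, s])


class TestEvaluate:
    def test_perfect_separation_gives_auc_one(self):
        scores = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        y = np.array([0, 0, 0, 1, 1, 1])
        m = evaluate(_FixedScoreModel(scores), x=np.zeros((6, 1, 2, 2)), y=y,
                     n_boot=200, seed=0)
        assert m.auc.point == pytest.approx(1.0)
        assert m.accuracy.point == pytest.approx(1.0)

    def test_constant_scores_give_auc_half(self):
        y = np.array([0, 1] * 5)
        m = evaluate(_FixedScoreModel([0.5] * 10), x=np.zeros((10, 1, 2, 2)),
                     y=y, n_boot=200, seed=0)
        # ties broken by rank averaging
        assert 0.45 <= m.auc.point <= 0.55

    def test_auc_matches_brute_force_pair_counting(self):
        # 5x5 score pairs with exactly 3 discordant -> AUC = 22/25 = 0.88
        neg = [0.10, 0.20, 0.30, 0.55, 0.65]
        pos = [0.50, 0.60, 0.70, 0.80, 0.90]
        y = np.array([0] * 5 + [1] * 5)
        scores = np.array(neg + pos)
        concordant = sum(
            1.0 if p > n_ else (0.5 if p == n_ else 0.0)
            for p in pos for n_ in neg
        )
        assert concordant / 25 == pytest.approx(0.88)
        from sklearn.metrics import roc_auc_score  # path used by evaluate

        m = evaluate(_FixedScoreModel(scores), x=np.zeros((10, 1, 2, 2)), y=y,
                     n_boot=200, seed=0)
        assert roc_auc_score(y, scores) == pytest.approx(0.88)
        # bootstrap mean stays near the full-sample value
        assert abs(m.auc.point - 0.88) < 0.1

    def test_ci_brackets_point_and_shrinks_with_n(self):
        rng = np.random.default_rng(5)

        def metrics_for(n):
            y = np.array([0, 1] * (n // 2))
            scores = np.clip(0.5 + (y - 0.5) * 0.4 + rng.normal(0, 0.2, n), 0, 1)
            return evaluate(_FixedScoreModel(scores), x=np.zeros((n, 1, 2, 2)),
                            y=y, n_boot=400, seed=1)

        small, big = metrics_for(20), metrics_for(200)
        for m in (small, big):
            for name in ("auc", "accuracy", "sensitivity", "specificity"):
                ci = getattr(m, name)
                assert ci.low <= ci.point <= ci.high
        assert (big.auc.high - big.auc.low) < (small.auc.high - small.auc.low)

    def test_single_class_test_set_rejected(self):
        with pytest.raises(DataError):
            evaluate(_FixedScoreModel([0.5] * 4), x=np.zeros((4, 1, 2, 2)),
                     y=np.ones(4, dtype=int))

    def test_counts_report_correct_and_total(self):
        scores = [0.1, 0.9, 0.2, 0.8]
        y = np.array([0, 1, 1, 0])
        m = evaluate(_FixedScoreModel(scores), x=np.zeros((4, 1, 2, 2)), y=y,
                     n_boot=150, seed=0)
        assert m.counts["accuracy"] == (2, 4)
        assert m.counts["sensitivity"] == (1, 2)
        assert m.counts["specificity"] == (1, 2)
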