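import numpy as np
import pytest

from pfnet.estimators import PFNetClassifier
from pfnet.nn.layers import Dropout
from pfnet.training import (
    TrainConfig,
    finetune_subject,
    lr_at_epoch,
    pretrain,
    write_training_log,
)


def toy_windows(n_per_class=20, N=8, C=4, classes=(1, 2), seed=0, scale=3.0):
    """Separable toy windows: each class has its own channel amplitudes."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for ci, cls in enumerate(classes):
        amp = np.ones(C)
        amp[ci % C] = scale
        X.append(rng.standard_normal((n_per_class, N, C)) * amp)
        y.extend([cls] * n_per_class)
    return np.concatenate(X), np.array(y)


TINY = dict(maps=2, fc_feature=8, fc_knowledge=8, fc_fusion=6)


class TestSchedule:
    @pytest.mark.parametrize(
        "epoch, lr",
        [(1, 0.1), (15, 0.1), (16, 0.01), (23, 0.01), (24, 0.001), (28, 0.001)],
    )
    def test_reference_schedule(self, epoch, lr):
        cfg = TrainConfig()
        assert lr_at_epoch(cfg, epoch) == pytest.approx(lr)

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            lr_at_epoch(TrainConfig(), 0)
        with pytest.raises(ValueError):
            lr_at_epoch(TrainConfig(), 29)

    def test_classifier_uses_same_schedule(self):
        cfg = TrainConfig()
        clf = PFNetClassifier(lr=cfg.lr_initial, lr_drop_epochs=cfg.lr_drop_epochs,
                              lr_drop_factor=cfg.lr_drop_factor)
        for epoch in (1, 15, 16, 23, 24, 28):
            assert clf._lr_at(epoch) == pytest.approx(lr_at_epoch(cfg, epoch))


class TestPretrain:
    def test_loss_decreases_on_toy_data(self):
        X, y = toy_windows()
        cfg = TrainConfig(batch_size=8, epochs=3, lr_initial=0.01,
                          lr_drop_epochs=(), dropout_pretrain=0.0, seed=0)
        state = pretrain(PFNetClassifier(**TINY), X, y, cfg)
        assert state.phase == "pretrained"
        assert len(state.history) == 3
        assert state.history[-1]["loss"] < state.history[0]["loss"]

    def test_empty_training_set_rejected(self):
        cfg = TrainConfig(epochs=1)
        with pytest.raises(ValueError, match="nonempty"):
            pretrain(PFNetClassifier(**TINY), np.zeros((0, 8, 4)), [], cfg)

    def test_seeded_runs_are_bit_identical(self):
        X, y = toy_windows()
        cfg = TrainConfig(batch_size=8, epochs=3, lr_initial=0.01,
                          lr_drop_epochs=(), seed=42)
        s1 = pretrain(PFNetClassifier(**TINY), X, y, cfg)
        s2 = pretrain(PFNetClassifier(**TINY), X, y, cfg)
        assert s1.history == s2.history
        for p, q in zip(s1.classifier.network_.params, s2.classifier.network_.params):
            np.testing.assert_array_equal(p, q)

    def test_overfit_sanity_on_separable_windows(self):
        """With dropout off, a small run must essentially memorize 40
        cleanly separable windows."""
        X, y = toy_windows(n_per_class=20, scale=5.0)
        cfg = TrainConfig(batch_size=40, epochs=40, lr_initial=0.05,
                          lr_drop_epochs=(), dropout_pretrain=0.0, seed=1)
        state = pretrain(PFNetClassifier(**TINY), X, y, cfg)
        assert state.history[-1]["train_acc"] >= 0.95

    def test_dropout_rate_applied_from_config(self):
        X, y = toy_windows(n_per_class=5)
        cfg = TrainConfig(batch_size=10, epochs=1, dropout_pretrain=0.5, seed=0)
        state = pretrain(PFNetClassifier(**TINY), X, y, cfg)
        rates = {
            l.rate
            for mod in state.classifier.network_._modules.values()
            for l in mod.layers
            if isinstance(l, Dropout)
        }
        assert rates == {0.5}


class TestFinetune:
    def _pretrained(self):
        X, y = toy_windows(n_per_class=10)
        cfg = TrainConfig(batch_size=10, epochs=2, lr_initial=0.01,
                          lr_drop_epochs=(), finetune_epochs=2,
                          dropout_pretrain=0.5, dropout_train=0.65, seed=0)
        return pretrain(PFNetClassifier(**TINY), X, y, cfg), cfg

    def test_zero_epochs_returns_pretrained_parameters(self):
        state, cfg = self._pretrained()
        cfg0 = TrainConfig(**{**cfg.to_dict(), "finetune_epochs": 0})
        X, y = toy_windows(n_per_class=4, seed=3)
        tuned = finetune_subject(state, X, y, subject_id="s1", cfg=cfg0)
        for p, q in zip(tuned.classifier.network_.params,
                        state.classifier.network_.params):
            np.testing.assert_array_equal(p, q)

    def test_dropout_switches_to_train_rate(self):
        state, cfg = self._pretrained()
        X, y = toy_windows(n_per_class=4, seed=3)
        tuned = finetune_subject(state, X, y, subject_id="s1", cfg=cfg)
        rates = {
            l.rate
            for mod in tuned.classifier.network_._modules.values()
            for l in mod.layers
            if isinstance(l, Dropout)
        }
        assert rates == {0.65}
        assert tuned.phase == "finetuned"

    def test_folds_are_independent_of_order(self):
        state, cfg = self._pretrained()
        Xa, ya = toy_windows(n_per_class=4, seed=3)
        Xb, yb = toy_windows(n_per_class=4, seed=4)
        first = finetune_subject(state, Xa, ya, subject_id="a", cfg=cfg)
        _ = finetune_subject(state, Xb, yb, subject_id="b", cfg=cfg)
        again = finetune_subject(state, Xa, ya, subject_id="a", cfg=cfg)
        for p, q in zip(first.classifier.network_.params,
                        again.classifier.network_.params):
            np.testing.assert_array_equal(p, q)

    def test_finetuning_improves_fit_on_subject_windows(self):
        state, cfg = self._pretrained()
        # a "subject" whose amplitudes differ from the pooled data
        X, y = toy_windows(n_per_class=15, seed=9, scale=4.0)
        cfg2 = TrainConfig(**{**cfg.to_dict(), "finetune_epochs": 10,
                              "dropout_train": 0.0})
        tuned = finetune_subject(state, X, y, subject_id="s", cfg=cfg2)
        before = np.mean(state.classifier.predict(X) == y)
        after = np.mean(tuned.classifier.predict(X) == y)
        assert after >= before

    def test_missing_class_warns_but_head_is_kept(self):
        state, cfg = self._pretrained()
        X, y = toy_windows(n_per_class=6, classes=(1,), seed=3)
        with pytest.warns(UserWarning, match="absent"):
            tuned = finetune_subject(state, X, y, subject_id="s", cfg=cfg)
        assert list(tuned.classifier.classes_) == [1, 2]


def test_training_log_round_trip(tmp_path):
    X, y = toy_windows(n_per_class=5)
    cfg = TrainConfig(batch_size=10, epochs=2, lr_initial=0.01,
                      lr_drop_epochs=(), seed=0)
    state = pretrain(PFNetClassifier(**TINY), X, y, cfg)
    path = tmp_path / "log.csv"
    write_training_log(state, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "epoch,lr,loss,train_acc"
    assert len(lines) == 3
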