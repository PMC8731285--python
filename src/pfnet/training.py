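"""The two-phase training recipe: pooled pre-training, then per-subject
fine-tuning.

A model is first pre-trained on the pooled training-repetition windows of
all subjects, then, for each subject (one fold of the intra-subject
evaluation), a copy of the pre-trained model is fine-tuned on that
subject's training windows alone.  Plain SGD with a step learning-rate
schedule; the dropout rate is 0.5 during pre-training and 0.65 during
fine-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .estimators import PFNetClassifier


@dataclass
class TrainConfig:
    """SGD schedule and regularization settings.

    Defaults are the reference profile: batch 1000, 28 epochs, learning
    rate 0.1 divided by ``lr_drop_factor`` = 10 at the (1-based) 16th and
    24th epochs, dropout 0.5 while pre-training and 0.65 while
    fine-tuning.
    """

    batch_size: int = 1000
    epochs: int = 28
    lr_initial: float = 0.1
    lr_drop_epochs: tuple = (16, 24)
    lr_drop_factor: float = 10.0
    dropout_pretrain: float = 0.5
    dropout_train: float = 0.65
    finetune_epochs: int = None
    seed: int = 0

    def __post_init__(self):
        if self.finetune_epochs is None:
            self.finetune_epochs = self.epochs

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """Scaled-down profile for CPU-sized experiments: batch 64,
        fewer epochs, same schedule shape."""
        base = dict(batch_size=64, epochs=10, lr_drop_epochs=(6, 9),
                    finetune_epochs=6)
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainedState:
    """A trained classifier plus its provenance."""

    classifier: PFNetClassifier
    history: list
    phase: str  # "pretrained" or "finetuned"
    config: TrainConfig
    subject_id: str = None


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate of the piecewise-constant schedule at a 1-based epoch.

    The rate starts at ``lr_initial`` and is divided by ``lr_drop_factor``
    at each epoch listed in ``lr_drop_epochs`` (so with the defaults,
    epochs 1-15 run at 0.1, 16-23 at 0.01 and 24-28 at 0.001).
    """
    if not 1 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch must lie in [1, {cfg.epochs}], got {epoch}")
    lr = cfg.lr_initial
    for drop in sorted(cfg.lr_drop_epochs):
        if epoch >= drop:
            lr /= cfg.lr_drop_factor
    return lr


def _apply_config(clf: PFNetClassifier, cfg: TrainConfig) -> PFNetClassifier:
    clf.set_params(
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        lr=cfg.lr_initial,
        lr_drop_epochs=tuple(cfg.lr_drop_epochs),
        lr_drop_factor=cfg.lr_drop_factor,
        dropout_rate=cfg.dropout_pretrain,
        random_state=cfg.seed,
    )
    return clf


def pretrain(model: PFNetClassifier, X, y, cfg: TrainConfig) -> TrainedState:
    """Phase 1: train on the pooled training windows of all subjects.

    ``X`` is the (B, N, C) stack of every subject's training-repetition
    windows, pooled; dropout runs at ``cfg.dropout_pretrain``.
    """
    X = np.asarray(X, dtype=float)
    if len(X) == 0:
        raise ValueError("pre-training requires a nonempty training set")
    _apply_config(model, cfg)
    model.fit(X, y)
    return TrainedState(
        classifier=model, history=list(model.history_),
        phase="pretrained", config=cfg,
    )


def finetune_subject(
    pretrained: TrainedState, X, y, subject_id=None, cfg: TrainConfig = None
) -> TrainedState:
    """Phase 2: fine-tune a copy of the pre-trained model on one subject.

    Starts from the pre-trained parameters, switches dropout to
    ``cfg.dropout_train`` and runs ``cfg.finetune_epochs`` more epochs on
    the subject's own training windows.  The pre-trained state is left
    untouched, so per-subject folds are independent.  A class missing
    from the subject's windows stays in the output head (with a warning).
    """
    import warnings

    cfg = pretrained.config if cfg is None else cfg
    clf = pretrained.classifier.clone_fitted()
    y = np.asarray(y)
    missing = np.setdiff1d(clf.classes_, np.unique(y))
    if missing.size:
        warnings.warn(
            f"subject {subject_id}: classes {missing.tolist()} absent from "
            "fine-tuning data; kept in the output head",
            stacklevel=2,
        )
    if cfg.finetune_epochs > 0:
        clf.continue_fit(X, y, epochs=cfg.finetune_epochs,
                         dropout_rate=cfg.dropout_train)
    return TrainedState(
        classifier=clf, history=list(clf.history_),
        phase="finetuned", config=cfg, subject_id=subject_id,
    )


def write_training_log(state: TrainedState, path) -> None:
    """Dump the per-epoch history as delimited text
    (epoch, lr, loss, train_acc)."""
    lines = ["epoch,lr,loss,train_acc"]
    for rec in state.history:
        lines.append(
            f"{rec['epoch']},{rec['lr']:g},{rec['loss']:.6f},{rec['train_acc']:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
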