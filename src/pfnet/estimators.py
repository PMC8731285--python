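"""Scikit-learn style estimators for the two-stream fusion pipeline.

:class:`DWPTCFeaturizer` and :class:`ChannelReorganizer` are stateless
transformers producing the coefficient images of the domain-knowledge
stream; :class:`PFNetClassifier` is the classifier.  The classifier takes
raw (B, N, C) sEMG windows as ``X`` and derives the wavelet-packet image
stream internally, so it composes with sklearn model selection out of
the box.
"""

from __future__ import annotations

import copy

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .augmentation import build_ordering, reorganize_image
from .dwpt import dwptc_image, wavelet_level
from .nn.model import FusionNetwork, VARIANTS


def _as_windows(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError(f"expected (n_windows, N, C) array, got shape {X.shape}")
    return X


def batch_haar_packet(X: np.ndarray, k: int) -> np.ndarray:
    """Vectorized level-k Haar packet transform along the last axis.

    Equivalent to per-signal :func:`pfnet.dwpt.dwpt_decompose` with
    periodization and natural leaf order (odd-length nodes repeat their
    last sample before pairing), but runs on whole batches at once.
    Returns the concatenated leaf coefficients (the DWPTC vector) along
    the last axis.
    """
    s = np.sqrt(0.5)
    leaves = [np.asarray(X, dtype=float)]
    for _ in range(k):
        nxt = []
        for leaf in leaves:
            if leaf.shape[-1] % 2:
                leaf = np.concatenate([leaf, leaf[..., -1:]], axis=-1)
            even, odd = leaf[..., 0::2], leaf[..., 1::2]
            nxt.append((even + odd) * s)
            nxt.append((even - odd) * s)
        leaves = nxt
    return np.concatenate(leaves, axis=-1)


class DWPTCFeaturizer(TransformerMixin, BaseEstimator):
    """Turn raw (B, N, C) windows into (B, D, C) wavelet-packet images.

    The decomposition level defaults to floor(log2 N).  ``fit`` only
    records the input geometry; the transform itself is parameter-free.
    """

    def __init__(self, level=None):
        self.level = level

    def fit(self, X, y=None):
        X = _as_windows(X)
        self.n_samples_in_ = X.shape[1]
        self.level_ = self.level if self.level is not None else wavelet_level(X.shape[1])
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "level_")
        X = _as_windows(X)
        # batch transform works channel-wise on axis 1 (time)
        vec = batch_haar_packet(np.moveaxis(X, 1, 2), self.level_)  # (B, C, D)
        return np.moveaxis(vec, 1, 2)  # (B, D, C)


class ChannelReorganizer(TransformerMixin, BaseEstimator):
    """Widen (B, D, C) images to (B, D, M) via the round-robin ordering
    in which every channel pair appears in adjacent columns."""

    def __init__(self, ordering=None):
        self.ordering = ordering

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        C = X.shape[-1]
        self.ordering_ = self.ordering if self.ordering is not None else build_ordering(C)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "ordering_")
        X = np.asarray(X, dtype=float)
        idx = np.asarray(self.ordering_.sequence) - 1
        return X[..., idx]


class PFNetClassifier(ClassifierMixin, BaseEstimator):
    """Two-stream progressive-fusion window classifier.

    Parameters
    ----------
    variant : str
        ``full`` (3-stage progressive fusion), ``FLonly``, ``DKonly``,
        ``decision_fusion``, ``stage1_only`` or ``stage2_only``.
    maps, fc_feature, fc_knowledge, fc_fusion : int
        Layer widths.  The reference configuration is 64 feature maps,
        512/1024-unit stream FCs and 512-unit fusion FCs; the defaults
        here are a desk-scale profile with the identical topology.
    epochs, batch_size, lr, lr_drop_epochs, lr_drop_factor : training
        schedule (plain SGD; the learning rate is divided by
        ``lr_drop_factor`` at each 1-based epoch in ``lr_drop_epochs``).
    dropout_rate : float
        Drop probability at the five dropout sites.
    standardize : bool
        Per-feature standardization of both input streams using
        training-set statistics.
    loss_mode : {"per_head", "final"}
        Sum of per-head cross-entropies (default) or cross-entropy on the
        averaged final scores.
    random_state : int
        Seeds initialization, dropout and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    network_ : FusionNetwork
        The underlying layer graph.
    history_ : list of dict
        Per-epoch ``{"epoch", "lr", "loss", "train_acc"}`` records.
    """

    def __init__(
        self,
        variant="full",
        maps=16,
        fc_feature=128,
        fc_knowledge=128,
        fc_fusion=64,
        epochs=10,
        batch_size=64,
        lr=0.1,
        lr_drop_epochs=(16, 24),
        lr_drop_factor=10.0,
        dropout_rate=0.5,
        standardize=True,
        loss_mode="per_head",
        wavelet_level=None,
        ordering=None,
        random_state=0,
    ):
        self.variant = variant
        self.maps = maps
        self.fc_feature = fc_feature
        self.fc_knowledge = fc_knowledge
        self.fc_fusion = fc_fusion
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_drop_epochs = lr_drop_epochs
        self.lr_drop_factor = lr_drop_factor
        self.dropout_rate = dropout_rate
        self.standardize = standardize
        self.loss_mode = loss_mode
        self.wavelet_level = wavelet_level
        self.ordering = ordering
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _lr_at(self, epoch: int) -> float:
        lr = self.lr
        for drop in sorted(self.lr_drop_epochs):
            if epoch >= drop:
                lr /= self.lr_drop_factor
        return lr

    def _feature_streams(self, X, fit=False):
        """Raw and (where the variant needs it) coefficient-image streams."""
        X = _as_windows(X)
        if self.variant == "DKonly":
            raw = None
        else:
            raw = X
        dwpt = None
        if self.variant != "FLonly":
            if fit:
                self._featurizer_ = DWPTCFeaturizer(level=self.wavelet_level).fit(X)
                imgs = self._featurizer_.transform(X)
                self._reorganizer_ = ChannelReorganizer(ordering=self.ordering).fit(imgs)
            imgs = self._featurizer_.transform(X)
            dwpt = self._reorganizer_.transform(imgs)
        if self.standardize:
            if fit:
                self.raw_mean_ = X.mean(axis=0)
                self.raw_std_ = X.std(axis=0) + 1e-8
                if dwpt is not None:
                    self.dwpt_mean_ = dwpt.mean(axis=0)
                    self.dwpt_std_ = dwpt.std(axis=0) + 1e-8
            if raw is not None:
                raw = (raw - self.raw_mean_) / self.raw_std_
            if dwpt is not None:
                dwpt = (dwpt - self.dwpt_mean_) / self.dwpt_std_
        return raw, dwpt

    def fit(self, X, y, epochs=None):
        """Train from scratch with minibatch SGD."""
        X = _as_windows(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y have inconsistent lengths")
        if len(X) == 0:
            raise ValueError("empty training set")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self._rng_ = np.random.default_rng(self.random_state)
        raw, dwpt = self._feature_streams(X, fit=True)
        raw_shape = X.shape[1:]
        dwpt_shape = dwpt.shape[1:] if dwpt is not None else None
        self.network_ = FusionNetwork(
            self.variant,
            raw_shape,
            dwpt_shape,
            num_classes=len(self.classes_),
            maps=self.maps,
            fc_feature=self.fc_feature,
            fc_knowledge=self.fc_knowledge,
            fc_fusion=self.fc_fusion,
            dropout_rate=self.dropout_rate,
            rng=self._rng_,
            loss_mode=self.loss_mode,
        )
        self.history_ = []
        self._run_epochs(raw, dwpt, y_idx, self.epochs if epochs is None else epochs,
                         start_epoch=1)
        return self

    def continue_fit(self, X, y, epochs, dropout_rate=None, lr=None):
        """Continue training the fitted network on new data (used by the
        per-subject fine-tuning phase).  Class labels must be drawn from
        ``classes_``; classes absent from ``y`` stay in the output head."""
        check_is_fitted(self, "network_")
        X = _as_windows(X)
        y = np.asarray(y)
        unknown = np.setdiff1d(np.unique(y), self.classes_)
        if unknown.size:
            raise ValueError(f"unseen class labels {unknown} in continue_fit")
        y_idx = np.searchsorted(self.classes_, y)
        if dropout_rate is not None:
            self.network_.set_dropout_rate(dropout_rate)
        raw, dwpt = self._feature_streams(X, fit=False)
        self._run_epochs(raw, dwpt, y_idx, epochs, start_epoch=1, lr_override=lr)
        return self

    def _run_epochs(self, raw, dwpt, y_idx, epochs, start_epoch, lr_override=None):
        n = len(y_idx)
        onehot = np.eye(len(self.classes_))[y_idx]
        net = self.network_
        for epoch in range(start_epoch, start_epoch + epochs):
            lr = self._lr_at(epoch) if lr_override is None else lr_override
            order = self._rng_.permutation(n)
            total_loss = 0.0
            correct = 0
            for s in range(0, n, self.batch_size):
                idx = order[s : s + self.batch_size]
                xb_raw = raw[idx] if raw is not None else None
                xb_dwpt = dwpt[idx] if dwpt is not None else None
                out = net.forward(xb_raw, xb_dwpt, training=True)
                loss = net.backward(out, onehot[idx])
                net.sgd_step(lr)
                total_loss += loss * len(idx)
                correct += int((np.argmax(out["scores"], axis=1) == y_idx[idx]).sum())
            self.history_.append(
                {
                    "epoch": epoch,
                    "lr": lr,
                    "loss": total_loss / n,
                    "train_acc": correct / n,
                }
            )

    # ------------------------------------------------------------------ #

    def _scores(self, X, batch_size=256):
        check_is_fitted(self, "network_")
        raw, dwpt = self._feature_streams(_as_windows(X), fit=False)
        n = len(X)
        chunks = []
        for s in range(0, n, batch_size):
            xb_raw = raw[s : s + batch_size] if raw is not None else None
            xb_dwpt = dwpt[s : s + batch_size] if dwpt is not None else None
            chunks.append(self.network_.forward(xb_raw, xb_dwpt, training=False)["scores"])
        return np.concatenate(chunks, axis=0)

    def decision_function(self, X):
        """Final fused scores (sum of softmax heads where two are fused)."""
        return self._scores(X)

    def predict_proba(self, X):
        s = self._scores(X)
        return s / s.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._scores(X), axis=1)]

    def clone_fitted(self) -> "PFNetClassifier":
        """Deep copy including trained parameters and generator state;
        the basis of independent per-subject fine-tuning."""
        check_is_fitted(self, "network_")
        return copy.deepcopy(self)


def reference_profile(**overrides) -> dict:
    """Keyword arguments reproducing the reference training profile:
    64 maps, 512/1024/512 FC widths, batch 1000, 28 epochs, learning rate
    0.1 divided by 10 at epochs 16 and 24."""
    kwargs = dict(
        maps=64,
        fc_feature=512,
        fc_knowledge=1024,
        fc_fusion=512,
        epochs=28,
        batch_size=1000,
        lr=0.1,
        lr_drop_epochs=(16, 24),
        lr_drop_factor=10.0,
    )
    kwargs.update(overrides)
    return kwargs
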