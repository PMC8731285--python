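"""The two-stream fusion network and its ablation variants.

The full architecture has

* a **feature-learning stream** on raw N x C sEMG windows:
  conv3x3(F) -> conv3x3(F) -> LC1x1(F) -> LC1x1(F) -> FC(w_f), with batch
  norm + ReLU after every weighted layer and dropout after the 2nd
  locally connected layer and the FC;
* a **domain-knowledge stream** on D x M reorganized wavelet-packet
  coefficient images: conv1x1(F) -> conv2x2(F, valid) -> LC1x1(F) ->
  LC1x1(F) -> FC(w_d), same normalization/dropout placement;
* a **3-stage progressive fusion module**: subnetwork H1 classifies the
  concatenated flattened 4th-layer maps (stage 1, feature-level),
  subnetwork H2 classifies the concatenated 5th-layer FC vectors
  (stage 2, feature-level), and the final decision is the element-wise
  sum of the two softmax score vectors (stage 3, decision-level).

H1 is FC(w_h) -> dropout -> FC(w_h) -> FC(classes)/softmax and H2 is
FC(w_h) -> FC(classes)/softmax, so the second-last FC of both
subnetworks has w_h units (512 in the reference configuration).

Ablation variants: ``FLonly``/``DKonly`` keep one stream plus a softmax
classifier; ``decision_fusion`` appends a second FC (w_h units) and a
softmax head to each stream and sums the two score vectors;
``stage1_only``/``stage2_only`` keep a single fusion subnetwork.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    LocallyConnected2D,
    ReLU,
    Sequential,
    softmax,
)

VARIANTS = ("full", "FLonly", "DKonly", "decision_fusion", "stage1_only", "stage2_only")

#: Reference layer widths (feature maps, stream FC widths, fusion FC width).
REFERENCE_WIDTHS = {"maps": 64, "fc_feature": 512, "fc_knowledge": 1024, "fc_fusion": 512}


def _bn_relu(width):
    return [BatchNorm(width), ReLU()]


class FusionNetwork:
    """Forward/backward graph for one variant.

    Parameters
    ----------
    variant : str
        One of :data:`VARIANTS`.
    raw_shape : (N, C)
        Shape of one raw sEMG window.
    dwpt_shape : (D, M)
        Shape of one reorganized coefficient image (may be ``None`` for
        ``FLonly``).
    num_classes : int
    maps, fc_feature, fc_knowledge, fc_fusion : int
        Feature maps per conv/LC layer and FC widths (reference values
        64 / 512 / 1024 / 512; smaller values give desk-scale models with
        the identical topology).
    dropout_rate : float
    rng : numpy Generator
        Sole source of randomness (init and dropout masks).
    loss_mode : {"per_head", "final"}
        ``per_head`` sums the cross-entropies of the individual softmax
        heads (each head must emit meaningful scores for the final score
        summation); ``final`` applies cross-entropy to the averaged final
        scores instead.
    """

    def __init__(
        self,
        variant,
        raw_shape,
        dwpt_shape,
        num_classes,
        maps=64,
        fc_feature=512,
        fc_knowledge=1024,
        fc_fusion=512,
        dropout_rate=0.5,
        rng=None,
        loss_mode="per_head",
    ):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
        if loss_mode not in ("per_head", "final"):
            raise ValueError(f"unknown loss_mode {loss_mode!r}")
        self.variant = variant
        self.num_classes = int(num_classes)
        self.loss_mode = loss_mode
        self.rng = np.random.default_rng() if rng is None else rng
        rng = self.rng
        self._modules = {}

        self.use_fl = variant != "DKonly"
        self.use_dk = variant != "FLonly"
        if self.use_dk and dwpt_shape is None:
            raise ValueError(f"variant {variant!r} requires the coefficient-image shape")

        if self.use_fl:
            N, C = raw_shape
            self._modules["fl_trunk"] = Sequential([
                Conv2D(1, maps, (3, 3), rng, padding="same"), *_bn_relu(maps),
                Conv2D(maps, maps, (3, 3), rng, padding="same"), *_bn_relu(maps),
                LocallyConnected2D(N, C, maps, maps, rng), *_bn_relu(maps),
                LocallyConnected2D(N, C, maps, maps, rng), *_bn_relu(maps),
                Dropout(dropout_rate, rng),
            ])
            self._fl_flat4 = N * C * maps
        if self.use_dk:
            D, M = dwpt_shape
            self._modules["dk_trunk"] = Sequential([
                Conv2D(1, maps, (1, 1), rng, padding="same"), *_bn_relu(maps),
                Conv2D(maps, maps, (2, 2), rng, padding="valid"), *_bn_relu(maps),
                LocallyConnected2D(D - 1, M - 1, maps, maps, rng), *_bn_relu(maps),
                LocallyConnected2D(D - 1, M - 1, maps, maps, rng), *_bn_relu(maps),
                Dropout(dropout_rate, rng),
            ])
            self._dk_flat4 = (D - 1) * (M - 1) * maps

        need_fc_f = self.use_fl and variant != "stage1_only"
        need_fc_d = self.use_dk and variant != "stage1_only"
        if need_fc_f:
            self._modules["fl_fc"] = Sequential([
                Flatten(), Dense(self._fl_flat4, fc_feature, rng),
                *_bn_relu(fc_feature), Dropout(dropout_rate, rng),
            ])
        if need_fc_d:
            self._modules["dk_fc"] = Sequential([
                Flatten(), Dense(self._dk_flat4, fc_knowledge, rng),
                *_bn_relu(fc_knowledge), Dropout(dropout_rate, rng),
            ])

        nc = self.num_classes
        if variant in ("full", "stage1_only"):
            self._modules["h1"] = Sequential([
                Dense(self._fl_flat4 + self._dk_flat4, fc_fusion, rng),
                *_bn_relu(fc_fusion), Dropout(dropout_rate, rng),
                Dense(fc_fusion, fc_fusion, rng), *_bn_relu(fc_fusion),
                Dense(fc_fusion, nc, rng),
            ])
        if variant in ("full", "stage2_only"):
            self._modules["h2"] = Sequential([
                Dense(fc_feature + fc_knowledge, fc_fusion, rng),
                *_bn_relu(fc_fusion),
                Dense(fc_fusion, nc, rng),
            ])
        if variant == "FLonly":
            self._modules["fl_head"] = Sequential([Dense(fc_feature, nc, rng)])
        if variant == "DKonly":
            self._modules["dk_head"] = Sequential([Dense(fc_knowledge, nc, rng)])
        if variant == "decision_fusion":
            self._modules["fl_head"] = Sequential([
                Dense(fc_feature, fc_fusion, rng), *_bn_relu(fc_fusion),
                Dense(fc_fusion, nc, rng),
            ])
            self._modules["dk_head"] = Sequential([
                Dense(fc_knowledge, fc_fusion, rng), *_bn_relu(fc_fusion),
                Dense(fc_fusion, nc, rng),
            ])

        self.params = [p for m in self._modules.values() for p in m.params]
        self.grads = [g for m in self._modules.values() for g in m.grads]

    # ------------------------------------------------------------------ #

    @staticmethod
    def _img(x):
        return x[..., None] if x.ndim == 3 else x

    def forward(self, x_raw, x_dwpt, training=False):
        """Run the variant; returns a dict with per-head softmax scores
        and ``scores``, the final decision vector (sums to 2 when two
        heads are fused, to 1 otherwise)."""
        m = self._modules
        out = {}
        cache = {}
        if self.use_fl:
            a4f = m["fl_trunk"].forward(self._img(x_raw), training)
            cache["a4f"] = a4f
            if "fl_fc" in m:
                cache["h5f"] = m["fl_fc"].forward(a4f, training)
        if self.use_dk:
            a4d = m["dk_trunk"].forward(self._img(x_dwpt), training)
            cache["a4d"] = a4d
            if "dk_fc" in m:
                cache["h5d"] = m["dk_fc"].forward(a4d, training)

        v = self.variant
        if v in ("full", "stage1_only"):
            B = cache["a4f"].shape[0]
            cat1 = np.concatenate(
                [cache["a4f"].reshape(B, -1), cache["a4d"].reshape(B, -1)], axis=1
            )
            out["y1"] = softmax(m["h1"].forward(cat1, training))
        if v in ("full", "stage2_only"):
            cat2 = np.concatenate([cache["h5f"], cache["h5d"]], axis=1)
            out["y2"] = softmax(m["h2"].forward(cat2, training))
        if v == "FLonly":
            out["y1"] = softmax(m["fl_head"].forward(cache["h5f"], training))
        if v == "DKonly":
            out["y1"] = softmax(m["dk_head"].forward(cache["h5d"], training))
        if v == "decision_fusion":
            out["y1"] = softmax(m["fl_head"].forward(cache["h5f"], training))
            out["y2"] = softmax(m["dk_head"].forward(cache["h5d"], training))

        if v in ("full", "decision_fusion"):
            out["scores"] = out["y1"] + out["y2"]
        elif v == "stage2_only":
            out["scores"] = out["y2"]
        else:
            out["scores"] = out["y1"]
        self._cache = cache
        return out

    def predict(self, x_raw, x_dwpt):
        """Predicted class indices (argmax of final scores; ties go to the
        lowest class index)."""
        return np.argmax(self.forward(x_raw, x_dwpt, training=False)["scores"], axis=1)

    # ------------------------------------------------------------------ #

    def _head_grads(self, out, t):
        """Cross-entropy loss and d(loss)/d(logits) for each active head."""
        B = t.shape[0]
        eps = 1e-12
        heads = [k for k in ("y1", "y2") if k in out]
        if self.loss_mode == "final" and len(heads) == 2:
            p = out["scores"] / 2.0
            loss = -np.log((p * t).sum(axis=1) + eps).mean()
            dp = -(t / (p + eps)) / (2.0 * B)
            dz = {}
            for h in heads:
                y = out[h]
                dz[h] = y * (dp - (dp * y).sum(axis=1, keepdims=True))
            return loss, dz
        loss = 0.0
        dz = {}
        for h in heads:
            y = out[h]
            loss += -np.log((y * t).sum(axis=1) + eps).mean()
            dz[h] = (y - t) / B
        return loss, dz

    def backward(self, out, labels_onehot):
        """Backpropagate the training loss; gradients accumulate into the
        layers.  Returns the scalar loss."""
        m = self._modules
        cache = self._cache
        loss, dz = self._head_grads(out, labels_onehot)
        v = self.variant
        d_a4f = d_a4d = d_h5f = d_h5d = None

        if v in ("full", "stage1_only"):
            dcat1 = m["h1"].backward(dz["y1"])
            n4f = self._fl_flat4
            d_a4f = dcat1[:, :n4f].reshape(cache["a4f"].shape)
            d_a4d = dcat1[:, n4f:].reshape(cache["a4d"].shape)
        if v in ("full", "stage2_only"):
            key = "y2" if "y2" in dz else "y1"
            dcat2 = m["h2"].backward(dz[key])
            nf = cache["h5f"].shape[1]
            d_h5f = dcat2[:, :nf]
            d_h5d = dcat2[:, nf:]
        if v == "FLonly":
            d_h5f = m["fl_head"].backward(dz["y1"])
        if v == "DKonly":
            d_h5d = m["dk_head"].backward(dz["y1"])
        if v == "decision_fusion":
            d_h5f = m["fl_head"].backward(dz["y1"])
            d_h5d = m["dk_head"].backward(dz["y2"])

        if d_h5f is not None:
            extra = m["fl_fc"].backward(d_h5f)
            d_a4f = extra if d_a4f is None else d_a4f + extra
        if d_h5d is not None:
            extra = m["dk_fc"].backward(d_h5d)
            d_a4d = extra if d_a4d is None else d_a4d + extra
        if d_a4f is not None:
            m["fl_trunk"].backward(d_a4f)
        if d_a4d is not None:
            m["dk_trunk"].backward(d_a4d)
        return loss

    # ------------------------------------------------------------------ #

    def zero_grad(self):
        for g in self.grads:
            g.fill(0.0)

    def sgd_step(self, lr):
        for p, g in zip(self.params, self.grads):
            p -= lr * g
        self.zero_grad()

    def set_dropout_rate(self, rate):
        for mod in self._modules.values():
            mod.set_dropout_rate(rate)

    # -- parameter state (for checkpointing and pre-train -> fine-tune) -- #

    def _bn_layers(self):
        for mod in self._modules.values():
            for l in mod.layers:
                if isinstance(l, BatchNorm):
                    yield l

    def get_state(self):
        """Copy of all parameters and batch-norm running statistics."""
        return {
            "params": [p.copy() for p in self.params],
            "bn": [(l.running_mean.copy(), l.running_var.copy()) for l in self._bn_layers()],
        }

    def set_state(self, state):
        for p, q in zip(self.params, state["params"]):
            p[...] = q
        for l, (mean, var) in zip(self._bn_layers(), state["bn"]):
            l.running_mean[...] = mean
            l.running_var[...] = var

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.params))
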