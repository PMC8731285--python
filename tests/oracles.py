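"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own transform/forward paths:
the wavelet-packet oracle builds the explicit orthogonal matrix of the
level-k Haar filter bank by composing per-level block matrices, and the
fusion oracle recomputes the network forward pass with straight-line
loops over the raw parameter arrays.
"""

import numpy as np

S = np.sqrt(0.5)


def haar_level_matrix(n: int) -> np.ndarray:
    """One analysis step on a length-n signal (n even): rows 0..n/2-1 are
    the averaging (low-pass) outputs, rows n/2.. the differencing ones."""
    assert n % 2 == 0
    T = np.zeros((n, n))
    for i in range(n // 2):
        T[i, 2 * i] = S
        T[i, 2 * i + 1] = S
        T[n // 2 + i, 2 * i] = S
        T[n // 2 + i, 2 * i + 1] = -S
    return T


def haar_packet_matrix(n: int, k: int) -> np.ndarray:
    """Explicit matrix of the level-k packet transform in natural leaf
    order (approximation block before detail block, recursively), for
    dyadic n with 2^k <= n."""
    if k == 0:
        return np.eye(n)
    T1 = haar_level_matrix(n)
    half = haar_packet_matrix(n // 2, k - 1)
    block = np.zeros((n, n))
    block[: n // 2, : n // 2] = half
    block[n // 2 :, n // 2 :] = half
    return block @ T1


def packet_leaf_lengths(n: int, k: int) -> int:
    """Per-leaf length after k periodized levels: ceil at every level."""
    for _ in range(k):
        n = (n + 1) // 2
    return n


# --------------------------------------------------------------------- #
# Straight-line forward pass over a FusionNetwork's parameter arrays.


def _run_layers(layers, x):
    from pfnet.nn.layers import (
        BatchNorm, Conv2D, Dense, Dropout, Flatten, LocallyConnected2D, ReLU,
    )

    for layer in layers:
        if isinstance(layer, Dense):
            x = x @ layer.W + layer.b
        elif isinstance(layer, Conv2D):
            x = _conv_forward(x, layer)
        elif isinstance(layer, LocallyConnected2D):
            B = x.shape[0]
            H, W, ci, co = layer.W.shape
            out = np.zeros((B, H, W, co))
            for b in range(B):
                for h in range(H):
                    for w in range(W):
                        out[b, h, w] = x[b, h, w] @ layer.W[h, w] + layer.b[h, w]
            x = out
        elif isinstance(layer, BatchNorm):
            x = (
                layer.gamma * (x - layer.running_mean)
                / np.sqrt(layer.running_var + layer.eps)
                + layer.beta
            )
        elif isinstance(layer, ReLU):
            x = np.maximum(x, 0.0)
        elif isinstance(layer, Dropout):
            pass  # identity at inference
        elif isinstance(layer, Flatten):
            x = x.reshape(x.shape[0], -1)
        else:  # pragma: no cover
            raise TypeError(f"oracle does not know layer {type(layer)}")
    return x


def _conv_forward(x, layer):
    B, H, W, C = x.shape
    kh, kw = layer.kh, layer.kw
    if layer.padding == "same":
        pt = (kh - 1) // 2
        pl = (kw - 1) // 2
        xp = np.pad(x, ((0, 0), (pt, kh - 1 - pt), (pl, kw - 1 - pl), (0, 0)))
        Ho, Wo = H, W
    else:
        xp = x
        Ho, Wo = H - kh + 1, W - kw + 1
    co = layer.W.shape[-1]
    out = np.zeros((B, Ho, Wo, co))
    for b in range(B):
        for h in range(Ho):
            for w in range(Wo):
                for o in range(co):
                    acc = layer.b[o]
                    for i in range(kh):
                        for j in range(kw):
                            for c in range(C):
                                acc += xp[b, h + i, w + j, c] * layer.W[i, j, c, o]
                    out[b, h, w, o] = acc
    return out


def _softmax(z):
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def fusion_forward_oracle(net, x_raw, x_dwpt):
    """Hand-composed 3-stage fusion: y1 = H1(F4f || F4d), y2 = H2(F5f ||
    F5d), y_final = y1 + y2, each from straight-line layer arithmetic."""
    m = net._modules
    a4f = _run_layers(m["fl_trunk"].layers, x_raw[..., None])
    a4d = _run_layers(m["dk_trunk"].layers, x_dwpt[..., None])
    h5f = _run_layers(m["fl_fc"].layers, a4f)
    h5d = _run_layers(m["dk_fc"].layers, a4d)
    B = a4f.shape[0]
    cat1 = np.concatenate([a4f.reshape(B, -1), a4d.reshape(B, -1)], axis=1)
    cat2 = np.concatenate([h5f, h5d], axis=1)
    y1 = _softmax(_run_layers(m["h1"].layers, cat1))
    y2 = _softmax(_run_layers(m["h2"].layers, cat2))
    return y1, y2, y1 + y2
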