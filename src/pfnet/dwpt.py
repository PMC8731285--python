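"""Discrete wavelet packet transform (Haar) and coefficient images.

The wavelet packet transform recursively splits *both* the approximation
and the detail branch with a half-band low-pass / high-pass filter pair,
downsampling by 2 at every node, so level k yields 2^k equal-bandwidth
sub-band sequences.  With the Daubechies-1 (Haar) pair

    lowpass  L = [1/sqrt(2),  1/sqrt(2)]
    highpass H = [1/sqrt(2), -1/sqrt(2)]

the filter bank is orthonormal: energy is conserved and the transform is
perfectly invertible.  Per channel, the 2^k leaf sequences are
concatenated (natural order, approximation before detail) into a DWPTC
vector of length D, and the per-channel vectors are stacked column-wise
into the D x C DWPTC image that feeds the domain-knowledge stream.

Boundary handling defaults to periodization, which keeps every level at
ceil(len/2) samples and so supports the non-dyadic 20-sample windows of a
200 ms window at 100 Hz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt


@dataclass(frozen=True)
class WaveletFilterPair:
    """A half-band analysis filter pair; Daubechies-1 by default."""

    lowpass: tuple = (1.0 / math.sqrt(2.0), 1.0 / math.sqrt(2.0))
    highpass: tuple = (1.0 / math.sqrt(2.0), -1.0 / math.sqrt(2.0))
    name: str = "db1"

    def __post_init__(self):
        lo = np.asarray(self.lowpass)
        hi = np.asarray(self.highpass)
        if not (np.isclose(lo @ lo, 1.0) and np.isclose(hi @ hi, 1.0)):
            raise ValueError("filters must have unit l2 norm")
        if len(lo) == len(hi) and not np.isclose(lo @ hi, 0.0):
            raise ValueError("lowpass and highpass filters must be orthogonal")


def haar_filters() -> WaveletFilterPair:
    """The Daubechies-1 (Haar) analysis pair."""
    return WaveletFilterPair()


@dataclass
class PacketTree:
    """A complete level-k wavelet packet decomposition of one signal.

    ``leaves`` holds the 2^k sub-band coefficient sequences in natural
    (binary-tree, approximation-before-detail) order; ``paths`` the
    corresponding a/d node paths (e.g. ``aad``).
    """

    level: int
    leaves: list
    paths: list
    input_length: int
    mode: str = "periodization"
    order: str = "natural"

    def __post_init__(self):
        if len(self.leaves) != 2 ** self.level:
            raise ValueError(
                f"level-{self.level} tree must have {2 ** self.level} leaves, "
                f"got {len(self.leaves)}"
            )
        lens = {len(l) for l in self.leaves}
        if len(lens) != 1:
            raise ValueError(f"leaf lengths are inconsistent: {sorted(lens)}")

    @property
    def leaf_length(self) -> int:
        return len(self.leaves[0])


@dataclass
class DWPTCImage:
    """D x C image of concatenated wavelet-packet coefficients per channel."""

    data: np.ndarray
    level: int

    @property
    def D(self) -> int:
        return self.data.shape[0]

    @property
    def C(self) -> int:
        return self.data.shape[1]


def wavelet_level(N: int) -> int:
    """Decomposition depth used for a window of N samples: floor(log2 N)."""
    if N < 1:
        raise ValueError(f"window length must be >= 1, got {N}")
    return int(math.floor(math.log2(N)))


def _check_filters(filters: WaveletFilterPair) -> str:
    if filters is None:
        return "db1"
    if filters.name != "db1":
        raise NotImplementedError(
            "only the Daubechies-1 (Haar) filter pair is supported"
        )
    return filters.name


def dwpt_decompose(
    x,
    k: int,
    filters: WaveletFilterPair | None = None,
    mode: str = "periodization",
    order: str = "natural",
) -> PacketTree:
    """Full wavelet packet decomposition of ``x`` to level ``k``.

    Both children of every node are expanded; each step convolves with the
    analysis pair and downsamples by 2.  ``order`` selects the leaf layout:
    ``natural`` (binary-tree, a-before-d) or ``freq`` (Gray-code frequency
    order).
    """
    x = np.asarray(x, dtype=float).ravel()
    wavelet = _check_filters(filters)
    if k < 0:
        raise ValueError("level must be nonnegative")
    if k == 0:
        return PacketTree(0, [x.copy()], [""], len(x), mode, order)
    max_k = wavelet_level(len(x)) if mode == "periodization" else k
    if len(x) < 2 ** k or (mode == "periodization" and k > max_k):
        raise ValueError(
            f"level {k} is too deep for an input of {len(x)} samples"
        )
    wp = pywt.WaveletPacket(x, wavelet, mode=mode, maxlevel=k)
    nodes = wp.get_level(k, order=order)
    return PacketTree(
        level=k,
        leaves=[np.asarray(n.data, dtype=float) for n in nodes],
        paths=[n.path for n in nodes],
        input_length=len(x),
        mode=mode,
        order=order,
    )


def dwpt_reconstruct(tree: PacketTree, filters: WaveletFilterPair | None = None):
    """Invert a packet decomposition; exact for the orthonormal Haar bank.

    Returns the signal on its original ``input_length`` samples (the
    synthesis of a periodized non-dyadic decomposition is defined on the
    padded dyadic grid and is cropped back).
    """
    wavelet = _check_filters(filters)
    if tree.level == 0:
        return tree.leaves[0].copy()
    wp = pywt.WaveletPacket(None, wavelet, mode=tree.mode, maxlevel=tree.level)
    for path, leaf in zip(tree.paths, tree.leaves):
        wp[path] = np.asarray(leaf, dtype=float)
    xr = wp.reconstruct(update=False)
    return np.asarray(xr, dtype=float)[: tree.input_length]


def dwptc_vector(tree: PacketTree) -> np.ndarray:
    """Concatenate the 2^k leaf sequences into one coefficient vector."""
    return np.concatenate([np.asarray(l, dtype=float) for l in tree.leaves])


def dwptc_image(
    window_data,
    filters: WaveletFilterPair | None = None,
    level: int | None = None,
    mode: str = "periodization",
    order: str = "natural",
) -> DWPTCImage:
    """DWPTC image of an N x C window: column c is channel c's DWPTC vector.

    ``level`` defaults to floor(log2 N).  All channels share one level, so
    the image is D x C with D = 2^k * leaf_length.
    """
    data = getattr(window_data, "data", window_data)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("window data must be an N x C matrix")
    N, C = data.shape
    k = wavelet_level(N) if level is None else level
    cols = [
        dwptc_vector(dwpt_decompose(data[:, c], k, filters, mode=mode, order=order))
        for c in range(C)
    ]
    return DWPTCImage(data=np.stack(cols, axis=1), level=k)


def subband_statistics(tree: PacketTree, excess_kurtosis: bool = False) -> np.ndarray:
    """Per-leaf {energy, mean, std, skewness, kurtosis}, concatenated.

    Classical shallow-learning descriptors of the packet sub-bands, kept as
    a utility.  Conventions: std is the population standard deviation,
    skewness is the biased g1 moment ratio, and kurtosis is raw (Gaussian
    -> 3) unless ``excess_kurtosis`` is set.  Leaves shorter than 2 samples
    report 0 for std/skewness/kurtosis with a warning.
    """
    from scipy import stats

    out = []
    for leaf in tree.leaves:
        leaf = np.asarray(leaf, dtype=float)
        energy = float(leaf @ leaf)
        mean = float(leaf.mean())
        if leaf.size < 2:
            warnings.warn(
                "leaf shorter than 2 samples; std/skewness/kurtosis set to 0",
                stacklevel=2,
            )
            out.extend([energy, mean, 0.0, 0.0, 0.0])
            continue
        std = float(leaf.std())
        if std == 0.0:
            skew = kurt = 0.0
        else:
            skew = float(stats.skew(leaf, bias=True))
            kurt = float(stats.kurtosis(leaf, fisher=excess_kurtosis, bias=True))
        out.extend([energy, mean, std, skew, kurt])
    return np.array(out)
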