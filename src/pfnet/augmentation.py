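"""Channel-reorganization augmentation of DWPTC images.

Surface-EMG electrodes form a ring or grid, but a D x C coefficient image
only places physically neighbouring channels in adjacent columns.  The
reorganization widens the image to D x M by repeating columns in an order
in which **every unordered pair of channels appears in adjacent columns
at least once**, so a small convolutional filter can see the spatial
correlation between any two channels.

For even C the ordering is the concatenation of C/2 edge-disjoint
Hamiltonian paths of the complete graph K_C (the classical round-robin /
zigzag decomposition), giving M = C^2/2: M = 50 for C = 10 and M = 72 for
C = 12.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .dwpt import DWPTCImage


@dataclass(frozen=True)
class ChannelOrdering:
    """A length-M sequence of 1-based channel indices covering all pairs."""

    sequence: tuple
    C: int

    def __post_init__(self):
        seq = tuple(int(s) for s in self.sequence)
        object.__setattr__(self, "sequence", seq)
        if any(not 1 <= s <= self.C for s in seq):
            raise ValueError(f"channel indices must lie in [1, {self.C}]")
        if set(seq) != set(range(1, self.C + 1)):
            raise ValueError("every channel must appear at least once")

    @property
    def M(self) -> int:
        return len(self.sequence)

    def adjacent_pairs(self) -> set:
        """Unordered channel pairs occupying adjacent output columns."""
        return {
            frozenset((a, b))
            for a, b in zip(self.sequence, self.sequence[1:])
            if a != b
        }

    def covers_all_pairs(self) -> bool:
        wanted = {frozenset(p) for p in combinations(range(1, self.C + 1), 2)}
        return wanted <= self.adjacent_pairs()


def _zigzag_path(start: int, C: int) -> list:
    # Zigzag Hamiltonian path of K_C (vertices 0..C-1), rotated to `start`:
    # offsets 0, +1, -1, +2, -2, ... so consecutive-vertex differences sweep
    # 1..C-1 and the C/2 rotations are edge-disjoint.
    offs = [0]
    step = 1
    while len(offs) < C:
        offs.append(step)
        if len(offs) < C:
            offs.append(-step)
        step += 1
    return [(start + o) % C for o in offs]


def build_ordering(C: int) -> ChannelOrdering:
    """Round-robin channel ordering with full pairwise adjacency coverage.

    Concatenates the C/2 edge-disjoint zigzag Hamiltonian paths of K_C,
    yielding a deterministic length-M sequence with M = C^2/2.  Requires
    even C >= 2 (all supported electrode counts are even); for odd C
    supply an explicit ordering via :func:`load_ordering`.
    """
    if C < 2 or C % 2:
        raise ValueError(
            f"round-robin ordering requires an even channel count >= 2, got {C}; "
            "supply an explicit ordering file for other layouts"
        )
    seq = []
    for start in range(C // 2):
        seq.extend(v + 1 for v in _zigzag_path(start, C))
    return ChannelOrdering(sequence=tuple(seq), C=C)


def load_ordering(path, C: int) -> ChannelOrdering:
    """Read a user-supplied ordering (one 1-based channel index per line).

    Coverage of all channel pairs is checked; a gap produces a warning,
    not an error, since partial orderings are occasionally intentional.
    """
    seq = [
        int(line)
        for line in Path(path).read_text().split()
        if line.strip()
    ]
    ordering = ChannelOrdering(sequence=tuple(seq), C=C)
    if not ordering.covers_all_pairs():
        warnings.warn(
            f"{path}: ordering does not make every channel pair adjacent",
            stacklevel=2,
        )
    return ordering


def reorganize_image(img, ordering: ChannelOrdering) -> np.ndarray:
    """Gather image columns by the ordering: output column j is input
    column ``sequence[j]``.  Values are copied, never transformed."""
    data = img.data if isinstance(img, DWPTCImage) else np.asarray(img, dtype=float)
    if data.ndim != 2:
        raise ValueError("image must be a D x C matrix")
    if data.shape[1] != ordering.C:
        raise ValueError(
            f"image has {data.shape[1]} channels but ordering expects {ordering.C}"
        )
    idx = np.asarray(ordering.sequence) - 1
    return data[:, idx].copy()
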