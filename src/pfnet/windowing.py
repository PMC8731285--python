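"""Sliding-window segmentation and repetition-wise train/test splits.

Classification operates on fixed-length windows of the multichannel
signal.  A window is emitted only if every sample in it carries the same
movement label and the same repetition index, so windows spanning a
movement or repetition boundary are discarded and the label track is
clean by construction.  Rest windows (label 0) are dropped by default,
matching the 52/50-movement protocols that exclude the rest class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Recording


@dataclass
class Window:
    """One N x C window with a single movement label and repetition index."""

    data: np.ndarray
    label: int
    repetition: int
    subject_id: str


@dataclass
class WindowSet:
    """An ordered collection of same-shaped windows from one segmentation."""

    windows: list
    window_ms: float
    step_ms: float
    fs: float

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i):
        return self.windows[i]

    def stack(self) -> np.ndarray:
        """Windows as one (B, N, C) array."""
        return np.stack([w.data for w in self.windows])

    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=int)

    def repetitions(self) -> np.ndarray:
        return np.array([w.repetition for w in self.windows], dtype=int)

    def subjects(self) -> np.ndarray:
        return np.array([w.subject_id for w in self.windows])

    def subset(self, mask) -> "WindowSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return WindowSet(
            windows=[self.windows[i] for i in idx],
            window_ms=self.window_ms,
            step_ms=self.step_ms,
            fs=self.fs,
        )


@dataclass(frozen=True)
class FoldSplit:
    """Disjoint sets of repetition indices used for training and testing."""

    train_repetitions: frozenset
    test_repetitions: frozenset

    def __post_init__(self):
        train = frozenset(self.train_repetitions)
        test = frozenset(self.test_repetitions)
        object.__setattr__(self, "train_repetitions", train)
        object.__setattr__(self, "test_repetitions", test)
        if not train or not test:
            raise ValueError("train and test repetition sets must be nonempty")
        if train & test:
            raise ValueError(f"train/test repetitions overlap: {sorted(train & test)}")


def window_samples(window_ms: float, fs: float) -> int:
    """Window length in samples: round(window_ms * fs / 1000)."""
    return int(round(window_ms * fs / 1000.0))


def segment_windows(
    rec: Recording,
    window_ms: float = 200.0,
    step_ms: float = 10.0,
    exclude_rest: bool = True,
    max_window_ms: float = 200.0,
) -> WindowSet:
    """Segment a recording into label-homogeneous sliding windows.

    Parameters
    ----------
    rec : Recording
        The recording to segment.
    window_ms, step_ms : float
        Window length and hop in milliseconds.  Windows longer than
        ``max_window_ms`` (default 200 ms, the usual real-time budget for
        myoelectric control) raise a warning but are still produced.
    exclude_rest : bool
        Drop windows whose label is 0 (rest).

    Returns
    -------
    WindowSet
        Every window whose samples all share one movement label and one
        repetition index; windows crossing a boundary are discarded.
    """
    if step_ms <= 0:
        raise ValueError(f"step_ms must be positive, got {step_ms}")
    if window_ms > max_window_ms:
        warnings.warn(
            f"window of {window_ms} ms exceeds the {max_window_ms} ms "
            "real-time control budget",
            stacklevel=2,
        )
    N = window_samples(window_ms, rec.fs)
    step = max(1, window_samples(step_ms, rec.fs))
    T = rec.n_samples
    if N < 1:
        raise ValueError(f"window of {window_ms} ms is shorter than one sample")
    out = WindowSet(windows=[], window_ms=window_ms, step_ms=step_ms, fs=rec.fs)
    if N > T:
        warnings.warn(
            f"window length {N} exceeds recording length {T}; no windows emitted",
            stacklevel=2,
        )
        return out
    for start in range(0, T - N + 1, step):
        lab = rec.labels[start : start + N]
        rep = rec.repetitions[start : start + N]
        if lab[0] != lab.min() or lab[0] != lab.max():
            continue
        if rep[0] != rep.min() or rep[0] != rep.max():
            continue
        if exclude_rest and lab[0] == 0:
            continue
        out.windows.append(
            Window(
                data=rec.signals[start : start + N].copy(),
                label=int(lab[0]),
                repetition=int(rep[0]),
                subject_id=rec.subject_id,
            )
        )
    return out


#: Standard repetition presets for the intra-subject protocol.
_SPLIT_PRESETS = {
    10: ({1, 3, 4, 6, 7, 8, 9}, {2, 5, 10}),
    6: ({1, 3, 4, 6}, {2, 5}),
}


def make_intra_subject_split(
    num_repetitions: int,
    train_repetitions=None,
    test_repetitions=None,
) -> FoldSplit:
    """Repetition-wise train/test split for intra-subject evaluation.

    The two standard protocols are built in: 10 repetitions split as
    train {1,3,4,6,7,8,9} / test {2,5,10}, and 6 repetitions split as
    train {1,3,4,6} / test {2,5} (roughly 2/3 of repetitions for
    training).  Any other repetition count requires explicit lists.
    """
    if train_repetitions is not None or test_repetitions is not None:
        if train_repetitions is None or test_repetitions is None:
            raise ValueError("supply both train_repetitions and test_repetitions")
        return FoldSplit(frozenset(train_repetitions), frozenset(test_repetitions))
    if num_repetitions not in _SPLIT_PRESETS:
        raise ValueError(
            f"no preset split for {num_repetitions} repetitions; "
            "supply explicit train/test repetition lists"
        )
    train, test = _SPLIT_PRESETS[num_repetitions]
    return FoldSplit(frozenset(train), frozenset(test))


def split_windows(windows: WindowSet, split: FoldSplit):
    """Partition a WindowSet into (train, test) by repetition index."""
    reps = windows.repetitions()
    train_mask = np.isin(reps, sorted(split.train_repetitions))
    test_mask = np.isin(reps, sorted(split.test_repetitions))
    return windows.subset(train_mask), windows.subset(test_mask)
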