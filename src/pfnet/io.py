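"""Reading, writing and resampling multichannel sEMG recordings.

The native on-disk format is a delimited-text matrix with one sample per
row and a header ``ch1,...,chC,label,repetition``, plus a key-value sidecar
metadata file supplying the sampling rate and subject identifier.  A
label of 0 marks rest; every non-rest sample must carry a positive
repetition index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class RecordingError(ValueError):
    """Malformed recording file or inconsistent label/repetition tracks."""


@dataclass
class Recording:
    """One subject's multichannel sEMG with per-sample annotations.

    Attributes
    ----------
    signals : ndarray of shape (T, C)
        Per-channel time series in arbitrary units.
    fs : float
        Sampling rate in Hz.
    labels : ndarray of shape (T,)
        Movement id per sample; 0 denotes rest.
    repetitions : ndarray of shape (T,)
        1-based repetition index per sample; 0 for rest/none.
    subject_id : str
        Subject identifier.
    channel_names : list of str, optional
        Defaults to ``ch1..chC``.
    """

    signals: np.ndarray
    fs: float
    labels: np.ndarray
    repetitions: np.ndarray
    subject_id: str
    channel_names: list = field(default=None)

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.repetitions = np.asarray(self.repetitions, dtype=int)
        if self.signals.ndim != 2:
            raise RecordingError("signals must be a T x C matrix")
        T, C = self.signals.shape
        if C < 2:
            raise RecordingError(f"need at least 2 channels, got {C}")
        if self.fs <= 0:
            raise RecordingError(f"sampling rate must be positive, got {self.fs}")
        if len(self.labels) != T or len(self.repetitions) != T:
            raise RecordingError(
                "signals, labels and repetitions must share length "
                f"(T={T}, labels={len(self.labels)}, repetitions={len(self.repetitions)})"
            )
        bad = np.flatnonzero((self.labels != 0) & (self.repetitions == 0))
        if bad.size:
            raise RecordingError(
                f"sample {bad[0]} is labeled (movement {self.labels[bad[0]]}) "
                "but has repetition index 0"
            )
        if self.channel_names is None:
            self.channel_names = [f"ch{i + 1}" for i in range(C)]
        elif len(self.channel_names) != C:
            raise RecordingError("channel_names length must equal channel count")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]


def _read_metadata(metadata_path) -> dict:
    meta = {}
    for lineno, line in enumerate(Path(metadata_path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" in line:
            key, _, val = line.partition("=")
        elif ":" in line:
            key, _, val = line.partition(":")
        else:
            raise RecordingError(
                f"{metadata_path}: line {lineno}: expected 'key = value', got {line!r}"
            )
        meta[key.strip()] = val.strip()
    return meta


def load_recording(path, metadata_path=None) -> Recording:
    """Load a recording from delimited text plus its metadata sidecar.

    ``metadata_path`` defaults to ``<path stem>.meta`` next to the data file.
    The data file must have columns ``ch1..chC,label,repetition``; ragged or
    non-numeric rows are rejected with the offending line named.
    """
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_suffix(".meta")
    meta = _read_metadata(metadata_path)
    if "fs" not in meta:
        raise RecordingError(f"{metadata_path}: missing required key 'fs'")
    fs = float(meta["fs"])
    subject_id = meta.get("subject_id", path.stem)

    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise RecordingError(f"{path}: malformed delimited text: {exc}") from exc
    cols = list(frame.columns)
    if len(cols) < 4 or cols[-2] != "label" or cols[-1] != "repetition":
        raise RecordingError(
            f"{path}: expected header 'ch1..chC,label,repetition', got {cols}"
        )
    frame = frame.apply(pd.to_numeric, errors="coerce")
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax())
        raise RecordingError(f"{path}: ragged or non-numeric row at data line {row + 1}")
    return Recording(
        signals=frame.iloc[:, :-2].to_numpy(dtype=float),
        fs=fs,
        labels=frame["label"].to_numpy(dtype=int),
        repetitions=frame["repetition"].to_numpy(dtype=int),
        subject_id=str(subject_id),
        channel_names=cols[:-2],
    )


def write_recording(rec: Recording, path, metadata_path=None) -> None:
    """Write a recording in the native delimited-text format plus sidecar."""
    path = Path(path)
    if metadata_path is None:
        metadata_path = path.with_suffix(".meta")
    frame = pd.DataFrame(rec.signals, columns=rec.channel_names)
    frame["label"] = rec.labels
    frame["repetition"] = rec.repetitions
    frame.to_csv(path, index=False)
    Path(metadata_path).write_text(
        f"fs = {rec.fs:g}\nsubject_id = {rec.subject_id}\n"
    )


def downsample(rec: Recording, target_fs: float, antialias: bool = False) -> Recording:
    """Decimate a recording to ``target_fs`` by keeping every k-th sample.

    The default is plain decimation (no anti-alias filter) so the label and
    repetition tracks stay exactly aligned with the signal; the stride
    k = fs/target_fs must be a whole number.  With ``antialias=True`` an
    order-8 Chebyshev low-pass is applied to the signals before decimation
    (labels and repetitions are still decimated directly).
    """
    ratio = rec.fs / target_fs
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise RecordingError(
            f"sampling rate {rec.fs} Hz is not an integer multiple of {target_fs} Hz"
        )
    if k == 1:
        return rec
    if antialias:
        from scipy.signal import decimate as _decimate

        signals = _decimate(rec.signals, k, axis=0, zero_phase=True)
    else:
        signals = rec.signals[::k]
    return Recording(
        signals=signals,
        fs=target_fs,
        labels=rec.labels[::k],
        repetitions=rec.repetitions[::k],
        subject_id=rec.subject_id,
        channel_names=list(rec.channel_names),
    )
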