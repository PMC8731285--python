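"""Seeded synthetic sEMG generator for desk-scale experiments.

Real surface EMG during a held movement is well approximated by
amplitude-modulated colored noise: each movement class activates the
electrode channels with a characteristic per-channel amplitude pattern,
and the interference pattern has a class- and muscle-dependent spectral
shape.  The generator emulates exactly the structure the classifier
exploits:

* **per-channel amplitudes** — for movement m and channel c an amplitude
  ``a[m, c] = exp(amplitude_separability * z[m, c])`` with standard
  normal ``z`` drawn once per dataset, i.e. log-normal around 1; at
  ``amplitude_separability = 0`` every class has unit amplitude on every
  channel;
* **class-dependent spectra** — each movement's signal is white Gaussian
  noise shaped by an AR(2) filter whose resonant frequency is spread
  across classes in proportion to ``spectral_separability`` (at 0, all
  classes share one resonance), which makes the wavelet-packet sub-band
  energy profile class-discriminative;
* **repetition structure** — each movement is repeated
  ``num_repetitions`` times with rest gaps (label 0, repetition 0) of
  white noise at ``noise_floor`` amplitude between repetitions.

At zero separability on both axes the classes are statistically
exchangeable and any classifier is reduced to chance.  Everything is
driven by one integer seed; identical configs reproduce bit-identical
recordings.

Not modeled: motor-unit action potentials, electrode drift, amputation-
related signal degradation, or force-level variation within a class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .io import Recording, write_recording

#: AR(2) pole radius; close to the unit circle for a pronounced resonance.
AR_POLE_RADIUS = 0.9
#: Central resonance angle (rad); pi/2 is fs/4, i.e. 25 Hz at 100 Hz.
AR_CENTER_ANGLE = 0.5 * np.pi
#: Full spread of resonance angles across classes at separability 1.
AR_ANGLE_SPREAD = 0.8 * np.pi


@dataclass
class SyntheticConfig:
    """Layout and statistics of one synthetic dataset."""

    num_subjects: int = 2
    num_movements: int = 5
    num_repetitions: int = 6
    channels: int = 8
    fs: float = 100.0
    movement_duration_s: float = 3.0
    rest_duration_s: float = 1.0
    amplitude_separability: float = 1.0
    spectral_separability: float = 1.0
    noise_floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.movement_duration_s <= 0 or self.rest_duration_s < 0:
            raise ValueError("durations must be positive")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.channels < 2:
            raise ValueError("need at least 2 channels")
        if min(self.num_subjects, self.num_movements, self.num_repetitions) < 1:
            raise ValueError("need at least one subject, movement and repetition")

    def to_dict(self) -> dict:
        return asdict(self)


def class_ar_angle(cfg: SyntheticConfig, movement: int) -> float:
    """Resonance angle (rad in (0, pi)) of a movement's AR(2) profile."""
    m, M = movement, cfg.num_movements
    if M == 1:
        offset = 0.0
    else:
        offset = ((m - 1) / (M - 1) - 0.5) * AR_ANGLE_SPREAD
    return AR_CENTER_ANGLE + cfg.spectral_separability * offset


def class_ar_coefficients(cfg: SyntheticConfig, movement: int) -> np.ndarray:
    """Denominator [1, a1, a2] of the movement's AR(2) transfer function."""
    theta = class_ar_angle(cfg, movement)
    r = AR_POLE_RADIUS
    return np.array([1.0, -2.0 * r * np.cos(theta), r * r])


def class_power_spectrum(cfg: SyntheticConfig, movement: int, freqs) -> np.ndarray:
    """Theoretical AR(2) power spectral density (unit-variance drive) at
    ``freqs`` in Hz; the oracle for periodogram checks."""
    w = 2.0 * np.pi * np.asarray(freqs, dtype=float) / cfg.fs
    a = class_ar_coefficients(cfg, movement)
    z = np.exp(-1j * w)
    denom = a[0] + a[1] * z + a[2] * z * z
    return 1.0 / (np.abs(denom) ** 2 * cfg.fs)


def class_amplitudes(cfg: SyntheticConfig) -> np.ndarray:
    """Per-(movement, channel) amplitude matrix, shared across subjects.

    Drawn once from the dataset seed so pooled pre-training sees one
    consistent class structure.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    z = rng.standard_normal((cfg.num_movements, cfg.channels))
    return np.exp(cfg.amplitude_separability * z)


def generate_recording(cfg: SyntheticConfig, subject_index: int) -> Recording:
    """One subject's recording: every movement repeated with rest gaps.

    Layout per movement m = 1..num_movements: repetitions 1..R of
    ``movement_duration_s`` of class-shaped noise, separated (and led)
    by ``rest_duration_s`` of white noise at the noise floor.
    """
    if not 0 <= subject_index < cfg.num_subjects:
        raise ValueError(
            f"subject_index must lie in [0, {cfg.num_subjects}), got {subject_index}"
        )
    amps = class_amplitudes(cfg)
    rng = np.random.default_rng([cfg.seed, 2, subject_index])
    n_mov = int(round(cfg.movement_duration_s * cfg.fs))
    n_rest = int(round(cfg.rest_duration_s * cfg.fs))
    C = cfg.channels

    sig_parts, lab_parts, rep_parts = [], [], []

    def rest():
        if n_rest == 0:
            return
        sig_parts.append(cfg.noise_floor * rng.standard_normal((n_rest, C)))
        lab_parts.append(np.zeros(n_rest, dtype=int))
        rep_parts.append(np.zeros(n_rest, dtype=int))

    rest()
    for m in range(1, cfg.num_movements + 1):
        a_coef = class_ar_coefficients(cfg, m)
        for rep in range(1, cfg.num_repetitions + 1):
            drive = rng.standard_normal((n_mov, C))
            shaped = sps.lfilter([1.0], a_coef, drive, axis=0)
            seg = shaped * amps[m - 1] + cfg.noise_floor * rng.standard_normal((n_mov, C))
            sig_parts.append(seg)
            lab_parts.append(np.full(n_mov, m, dtype=int))
            rep_parts.append(np.full(n_mov, rep, dtype=int))
            rest()

    return Recording(
        signals=np.concatenate(sig_parts),
        fs=cfg.fs,
        labels=np.concatenate(lab_parts),
        repetitions=np.concatenate(rep_parts),
        subject_id=f"s{subject_index + 1:02d}",
    )


def generate_recordings(cfg: SyntheticConfig) -> dict:
    """All subjects' recordings, keyed by subject id."""
    recs = [generate_recording(cfg, i) for i in range(cfg.num_subjects)]
    return {rec.subject_id: rec for rec in recs}


def generate_dataset(cfg: SyntheticConfig, out_dir) -> dict:
    """Write one recording per subject in the native delimited-text format
    plus a JSON manifest (files, seed, full config).  Returns the
    manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i in range(cfg.num_subjects):
        rec = generate_recording(cfg, i)
        name = f"{rec.subject_id}.csv"
        write_recording(rec, out_dir / name)
        files.append(name)
    manifest = {"config": cfg.to_dict(), "seed": cfg.seed, "files": files}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
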