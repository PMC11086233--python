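"""Seeded generator of ECG-like labeled signals with class-dependent morphology.

Each class is a sum of Gaussian bumps standing in for the P wave, QRS complex
and T wave, with class-specific centres, widths and amplitudes, plus additive
white noise and slow sinusoidal baseline wander.  This is not a physiological
simulator — it exists to give every other module labeled, reproducible,
class-separable 1-D signals with the right shapes (fixed-length single-lead
beats, and variable-length multi-lead records) without any download.

Class templates are drawn once per generator call from a seeded RNG, spread
apart in parameter space so classes are linearly separable at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg_data import ECGDataset, ECGRecord, STANDARD_12_LEADS


@dataclass
class Bump:
    center: float  # fraction of beat in (0, 1)
    width: float   # fraction of beat, > 0
    amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("bump width must be positive")


@dataclass
class MorphologySpec:
    """Per-class bump templates plus noise levels.

    ``noise_sd`` is the per-sample white-noise standard deviation (unitless,
    relative to unit QRS amplitude); ``baseline_wander_amp`` scales a slow
    sinusoid emulating respiration drift.
    """

    class_bumps: list[list[Bump]] = field(default_factory=list)
    noise_sd: float = 0.05
    baseline_wander_amp: float = 0.05

    def __post_init__(self):
        if any(len(bumps) == 0 for bumps in self.class_bumps):
            raise ValueError("every class needs at least one bump")
        keys = [tuple((b.center, b.width, b.amplitude) for b in bumps)
                for bumps in self.class_bumps]
        if len(set(keys)) != len(keys):
            raise ValueError("classes must have pairwise-distinct bump parameters")

    @property
    def n_classes(self) -> int:
        return len(self.class_bumps)


def default_spec(n_classes: int, seed: int = 0, noise_sd: float = 0.05,
                 baseline_wander_amp: float = 0.05) -> MorphologySpec:
    """Draw distinct P/QRS/T-like templates for ``n_classes`` classes.

    The QRS-like bump is narrow and dominant; the P- and T-like bumps are
    broader and smaller.  Centres and amplitudes are jittered per class from
    evenly spaced anchors so templates are distinct and well separated.
    """
    if n_classes < 1:
        raise ValueError("need at least one class")
    rng = np.random.default_rng(seed)
    classes = []
    for c in range(n_classes):
        u = (c + 0.5) / n_classes
        qrs_center = 0.30 + 0.40 * u + rng.uniform(-0.02, 0.02)
        qrs_amp = 1.0 - 0.5 * u + rng.uniform(-0.05, 0.05)
        classes.append([
            Bump(center=qrs_center - 0.18, width=0.05, amplitude=0.20 + 0.1 * u),
            Bump(center=qrs_center, width=0.015 + 0.01 * u, amplitude=qrs_amp),
            Bump(center=qrs_center + 0.20, width=0.07, amplitude=0.35 - 0.2 * u),
        ])
    return MorphologySpec(classes, noise_sd=noise_sd,
                          baseline_wander_amp=baseline_wander_amp)


def class_template(spec: MorphologySpec, cls: int, length: int) -> np.ndarray:
    """Noise-free waveform for one class at a given length."""
    t = np.linspace(0.0, 1.0, length)
    wave = np.zeros(length)
    for bump in spec.class_bumps[cls]:
        wave += bump.amplitude * np.exp(-0.5 * ((t - bump.center) / bump.width) ** 2)
    return wave


def _finalize(wave: np.ndarray) -> np.ndarray:
    peak = np.abs(wave).max()
    return wave / peak if peak > 1.0 else wave


def generate_beats(n_per_class: int, n_classes: int, length: int = 187,
                   spec: MorphologySpec | None = None, seed: int = 0,
                   sampling_rate: float = 125.0, split: str = "train") -> ECGDataset:
    """Fixed-length single-lead beats, ``n_per_class`` records per class."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if length < 16:
        raise ValueError("length must be >= 16")
    if spec is None:
        spec = default_spec(n_classes, seed=seed)
    if spec.n_classes != n_classes:
        raise ValueError("spec class count does not match n_classes")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, length)
    records = []
    for cls in range(n_classes):
        template = class_template(spec, cls, length)
        for _ in range(n_per_class):
            wave = template + rng.normal(0.0, spec.noise_sd, size=length)
            if spec.baseline_wander_amp > 0:
                phase = rng.uniform(0, 2 * np.pi)
                wave = wave + spec.baseline_wander_amp * np.sin(2 * np.pi * t + phase)
            records.append(
                ECGRecord(signal=_finalize(wave)[None, :], label=cls,
                          sampling_rate=sampling_rate)
            )
    class_names = [f"class{i}" for i in range(n_classes)]
    return ECGDataset(records, class_names, split)


def generate_multilead(n_per_class: int, n_classes: int, leads: int = 12,
                       seconds_range: tuple[float, float] = (6.0, 60.0),
                       fs: float = 500.0, spec: MorphologySpec | None = None,
                       seed: int = 0, beat_rate_hz: float = 1.2,
                       split: str = "train") -> ECGDataset:
    """Variable-length multi-lead records with per-lead amplitude scalings.

    Durations are uniform over ``seconds_range``; each record repeats the
    class beat template at ``beat_rate_hz`` and applies a fixed per-lead
    gain pattern (drawn per class) so leads are correlated but not equal.
    """
    lo, hi = seconds_range
    if lo > hi:
        raise ValueError("seconds_range must satisfy lo <= hi")
    if leads < 1:
        raise ValueError("need at least one lead")
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if spec is None:
        spec = default_spec(n_classes, seed=seed)
    if spec.n_classes != n_classes:
        raise ValueError("spec class count does not match n_classes")
    rng = np.random.default_rng(seed)
    beat_len = max(int(round(fs / beat_rate_hz)), 16)
    lead_names = (STANDARD_12_LEADS if leads == 12
                  else [f"lead{i}" for i in range(leads)])
    # per-class per-lead gains, fixed across records of the class
    gains = 0.4 + rng.uniform(0.0, 1.0, size=(n_classes, leads))
    gains *= np.where(rng.uniform(size=(n_classes, leads)) < 0.25, -1.0, 1.0)
    records = []
    for cls in range(n_classes):
        beat = class_template(spec, cls, beat_len)
        for _ in range(n_per_class):
            seconds = rng.uniform(lo, hi)
            n_samples = int(round(seconds * fs))
            reps = int(np.ceil(n_samples / beat_len))
            base = np.tile(beat, reps)[:n_samples]
            sig = gains[cls][:, None] * base[None, :]
            sig = sig + rng.normal(0.0, spec.noise_sd, size=sig.shape)
            if spec.baseline_wander_amp > 0:
                tt = np.arange(n_samples) / fs
                phases = rng.uniform(0, 2 * np.pi, size=leads)
                sig = sig + spec.baseline_wander_amp * np.sin(
                    2 * np.pi * 0.25 * tt[None, :] + phases[:, None]
                )
            records.append(
                ECGRecord(signal=sig, label=cls, sampling_rate=fs,
                          lead_names=list(lead_names))
            )
    class_names = [f"class{i}" for i in range(n_classes)]
    return ECGDataset(records, class_names, split)
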