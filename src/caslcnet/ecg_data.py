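"""ECG data containers, readers/writers, and the preprocessing pipeline.

Two dataset styles are supported:

* **beats** — fixed-length single-lead heartbeats (the public five-class
  arrhythmia beat layout: one beat per CSV row, samples then an integer
  label);
* **multilead** — variable-length 12-lead records (6–60 s at 500 Hz, nine
  rhythm classes) which are zero-padded to a common length, reduced to the
  eight informative leads (V3–V6 are linear combinations of the others and
  are dropped), and per-lead max-abs normalised into [−1, 1].

Preprocessing steps: symmetric zero padding / front truncation to a target
duration, lead selection, per-lead max-abs normalisation over the valid
region, and class rebalancing by seeded oversampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

STANDARD_12_LEADS = [
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
]
DERIVABLE_LEADS = ["V3", "V4", "V5", "V6"]


class ConfigurationError(ValueError):
    """Raised for invalid preprocessing configuration."""


class ParseError(ValueError):
    """Raised when an on-disk dataset is malformed."""


@dataclass
class ECGRecord:
    """A labeled multi-lead signal with a validity mask.

    ``signal`` is [leads, samples]; entries at index >= ``valid_length`` are
    padding and are exactly zero after :func:`pad_or_truncate`.
    """

    signal: np.ndarray
    label: int
    sampling_rate: float
    valid_length: int | None = None
    pad_left: int = 0
    lead_names: list[str] | None = None

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=np.float64))
        if self.valid_length is None:
            self.valid_length = self.signal.shape[1]
        if self.valid_length < 1:
            raise ValueError("record must have positive valid_length")
        if self.lead_names is None:
            self.lead_names = [f"lead{i}" for i in range(self.signal.shape[0])]

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def valid_mask(self) -> np.ndarray:
        """Binary [samples] mask, 1 on the observed region."""
        m = np.zeros(self.n_samples)
        m[self.pad_left : self.pad_left + self.valid_length] = 1.0
        return m


@dataclass
class ECGDataset:
    records: list[ECGRecord]
    class_names: list[str]
    split: str = "train"

    def __post_init__(self):
        if self.records:
            leads = {r.n_leads for r in self.records}
            rates = {r.sampling_rate for r in self.records}
            if len(leads) != 1 or len(rates) != 1:
                raise ValueError("all records must share lead count and sampling rate")
            m = len(self.class_names)
            bad = [r.label for r in self.records if not 0 <= r.label < m]
            if bad:
                raise ValueError(f"labels out of range [0, {m}): {sorted(set(bad))}")

    def __len__(self):
        return len(self.records)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.intp)

    def signals(self) -> np.ndarray:
        """Stacked [N, leads, samples] array (records must share length)."""
        lengths = {r.n_samples for r in self.records}
        if len(lengths) > 1:
            raise ValueError("records have unequal lengths; pad first")
        return np.stack([r.signal for r in self.records])

    def masks(self) -> np.ndarray:
        return np.stack([r.valid_mask() for r in self.records])

    def map(self, fn) -> "ECGDataset":
        return ECGDataset([fn(r) for r in self.records], list(self.class_names), self.split)


@dataclass
class PreprocessConfig:
    target_seconds: float = 60.0
    drop_leads: list[str] = field(default_factory=lambda: list(DERIVABLE_LEADS))
    normalize: bool = True
    balance: bool = True
    balance_test: bool = True  # beats-style protocol rebalances the test split too
    seed: int = 0

    def __post_init__(self):
        if self.target_seconds <= 0:
            raise ConfigurationError("target_seconds must be positive")


# ---------------------------------------------------------------------------
# operations


def pad_or_truncate(record: ECGRecord, target_seconds: float) -> ECGRecord:
    """Fix a record's duration: zero-pad symmetrically or keep the leading span.

    Shorter records receive equal zero padding at both ends (the odd extra
    sample goes on the right); longer records keep only the first
    ``target_seconds``.
    """
    if target_seconds <= 0:
        raise ConfigurationError("target_seconds must be positive")
    target = int(round(target_seconds * record.sampling_rate))
    n = record.n_samples
    if n == target:
        return record
    if n > target:
        return replace(
            record,
            signal=record.signal[:, :target].copy(),
            valid_length=min(record.valid_length, target),
            pad_left=0,
        )
    deficit = target - n
    left = deficit // 2
    right = deficit - left
    padded = np.pad(record.signal, ((0, 0), (left, right)))
    return replace(
        record,
        signal=padded,
        valid_length=record.valid_length,
        pad_left=record.pad_left + left,
    )


def select_leads(record: ECGRecord, drop: list[str]) -> ECGRecord:
    """Remove named leads (e.g. the derivable chest leads V3–V6)."""
    if not drop:
        return record
    unknown = [name for name in drop if name not in record.lead_names]
    if unknown:
        raise KeyError(
            f"unknown lead(s) {unknown}; record has leads {record.lead_names}"
        )
    keep = [i for i, name in enumerate(record.lead_names) if name not in drop]
    return replace(
        record,
        signal=record.signal[keep].copy(),
        lead_names=[record.lead_names[i] for i in keep],
    )


def normalize_leads(record: ECGRecord) -> ECGRecord:
    """Scale each lead into [−1, 1] by its own max absolute value.

    The maximum is taken over the valid (pre-padding) region only, so padded
    zeros neither shift the scale nor stop being zero.  An all-zero lead is
    left unchanged with a warning.
    """
    sl = slice(record.pad_left, record.pad_left + record.valid_length)
    scales = np.abs(record.signal[:, sl]).max(axis=1)
    zero = scales == 0
    if zero.any():
        warnings.warn(
            f"lead(s) {[record.lead_names[i] for i in np.flatnonzero(zero)]} are "
            "all zero over the valid region; left unnormalized",
            RuntimeWarning,
            stacklevel=2,
        )
        scales = np.where(zero, 1.0, scales)
    return replace(record, signal=record.signal / scales[:, None])


def balance_classes(dataset: ECGDataset, seed: int) -> ECGDataset:
    """Equalise class counts by oversampling with replacement (seeded).

    Every original record is retained; each minority class is topped up to
    the majority count by sampling its own records with replacement.
    """
    labels = dataset.labels()
    counts = np.bincount(labels, minlength=dataset.n_classes)
    if (counts == 0).any():
        empty = [dataset.class_names[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"cannot balance: empty class(es) {empty}")
    target = counts.max()
    rng = np.random.default_rng(seed)
    records = list(dataset.records)
    for cls in range(dataset.n_classes):
        idx = np.flatnonzero(labels == cls)
        deficit = target - len(idx)
        if deficit > 0:
            extra = rng.choice(idx, size=deficit, replace=True)
            records.extend(dataset.records[i] for i in extra)
    return ECGDataset(records, list(dataset.class_names), dataset.split)


def preprocess(dataset: ECGDataset, config: PreprocessConfig) -> ECGDataset:
    """Run the full pipeline: pad/truncate, drop leads, normalise, balance."""
    drop = [d for d in config.drop_leads if d in (dataset.records[0].lead_names or [])]

    def per_record(r: ECGRecord) -> ECGRecord:
        r = select_leads(r, drop)
        if config.normalize:
            r = normalize_leads(r)
        return pad_or_truncate(r, config.target_seconds)

    out = dataset.map(per_record)
    if config.balance and (dataset.split == "train" or config.balance_test):
        out = balance_classes(out, config.seed)
    return out


# ---------------------------------------------------------------------------
# readers / writers


def read_beats_csv(path, class_names: list[str] | None = None,
                   sampling_rate: float = 125.0, split: str = "train") -> ECGDataset:
    """Read fixed-length single-lead beats: N sample columns + integer label."""
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if width is None:
                width = len(parts)
                if width < 2:
                    raise ParseError(f"row {lineno}: need at least one sample and a label")
            elif len(parts) != width:
                raise ParseError(
                    f"row {lineno}: expected {width} columns, got {len(parts)}"
                )
            try:
                samples = np.array(parts[:-1], dtype=np.float64)
                raw_label = float(parts[-1])
            except ValueError as exc:
                raise ParseError(f"row {lineno}: {exc}") from None
            label = int(raw_label)
            if label != raw_label:
                raise ParseError(f"row {lineno}: non-integer label {parts[-1]!r}")
            rows.append((samples, label))
    if not rows:
        raise ParseError(f"{path}: empty dataset")
    m = max(label for _, label in rows) + 1
    if class_names is None:
        class_names = [f"class{i}" for i in range(m)]
    records = [
        ECGRecord(signal=s[None, :], label=lab, sampling_rate=sampling_rate)
        for s, lab in rows
    ]
    return ECGDataset(records, class_names, split)


def write_beats_csv(dataset: ECGDataset, path):
    with open(path, "w") as fh:
        for r in dataset.records:
            if r.n_leads != 1:
                raise ValueError("beats CSV format is single-lead")
            fh.write(",".join(repr(float(v)) for v in r.signal[0]) + f",{r.label}\n")


def write_archive(dataset: ECGDataset, path):
    """Write a multi-lead dataset to an .npz archive (padded to max length)."""
    max_len = max(r.n_samples for r in dataset.records)
    n = len(dataset.records)
    leads = dataset.records[0].n_leads
    signals = np.zeros((n, leads, max_len))
    valid = np.empty(n, dtype=np.int64)
    pad_left = np.empty(n, dtype=np.int64)
    for i, r in enumerate(dataset.records):
        signals[i, :, : r.n_samples] = r.signal
        valid[i] = r.valid_length
        pad_left[i] = r.pad_left
    np.savez(
        path,
        signals=signals,
        labels=dataset.labels(),
        valid_lengths=valid,
        pad_left=pad_left,
        fs=dataset.records[0].sampling_rate,
        class_names=np.array(dataset.class_names),
        lead_names=np.array(dataset.records[0].lead_names),
        split=np.array(dataset.split),
    )


def read_archive(path) -> ECGDataset:
    with np.load(path, allow_pickle=False) as z:
        fs = float(z["fs"])
        lead_names = [str(s) for s in z["lead_names"]]
        records = [
            ECGRecord(
                signal=sig,
                label=int(lab),
                sampling_rate=fs,
                valid_length=int(v),
                pad_left=int(pl),
                lead_names=list(lead_names),
            )
            for sig, lab, v, pl in zip(
                z["signals"], z["labels"], z["valid_lengths"], z["pad_left"]
            )
        ]
        return ECGDataset(records, [str(s) for s in z["class_names"]], str(z["split"]))
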