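"""Robustness metrics, attack-sweep evaluation, and channel activation analysis.

The headline robustness summaries are

    ACC_robust = ACC_clean * AUC,    F1_robust = F1_clean * AUC,

where ACC_clean (F1_clean) is the clean test metric as a fraction and AUC is
the trapezoidal area under the metric-versus-perturbation curve over
[0, eps_max], normalised by eps_max, so both factors live in [0, 1].  The
sweep protocol evaluates accuracy and macro-F1 at each point of an
ascending epsilon grid whose first entry is 0 (the clean point); iterated
attacks default to 100 iterations with step size eps/10.  For the smoothed
attack (SAP), whose natural sweep axis is the Gaussian kernel (size, sigma)
grid rather than epsilon, the rank index of the grid entry serves as a
unitless abscissa for the area computation.

The channel analysis mirrors the activation-suppression diagnostics: for a
batch of natural and adversarial inputs it reports per-channel mean pooled
activation magnitude and activation frequency — a channel counts as active
on a sample when its pooled activation exceeds ``threshold_frac`` times the
sample's maximum activation over channels (a batch-global reference is
available behind a flag) — ordered by descending natural frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.metrics import f1_score

from .attacks import AttackConfig, get_attack
from .ecg_data import ECGDataset

__all__ = [
    "RobustnessCurve",
    "ChannelStats",
    "evaluate_curve",
    "acc_robust",
    "f1_robust",
    "channel_stats",
]

# default activation-threshold fractions per dataset style
THRESHOLD_FRAC_BEATS = 0.20
THRESHOLD_FRAC_MULTILEAD = 0.70


@dataclass
class RobustnessCurve:
    eps_grid: np.ndarray
    accuracy: np.ndarray
    f1: np.ndarray
    attack: str = "pgd"
    sap_grid: list | None = None      # list of (s, sigma) when attack == "sap"

    def __post_init__(self):
        self.eps_grid = np.asarray(self.eps_grid, dtype=float)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        self.f1 = np.asarray(self.f1, dtype=float)
        if not (len(self.eps_grid) == len(self.accuracy) == len(self.f1)):
            raise ValueError("grid and metric lists must have equal length")
        if np.any(np.diff(self.eps_grid) <= 0):
            raise ValueError("eps grid must be strictly ascending")
        for name, vals in (("accuracy", self.accuracy), ("f1", self.f1)):
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"{name} values must lie in [0, 1]")


@dataclass
class ChannelStats:
    magnitude_natural: np.ndarray
    magnitude_adversarial: np.ndarray
    frequency_natural: np.ndarray
    frequency_adversarial: np.ndarray
    threshold_frac: float
    order: np.ndarray                  # channels sorted by descending natural freq


def _normalized_auc(grid: np.ndarray, values: np.ndarray) -> float:
    if len(grid) < 2:
        raise ValueError("need at least two curve points to integrate")
    span = grid[-1] - grid[0]
    return float(np.trapezoid(values, grid) / span)


def acc_robust(curve: RobustnessCurve) -> float:
    """Clean accuracy times the normalised area under the accuracy curve."""
    return curve.accuracy[0] * _normalized_auc(curve.eps_grid, curve.accuracy)


def f1_robust(curve: RobustnessCurve) -> float:
    """Clean macro-F1 times the normalised area under the F1 curve."""
    return curve.f1[0] * _normalized_auc(curve.eps_grid, curve.f1)


def _metrics(model, x, y, masks, n_classes) -> tuple[float, float]:
    pred = model.predict(x, mask=masks) if masks is not None else model.predict(x)
    acc = float((pred == y).mean())
    f1 = float(f1_score(y, pred, labels=np.arange(n_classes),
                        average="macro", zero_division=0))
    return acc, f1


def evaluate_curve(model, dataset: ECGDataset, attack_name: str,
                   eps_grid, protocol: AttackConfig | None = None,
                   sap_grid: list | None = None) -> RobustnessCurve:
    """Sweep an attack over an epsilon grid (or an (s, sigma) grid for SAP).

    ``eps_grid`` must start at 0; the 0 entry is the clean metric.  The
    protocol defaults to 100 iterations at step eps/10 with the random start
    disabled (so sweeps are deterministic and comparable across epsilons).
    For SAP, provide ``sap_grid`` as a list of (s, sigma) pairs; the sweep
    holds epsilon fixed at the protocol value and varies the kernel, and the
    returned curve's abscissa is the normalised rank index.
    """
    attack = get_attack(attack_name)
    base = protocol or AttackConfig(steps=100, random_start=False)
    x = dataset.signals()
    y = dataset.labels()
    style = getattr(getattr(model, "config", None), "dataset_style", "beats")
    masks = dataset.masks() if style == "multilead" else None
    m = dataset.n_classes

    if attack_name == "sap" and sap_grid is not None:
        accs, f1s = [], []
        clean_acc, clean_f1 = _metrics(model, x, y, masks, m)
        accs.append(clean_acc)
        f1s.append(clean_f1)
        for s, sigma in sap_grid:
            cfg = replace(base, sap_kernel=(int(s), float(sigma)))
            res = attack(model, x, y, cfg, mask=masks)
            a, f = _metrics(model, res.x_adv, y, masks, m)
            accs.append(a)
            f1s.append(f)
        axis = np.arange(len(sap_grid) + 1, dtype=float) / max(len(sap_grid), 1)
        return RobustnessCurve(axis, accs, f1s, attack="sap", sap_grid=list(sap_grid))

    eps_grid = np.asarray(eps_grid, dtype=float)
    if eps_grid[0] != 0:
        raise ValueError("eps grid must start at 0 (the clean point)")
    accs, f1s = [], []
    for eps in eps_grid:
        if eps == 0:
            a, f = _metrics(model, x, y, masks, m)
        else:
            cfg = replace(base, epsilon=float(eps),
                          step_size=(None if base.step_size is None else base.step_size))
            res = attack(model, x, y, cfg, mask=masks)
            a, f = _metrics(model, res.x_adv, y, masks, m)
        accs.append(a)
        f1s.append(f)
    return RobustnessCurve(eps_grid, accs, f1s, attack=attack_name)


def channel_stats(model, natural_batch, adversarial_batch,
                  threshold_frac: float = THRESHOLD_FRAC_BEATS,
                  masks=None, batch_global: bool = False) -> ChannelStats:
    """Per-channel pooled activation magnitude and activation frequency.

    Activations are taken at the final feature-extraction layer (pooled over
    the valid temporal extent).  ``batch_global=True`` references the
    activation threshold to the batch-wide maximum instead of each sample's
    own maximum across channels.
    """
    nat = np.asarray(natural_batch, dtype=np.float64)
    adv = np.asarray(adversarial_batch, dtype=np.float64)
    if nat.shape != adv.shape:
        raise ValueError("natural and adversarial batches must share shape")
    if nat.shape[0] == 0:
        raise ValueError("empty batch")
    was_training = model.training
    model.eval()
    try:
        pooled_nat = model.pooled_features(nat, mask=masks).data
        pooled_adv = model.pooled_features(adv, mask=masks).data
    finally:
        if was_training:
            model.train()

    def freq(pooled):
        if batch_global:
            ref = pooled.max()
            return (pooled > threshold_frac * ref).mean(axis=0)
        ref = pooled.max(axis=1, keepdims=True)
        return (pooled > threshold_frac * ref).mean(axis=0)

    f_nat = freq(pooled_nat)
    f_adv = freq(pooled_adv)
    order = np.argsort(-f_nat, kind="stable")
    return ChannelStats(
        magnitude_natural=pooled_nat.mean(axis=0),
        magnitude_adversarial=pooled_adv.mean(axis=0),
        frequency_natural=f_nat,
        frequency_adversarial=f_adv,
        threshold_frac=threshold_frac,
        order=order,
    )
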