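"""Training objectives and the adversarial-training loop.

Objectives (all operate on probability tensors; ``y`` are integer labels):

* ``ce_loss``      — plain cross-entropy (natural training baseline);
* ``at_loss``      — cross-entropy on adversarial examples (standard AT);
* ``trades_loss``  — natural CE + beta * KL(p_nat || p_adv);
* ``boosted_ce``   — -log p_y - log(1 - max_{k!=y} p_k), the margin-boosted
  cross-entropy;
* ``mart_loss``    — misclassification-aware training: mean over the batch
  of BCE(p_adv, y) + lambda * KL(p_nat || p_adv) * (1 - p_nat[y]);
* ``cas_loss``     — (alpha / K) * sum over the K auxiliary CAS heads of the
  configured outer objective applied to that head's outputs;
* ``total_loss``   — outer objective + CAS term (+ an optional MSE between
  the one-hot label and the natural probability vector, which stabilises
  convergence on the multilead profile).

The training loop regenerates adversarial examples with the inner attack at
every step (the inner maximisation targets plain cross-entropy; the outer
minimisation targets the configured total objective), optimises with
Adamax under a plateau learning-rate schedule, and ramps the distance-head
norm exponent p geometrically across epochs — the exact l-inf max has
degenerate gradients, so training uses a smooth p-norm surrogate and
evaluation switches to exact p=inf.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .attacks import AttackConfig, pgd
from .ecg_data import ECGDataset
from .model import CASLCNet, LinfDistNet
from .nn import Adamax, ReduceLROnPlateau, Tensor, as_tensor, clip_floor, log, softmax
from .nn.autodiff import gather_rows_at

__all__ = [
    "LossConfig",
    "TrainConfig",
    "boosted_ce",
    "ce_loss",
    "at_loss",
    "trades_loss",
    "mart_loss",
    "cas_loss",
    "total_loss",
    "train",
]

_PROB_FLOOR = 1e-12


@dataclass
class LossConfig:
    name: str = "mart"                 # {ce, at, trades, mart}
    lam: float = 5.0                   # MART trade-off lambda
    beta: float = 6.0                  # TRADES trade-off
    alpha: float = 2.0                 # CAS auxiliary weight
    use_mse_aux: bool = False
    inner_attack: AttackConfig = field(
        default_factory=lambda: AttackConfig(epsilon=0.1, steps=10, step_size=0.01,
                                             clip_range=(-1.0, 1.0))
    )

    def __post_init__(self):
        if self.lam < 0 or self.alpha < 0 or self.beta < 0:
            raise ValueError("loss trade-off weights must be non-negative")
        if self.name not in {"ce", "at", "trades", "mart"}:
            raise ValueError(f"unknown loss name {self.name!r}")


@dataclass
class TrainConfig:
    loss: LossConfig = field(default_factory=LossConfig)
    epochs: int = 5
    batch_size: int = 512
    lr: float = 1e-3
    seed: int = 0
    p_start: float = 8.0
    p_end: float = 1000.0
    scheduler_factor: float = 0.5
    scheduler_patience: int = 3
    history_max_eval: int = 512        # cap on records scored per epoch


# ---------------------------------------------------------------------------
# probability helpers


def _as_prob_2d(p) -> Tensor:
    p = as_tensor(p)
    if p.ndim == 1:
        p = p.reshape((1, p.shape[0]))
    return p


def _safe_log(p: Tensor) -> Tensor:
    return log(clip_floor(p, _PROB_FLOOR))


def _nll(p: Tensor, y) -> Tensor:
    """Per-sample -log p[y]."""
    return -_safe_log(gather_rows_at(p, np.asarray(y, dtype=np.intp)))


def _kl(p: Tensor, q: Tensor) -> Tensor:
    """Per-sample KL(p || q) with probability flooring."""
    return (p * (_safe_log(p) - _safe_log(q))).sum(axis=1)


# ---------------------------------------------------------------------------
# objectives


def boosted_ce(p_adv, y) -> Tensor:
    """Boosted cross-entropy: -log p_y - log(1 - max_{k != y} p_k).

    Accepts one probability vector or a batch; returns the scalar mean.
    """
    p = _as_prob_2d(p_adv)
    y = np.atleast_1d(np.asarray(y, dtype=np.intp))
    masked = p.data.copy()
    masked[np.arange(p.shape[0]), y] = -np.inf
    other_idx = masked.argmax(axis=1)
    p_other = gather_rows_at(p, other_idx)
    per_sample = _nll(p, y) - _safe_log(1.0 - p_other)
    return per_sample.mean()


def ce_loss(p_nat, y) -> Tensor:
    return _nll(_as_prob_2d(p_nat), np.atleast_1d(np.asarray(y, dtype=np.intp))).mean()


def at_loss(p_nat, p_adv, y, config: LossConfig) -> Tensor:
    return ce_loss(p_adv, y)


def trades_loss(p_nat, p_adv, y, config: LossConfig) -> Tensor:
    p, q = _as_prob_2d(p_nat), _as_prob_2d(p_adv)
    return ce_loss(p, y) + config.beta * _kl(p, q).mean()


def mart_loss(p_nat, p_adv, y, lam: float = 5.0) -> Tensor:
    """Misclassification-aware objective (batch mean)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    p, q = _as_prob_2d(p_nat), _as_prob_2d(p_adv)
    y = np.atleast_1d(np.asarray(y, dtype=np.intp))
    bce = boosted_ce(q, y)
    soft = 1.0 - gather_rows_at(p, y)
    return bce + lam * (_kl(p, q) * soft).mean()


def _outer(name: str):
    if name == "mart":
        return lambda p, q, y, cfg: mart_loss(p, q, y, cfg.lam)
    if name == "trades":
        return trades_loss
    if name == "at":
        return at_loss
    if name == "ce":
        return lambda p, q, y, cfg: ce_loss(p, y)
    raise ValueError(f"unknown loss name {name!r}")


def cas_loss(aux_pairs, y, alpha: float, base_loss, config: LossConfig | None = None) -> Tensor:
    """(alpha / K) * sum over CAS heads of the outer objective on that head.

    ``aux_pairs`` is a list of (p_nat_k, p_adv_k) auxiliary probability
    pairs, one per CAS module.
    """
    if not aux_pairs:
        raise ValueError("need at least one CAS auxiliary head")
    config = config or LossConfig()
    total = None
    for p_nat_k, p_adv_k in aux_pairs:
        term = base_loss(p_nat_k, p_adv_k, y, config)
        total = term if total is None else total + term
    return (alpha / len(aux_pairs)) * total


def total_loss(model_outputs, aux_outputs, y, config: LossConfig) -> Tensor:
    """Outer objective + CAS auxiliary term (+ optional natural-MSE term).

    ``model_outputs`` is the (p_nat, p_adv) pair from the final classifier;
    ``aux_outputs`` the list of per-CAS-head pairs (may be empty when the
    model has no CAS modules or alpha is zero).
    """
    p_nat, p_adv = model_outputs
    outer = _outer(config.name)
    loss = outer(_as_prob_2d(p_nat), _as_prob_2d(p_adv), y, config)
    if config.alpha > 0 and aux_outputs:
        loss = loss + cas_loss(aux_outputs, y, config.alpha, outer, config)
    if config.use_mse_aux:
        p = _as_prob_2d(p_nat)
        y_arr = np.atleast_1d(np.asarray(y, dtype=np.intp))
        onehot = np.zeros(p.shape)
        onehot[np.arange(p.shape[0]), y_arr] = 1.0
        diff = p - onehot
        loss = loss + (diff * diff).sum(axis=1).mean()
    return loss


# ---------------------------------------------------------------------------
# training loop


def _accuracy(model: CASLCNet, x, y, masks=None) -> float:
    return float((model.predict(x, mask=masks) == y).mean())


def train(model: CASLCNet, dataset: ECGDataset, config: TrainConfig,
          epochs: int | None = None, seed: int | None = None,
          eval_dataset: ECGDataset | None = None, verbose: bool = False):
    """Adversarially train ``model`` in place; returns (model, history).

    Each minibatch regenerates adversarial examples against the current
    parameters with the inner attack (skipped for pure ``ce`` training),
    then takes one Adamax step on the configured total objective.  History
    rows carry per-epoch loss, clean accuracy, and robust accuracy under
    the inner attack (evaluated at exact p=inf on a capped subset).
    """
    epochs = config.epochs if epochs is None else epochs
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    loss_cfg = config.loss
    adversarial = loss_cfg.name != "ce"

    x_all = dataset.signals()
    y_all = dataset.labels()
    masks_all = dataset.masks() if model.config.dataset_style == "multilead" else None

    eval_ds = eval_dataset or dataset
    x_eval = eval_ds.signals()
    y_eval = eval_ds.labels()
    m_eval = eval_ds.masks() if model.config.dataset_style == "multilead" else None
    if len(y_eval) > config.history_max_eval:
        pick = np.random.default_rng(seed + 1).choice(
            len(y_eval), config.history_max_eval, replace=False
        )
        x_eval, y_eval = x_eval[pick], y_eval[pick]
        m_eval = m_eval[pick] if m_eval is not None else None

    params = list(model.parameters())
    opt = Adamax(params, lr=config.lr)
    sched = ReduceLROnPlateau(opt, factor=config.scheduler_factor,
                              patience=config.scheduler_patience)
    history = []
    n = len(y_all)
    for epoch in range(epochs):
        if isinstance(model.head, LinfDistNet):
            if epochs > 1:
                ratio = (config.p_end / config.p_start) ** (epoch / (epochs - 1))
            else:
                ratio = 1.0
            model.set_head_p(config.p_start * ratio)
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        t0 = time.time()
        model.train()
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            mb = masks_all[idx] if masks_all is not None else None
            if adversarial:
                atk = pgd(model, xb, yb, loss_cfg.inner_attack, mask=mb)
                xb_adv = atk.x_adv
            model.train()
            logits_nat, aux_nat = model.forward(xb, labels=yb, mask=mb)
            p_nat = softmax(logits_nat, axis=1)
            if adversarial:
                logits_adv, aux_adv = model.forward(xb_adv, labels=yb, mask=mb)
                p_adv = softmax(logits_adv, axis=1)
                # CAS heads already emit probabilities
                aux_pairs = list(zip(aux_nat, aux_adv))
            else:
                p_adv = p_nat
                aux_pairs = [(a, a) for a in aux_nat]
            loss = total_loss((p_nat, p_adv), aux_pairs, yb, loss_cfg)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: "
                    f"{float(loss.data)!r}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        mean_loss = epoch_loss / max(n_batches, 1)
        sched.step(mean_loss)

        model.eval()
        model.set_head_p(np.inf)
        clean_acc = _accuracy(model, x_eval, y_eval, m_eval)
        if adversarial:
            atk = pgd(model, x_eval, y_eval, loss_cfg.inner_attack, mask=m_eval)
            robust_acc = float((~atk.success).mean())
        else:
            robust_acc = float("nan")
        history.append({
            "epoch": epoch,
            "loss": mean_loss,
            "clean_accuracy": clean_acc,
            "robust_accuracy": robust_acc,
            "lr": opt.lr,
            "seconds": time.time() - t0,
        })
        if verbose:
            print(
                f"epoch {epoch}: loss {mean_loss:.4f} "
                f"clean {clean_acc:.3f} robust {robust_acc:.3f}"
            )
    model.eval()
    model.set_head_p(np.inf)
    return model, history
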