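"""White-box attack suite for 1-D signal classifiers.

All attacks share a common contract: they receive a model (anything whose
``forward`` maps a batch Tensor to logits, optionally via a validity mask),
a natural batch ``x`` [N, leads, W] (or [N, W] for single-lead), integer
labels ``y``, and an :class:`AttackConfig`; they return an
:class:`AttackResult` with the perturbed batch, the achieved per-sample
l-infinity distortion, and a per-sample success flag (prediction != label).

Implemented attacks:

* ``white_noise`` — uniform noise in the eps-ball (no gradient);
* ``fgsm``       — single sign-gradient step of size eps;
* ``pgd``        — iterated sign-gradient steps projected onto the eps-ball,
  optionally from a uniform random start;
* ``mi_fgsm``    — PGD with an l1-normalised momentum-accumulated gradient;
* ``sap``        — PGD whose per-step update is convolved with a 1-D
  Gaussian kernel so the perturbation stays smooth (physiologically
  plausible for ECG);
* ``cw``         — Carlini–Wagner l2: minimises distortion plus a margin
  objective via a tanh change of variables.

Every l-inf attack clamps iterates to [x-eps, x+eps] and then to the data
range (``clip_range``), and is deterministic given (model, inputs, config).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import convolve1d

from .nn import Tensor, log_softmax, gather_rows_at, clip_floor
from .nn.autodiff import tanh as t_tanh

__all__ = [
    "AttackConfig",
    "AttackResult",
    "gaussian_kernel_1d",
    "white_noise",
    "fgsm",
    "pgd",
    "mi_fgsm",
    "cw",
    "sap",
    "get_attack",
]


@dataclass
class AttackConfig:
    epsilon: float = 0.1
    steps: int = 10
    step_size: float | None = None        # default: epsilon / 10
    random_start: bool = True
    clip_range: tuple | None = (-1.0, 1.0)
    momentum_decay: float = 1.0
    sap_kernel: tuple = (11, 5.0)          # (size s — odd, sigma)
    cw_iterations: int = 100
    cw_c: float = 1.0
    cw_kappa: float = 0.0
    cw_lr: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.sap_kernel[0] % 2 == 0:
            raise ValueError("SAP kernel size must be odd")

    @property
    def delta(self) -> float:
        return self.epsilon / 10.0 if self.step_size is None else self.step_size


@dataclass
class AttackResult:
    x_adv: np.ndarray
    achieved_linf: np.ndarray
    success: np.ndarray
    loss_trace: list = field(default_factory=list)


def gaussian_kernel_1d(s: int, sigma: float) -> np.ndarray:
    """Normalised symmetric Gaussian taps at offsets -(s-1)/2 .. (s-1)/2."""
    if s < 1 or s % 2 == 0:
        raise ValueError(f"kernel size must be a positive odd integer, got {s}")
    if s == 1:
        return np.ones(1)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = (s - 1) // 2
    offsets = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (offsets / sigma) ** 2)
    return k / k.sum()


# ---------------------------------------------------------------------------
# helpers


def _forward_logits(model, x: np.ndarray, mask=None) -> Tensor:
    xt = Tensor(x, requires_grad=True)
    out = model.forward(xt, mask=mask) if mask is not None else model.forward(xt)
    logits = out[0] if isinstance(out, tuple) else out
    return xt, logits


def ce_input_grad(model, x: np.ndarray, y: np.ndarray, mask=None):
    """Cross-entropy loss and its gradient with respect to the input batch."""
    xt, logits = _forward_logits(model, x, mask)
    logp = log_softmax(logits, axis=1)
    loss = -gather_rows_at(logp, y).mean()
    loss.backward()
    g = xt.grad
    if not np.isfinite(g).all():
        raise FloatingPointError("non-finite input gradient")
    return float(loss.data), g


def _project(x_adv, x0, epsilon, clip_range):
    x_adv = np.clip(x_adv, x0 - epsilon, x0 + epsilon)
    if clip_range is not None:
        x_adv = np.clip(x_adv, clip_range[0], clip_range[1])
    return x_adv


def _finish(model, x, x_adv, y, mask=None, loss_trace=None) -> AttackResult:
    axes = tuple(range(1, x.ndim))
    achieved = np.abs(x_adv - x).max(axis=axes)
    pred = model.predict(x_adv, mask=mask) if mask is not None else model.predict(x_adv)
    return AttackResult(
        x_adv=x_adv,
        achieved_linf=achieved,
        success=pred != np.asarray(y),
        loss_trace=loss_trace or [],
    )


# ---------------------------------------------------------------------------
# attacks


def white_noise(model, x, y, config: AttackConfig, mask=None) -> AttackResult:
    """Uniform random perturbation in the eps-ball (single draw, seeded)."""
    x = np.asarray(x, dtype=np.float64)
    rng = np.random.default_rng(config.seed)
    u = rng.uniform(-config.epsilon, config.epsilon, size=x.shape)
    x_adv = _project(x + u, x, config.epsilon, config.clip_range)
    return _finish(model, x, x_adv, y, mask)


def _iterated_sign_attack(model, x, y, config: AttackConfig, mask=None, *,
                          momentum: float | None = None,
                          smooth_kernel: np.ndarray | None = None,
                          random_start: bool | None = None) -> AttackResult:
    """Shared core of PGD / MI-FGSM / SAP."""
    x = np.asarray(x, dtype=np.float64)
    delta = config.delta
    if delta > config.epsilon:
        warnings.warn("step size exceeds epsilon; attack is still valid",
                      RuntimeWarning, stacklevel=3)
    if random_start is None:
        random_start = config.random_start
    x_adv = x.copy()
    if random_start and config.epsilon > 0:
        rng = np.random.default_rng(config.seed)
        x_adv = _project(
            x + rng.uniform(-config.epsilon, config.epsilon, size=x.shape),
            x, config.epsilon, config.clip_range,
        )
    g_acc = np.zeros_like(x)
    trace = []
    for _ in range(config.steps):
        loss, grad = ce_input_grad(model, x_adv, y, mask)
        trace.append(loss)
        if momentum is not None:
            axes = tuple(range(1, x.ndim))
            l1 = np.abs(grad).sum(axis=axes, keepdims=True)
            normed = np.divide(grad, l1, out=np.zeros_like(grad), where=l1 > 0)
            g_acc = momentum * g_acc + normed
            direction = g_acc
        else:
            direction = grad
        update = delta * np.sign(direction)
        if smooth_kernel is not None and smooth_kernel.size > 1:
            update = convolve1d(update, smooth_kernel, axis=-1, mode="reflect")
        x_adv = _project(x_adv + update, x, config.epsilon, config.clip_range)
    return _finish(model, x, x_adv, y, mask, trace)


def pgd(model, x, y, config: AttackConfig, mask=None) -> AttackResult:
    """Projected gradient descent in the l-inf eps-ball."""
    return _iterated_sign_attack(model, x, y, config, mask)


def fgsm(model, x, y, config: AttackConfig, mask=None) -> AttackResult:
    """Single sign-gradient step of size epsilon (PGD with one full step)."""
    one_step = replace(config, steps=1, step_size=config.epsilon,
                       random_start=False)
    return _iterated_sign_attack(model, x, y, one_step, mask, random_start=False)


def mi_fgsm(model, x, y, config: AttackConfig, mask=None) -> AttackResult:
    """Momentum iterative FGSM: l1-normalised accumulated gradient."""
    return _iterated_sign_attack(model, x, y, config, mask,
                                 momentum=config.momentum_decay,
                                 random_start=False)


def sap(model, x, y, config: AttackConfig, mask=None) -> AttackResult:
    """Smooth adversarial perturbation: PGD with Gaussian-smoothed updates."""
    s, sigma = config.sap_kernel
    x = np.asarray(x, dtype=np.float64)
    if s > x.shape[-1]:
        raise ValueError(f"kernel size {s} exceeds signal length {x.shape[-1]}")
    kernel = gaussian_kernel_1d(int(s), float(sigma))
    return _iterated_sign_attack(model, x, y, config, mask, smooth_kernel=kernel)


def cw(model, x, y, config: AttackConfig, mask=None) -> AttackResult:
    """Carlini–Wagner l2 attack with a tanh change of variables.

    Minimises ||x_adv - x||_2^2 + c * max(z_y - max_{k!=y} z_k + kappa, 0)
    by Adam for ``cw_iterations`` steps; returns, per sample, the successful
    iterate of least l2 distortion (or the final iterate if never successful).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.intp)
    if config.clip_range is None:
        raise ValueError("C&W requires a finite clip_range for the change of variables")
    lo, hi = config.clip_range
    mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
    shrink = 0.999999
    w0 = np.arctanh(np.clip((x - mid) / half, -shrink, shrink))
    w = Tensor(w0, requires_grad=True)
    n = x.shape[0]
    best_adv = x.copy()
    best_l2 = np.full(n, np.inf)
    # Adam state
    m = np.zeros_like(w0)
    v = np.zeros_like(w0)
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    axes = tuple(range(1, x.ndim))
    trace = []
    for t in range(1, config.cw_iterations + 1):
        w = Tensor(w.data, requires_grad=True)
        x_adv = mid + half * t_tanh(w)
        diff = x_adv - Tensor(x)
        dist2 = (diff * diff).sum(axis=axes)
        out = (model.forward(x_adv, mask=mask) if mask is not None
               else model.forward(x_adv))
        logits = out[0] if isinstance(out, tuple) else out
        z = logits.data
        z_true = gather_rows_at(logits, y)
        masked = z.copy()
        masked[np.arange(n), y] = -np.inf
        other_idx = masked.argmax(axis=1)
        z_other = gather_rows_at(logits, other_idx)
        margin = clip_floor(z_true - z_other + config.cw_kappa, 0.0)
        loss = (dist2 + config.cw_c * margin).sum()
        loss.backward()
        trace.append(float(loss.data))
        # track best successful iterate (success = margin beaten by kappa)
        succ = (z_true.data - z_other.data + config.cw_kappa) <= 0
        l2 = np.sqrt(dist2.data)
        improve = succ & (l2 < best_l2)
        best_l2[improve] = l2[improve]
        best_adv[improve] = x_adv.data[improve]
        g = w.grad
        m = b1 * m + (1 - b1) * g
        v = b2 * v + (1 - b2) * g * g
        mh = m / (1 - b1 ** t)
        vh = v / (1 - b2 ** t)
        w = Tensor(w.data - config.cw_lr * mh / (np.sqrt(vh) + eps_adam))
    final = x_adv.data
    never = ~np.isfinite(best_l2)
    best_adv[never] = final[never]
    return _finish(model, x, best_adv, y, mask, trace)


_ATTACKS = {
    "noise": white_noise,
    "fgsm": fgsm,
    "mifgsm": mi_fgsm,
    "pgd": pgd,
    "cw": cw,
    "sap": sap,
}


def get_attack(name: str):
    try:
        return _ATTACKS[name]
    except KeyError:
        raise KeyError(
            f"unknown attack {name!r}; choose from {sorted(_ATTACKS)}"
        ) from None
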