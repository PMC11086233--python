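"""CASLCNet: residual 1-D feature extractor with channel-wise activation
suppression (CAS) and a 1-Lipschitz l-infinity-distance classifier.

Architecture (beats profile, 187-sample single-lead input):

==========================  ===========  =================================
layer                       output       parameters
==========================  ===========  =================================
stem conv                   64 x 94      kernel 11, stride 2
residual layer 1            128 x 24     2 blocks of [k3, k3], stride 2 each
residual layer 2            256 x 6      idem
residual layer 3            512 x 2      idem
residual + CAS layer        512 x 2      2 blocks, stride 1, CAS per block
global average pool         512
l-inf distance head         M            widths 512 x 5, then M
==========================  ===========  =================================

The multilead profile shares the trunk but halves the width once in the CAS
layer and replaces global pooling with a masked average over the valid
(non-padded) region; group-norm statistics are likewise restricted to the
valid region so the amount of zero padding cannot influence the features.

Each CAS module is an auxiliary linear classifier on globally pooled
channel activations; its weight column for the true class (training) or the
predicted class (evaluation) multiplicatively reweights the channels,
suppressing channels that are not predictive for the class.

The classifier head is built from distance neurons u(x) = ||x - w||_inf + b,
a 1-Lipschitz map under the l-inf norm, so any input perturbation of size
eps moves every logit by at most eps: a top-two logit margin above 2*eps
certifies the prediction against all such perturbations.  Training uses a
smooth p-norm surrogate (p ramped geometrically upward each epoch) because
the exact max has degenerate gradients.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import (
    Conv1d,
    GroupNorm,
    LeakyReLU,
    Module,
    PNormDistLayer,
    Tensor,
    as_tensor,
    gather_cols,
    relu,
    softmax,
)
from .nn.layers import Linear

__all__ = [
    "NetworkConfig",
    "CASModule",
    "LinfDistNet",
    "ResidualBlock",
    "CASLCNet",
    "linf_neuron",
    "linf_forward",
    "cas_forward",
    "masked_reduce",
    "build_caslcnet",
    "trace_widths",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_SCHEMA = 1


# ---------------------------------------------------------------------------
# configuration


@dataclass
class NetworkConfig:
    dataset_style: str = "beats"          # {beats, multilead}
    n_classes: int = 5
    in_leads: int = 1
    stem_channels: int = 64
    stem_kernel: int = 11
    stem_stride: int = 2
    res_channels: tuple = (128, 256, 512)
    blocks_per_layer: int = 2
    cas_channels: int = 512
    cas_blocks: int = 2
    head_widths: tuple = (512, 512, 512, 512, 512)
    n_groups: int = 32
    leaky_slope: float = 0.01
    use_cas: bool = True
    use_linf_head: bool = True
    seed: int = 0

    @property
    def cas_strides(self) -> tuple:
        # beats: keep width; multilead: halve once in the first CAS block
        if self.dataset_style == "multilead":
            return (2,) + (1,) * (self.cas_blocks - 1)
        return (1,) * self.cas_blocks

    @classmethod
    def beats(cls, n_classes: int = 5, **kw) -> "NetworkConfig":
        return cls(dataset_style="beats", n_classes=n_classes, in_leads=1, **kw)

    @classmethod
    def multilead(cls, n_classes: int = 9, **kw) -> "NetworkConfig":
        return cls(dataset_style="multilead", n_classes=n_classes, in_leads=8, **kw)

    @classmethod
    def small_beats(cls, n_classes: int = 5, **kw) -> "NetworkConfig":
        """Desk-scale profile: same topology, narrow channels."""
        kw.setdefault("stem_channels", 16)
        kw.setdefault("res_channels", (16, 32, 32))
        kw.setdefault("cas_channels", 32)
        kw.setdefault("head_widths", (64, 64))
        kw.setdefault("n_groups", 4)
        return cls(dataset_style="beats", n_classes=n_classes, in_leads=1, **kw)

    @classmethod
    def small_multilead(cls, n_classes: int = 9, in_leads: int = 8, **kw) -> "NetworkConfig":
        kw.setdefault("stem_channels", 16)
        kw.setdefault("res_channels", (16, 32, 32))
        kw.setdefault("cas_channels", 32)
        kw.setdefault("head_widths", (64, 64))
        kw.setdefault("n_groups", 4)
        return cls(dataset_style="multilead", n_classes=n_classes, in_leads=in_leads, **kw)


# ---------------------------------------------------------------------------
# primitive operations (also exposed functionally for testing)


def linf_neuron(x_f: np.ndarray, w: np.ndarray, b: float) -> float:
    """One distance neuron: ||x_f - w||_inf + b."""
    x_f, w = np.asarray(x_f, dtype=float), np.asarray(w, dtype=float)
    if x_f.shape != w.shape:
        raise ValueError(f"length mismatch: input {x_f.shape}, weight {w.shape}")
    return float(np.abs(x_f - w).max() + b)


def masked_reduce(features, mask) -> Tensor:
    """Masked channel average: out[n, c] = sum_w f[n,c,w]*m[n,w] / sum_w m[n,w]."""
    features = as_tensor(features)
    mask = np.asarray(mask, dtype=np.float64)
    counts = mask.sum(axis=1)
    if (counts == 0).any():
        raise ValueError("mask selects no positions for at least one record")
    weighted = features * mask[:, None, :]
    return weighted.sum(axis=2) * (1.0 / counts)[:, None]


# ---------------------------------------------------------------------------
# modules


class ResidualBlock(Module):
    """conv(k3,s)-GN-act-conv(k3,1)-GN + projected skip, then activation.

    ``final_relu`` switches the output activation from the leaky rectifier
    to a plain rectifier (CAS modules require non-negative features).
    """

    def __init__(self, in_ch, out_ch, stride, n_groups, slope,
                 rng: np.random.Generator, final_relu: bool = False):
        super().__init__()
        self.stride = stride
        self.conv1 = Conv1d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng)
        self.gn1 = GroupNorm(min(n_groups, out_ch), out_ch)
        self.conv2 = Conv1d(out_ch, out_ch, 3, stride=1, padding=1, rng=rng)
        self.gn2 = GroupNorm(min(n_groups, out_ch), out_ch)
        self.act = LeakyReLU(slope)
        self.final_relu = final_relu
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv1d(in_ch, out_ch, 1, stride=stride, padding=0, rng=rng)
            self.gn_proj = GroupNorm(min(n_groups, out_ch), out_ch)
        else:
            self.proj = None

    def forward(self, x, mask: np.ndarray | None = None):
        out_mask = mask[:, :: self.stride] if mask is not None else None
        h = self.act(self.gn1(self.conv1(x), out_mask))
        h = self.gn2(self.conv2(h), out_mask)
        if self.proj is not None:
            skip = self.gn_proj(self.proj(x), out_mask)
        else:
            skip = x
        s = h + skip
        out = relu(s) if self.final_relu else self.act(s)
        return out, out_mask


class CASModule(Module):
    """Auxiliary classifier whose class column reweights feature channels."""

    def __init__(self, channels: int, n_classes: int, rng: np.random.Generator):
        super().__init__()
        self.n_classes = n_classes
        self.H = Tensor(
            rng.normal(1.0, 0.1, size=(channels, n_classes)), requires_grad=True
        )

    def forward(self, features, labels=None, mask: np.ndarray | None = None):
        features = as_tensor(features)
        if (features.data < 0).any():
            raise ValueError("CAS features must be non-negative (post-rectifier)")
        pooled = (
            masked_reduce(features, mask)
            if mask is not None
            else features.mean(axis=2)
        )
        aux_logits = pooled @ self.H
        p_hat = softmax(aux_logits, axis=1)
        if self.training and labels is not None:
            labels = np.asarray(labels, dtype=np.intp)
            if (labels >= self.n_classes).any() or (labels < 0).any():
                raise ValueError(f"label out of range [0, {self.n_classes})")
            idx = labels
        else:
            idx = p_hat.data.argmax(axis=1)  # ties -> lowest index
        cols = gather_cols(self.H, idx)                      # [N, C]
        reweighted = features * cols.reshape((cols.shape[0], cols.shape[1], 1))
        return reweighted, p_hat


def cas_forward(features, cas: CASModule, label_or_none=None, mask=None):
    """Functional wrapper around :class:`CASModule`."""
    return cas(features, label_or_none, mask)


class LinfDistNet(Module):
    """Stack of distance-neuron layers; 1-Lipschitz end to end at p=inf."""

    def __init__(self, in_features: int, widths, n_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        dims = [in_features, *widths, n_classes]
        self.layers = [
            PNormDistLayer(dims[i], dims[i + 1], rng=rng) for i in range(len(dims) - 1)
        ]
        self.n_classes = n_classes

    def set_p(self, p: float):
        for layer in self.layers:
            layer.p = p

    @property
    def p(self):
        return self.layers[0].p

    def forward(self, x):
        h = as_tensor(x)
        for layer in self.layers:
            h = layer(h)
        return h

    def predict(self, x) -> np.ndarray:
        return self.forward(as_tensor(x)).data.argmax(axis=1)


def linf_forward(net: LinfDistNet, x_f) -> np.ndarray:
    """Evaluate the head at exact p=inf, returning the logit array."""
    old = net.layers[0].p
    net.set_p(np.inf)
    try:
        return net.forward(as_tensor(np.atleast_2d(x_f))).data
    finally:
        net.set_p(old)


class CASLCNet(Module):
    """Full network; see the module docstring for the layer plan."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ng, slope = config.n_groups, config.leaky_slope

        self.stem = Conv1d(config.in_leads, config.stem_channels, config.stem_kernel,
                           stride=config.stem_stride,
                           padding=config.stem_kernel // 2, rng=rng)
        self.stem_gn = GroupNorm(min(ng, config.stem_channels), config.stem_channels)
        self.act = LeakyReLU(slope)

        blocks = []
        in_ch = config.stem_channels
        for out_ch in config.res_channels:
            layer = []
            for _ in range(config.blocks_per_layer):
                layer.append(ResidualBlock(in_ch, out_ch, 2, ng, slope, rng))
                in_ch = out_ch
            blocks.append(layer)
        self.res_layers = [b for layer in blocks for b in layer]
        self._layer_sizes = [config.blocks_per_layer] * len(config.res_channels)

        self.cas_blocks_list = []
        self.cas_modules = []
        for stride in config.cas_strides:
            self.cas_blocks_list.append(
                ResidualBlock(in_ch, config.cas_channels, stride, ng, slope, rng,
                              final_relu=config.use_cas)
            )
            in_ch = config.cas_channels
            if config.use_cas:
                self.cas_modules.append(CASModule(in_ch, config.n_classes, rng))

        if config.use_linf_head:
            self.head = LinfDistNet(in_ch, config.head_widths, config.n_classes, rng)
        else:
            self.head = Linear(in_ch, config.n_classes, rng=rng)

    # -- forward ----------------------------------------------------------
    def extract(self, x, labels=None, mask: np.ndarray | None = None):
        """Run the feature extractor; returns (features [N,C,W], aux_ps, mask)."""
        x = as_tensor(x)
        if x.ndim == 2:
            x = x.reshape((x.shape[0], 1, x.shape[1]))
        if x.shape[1] != self.config.in_leads:
            raise ValueError(
                f"expected {self.config.in_leads} lead(s), got {x.shape[1]}"
            )
        if x.shape[2] < self.config.stem_kernel:
            raise ValueError(
                f"input length {x.shape[2]} is shorter than the stem kernel "
                f"({self.config.stem_kernel}); temporal width would collapse"
            )
        m = np.asarray(mask, dtype=np.float64) if mask is not None else None
        if m is not None:
            m = m[:, :: self.config.stem_stride]

        def masked(t, mm):
            # zero the padded region so features are independent of how much
            # zero padding a record carries (output masking)
            return t if mm is None else t * mm[:, None, :]

        h = masked(self.act(self.stem_gn(self.stem(x), m)), m)
        for block in self.res_layers:
            h, m = block(h, m)
            h = masked(h, m)
        aux_ps = []
        for i, block in enumerate(self.cas_blocks_list):
            h, m = block(h, m)
            h = masked(h, m)
            if self.config.use_cas:
                h, p_hat = self.cas_modules[i](h, labels, m)
                aux_ps.append(p_hat)
        return h, aux_ps, m

    def pooled_features(self, x, labels=None, mask=None) -> Tensor:
        """Channel vector fed to the classifier head ([N, C])."""
        h, _aux, m = self.extract(x, labels, mask)
        if m is not None:
            return masked_reduce(h, m)
        return h.mean(axis=2)

    def forward(self, x, labels=None, mask: np.ndarray | None = None):
        """Returns (logits [N, M], list of auxiliary probability tensors)."""
        h, aux_ps, m = self.extract(x, labels, mask)
        feat = masked_reduce(h, m) if m is not None else h.mean(axis=2)
        logits = self.head(feat)
        return logits, aux_ps

    def predict(self, x, mask=None) -> np.ndarray:
        was_training = self.training
        self.eval()
        try:
            logits, _ = self.forward(x, mask=mask)
        finally:
            if was_training:
                self.train()
        return logits.data.argmax(axis=1)

    def set_head_p(self, p: float):
        if isinstance(self.head, LinfDistNet):
            self.head.set_p(p)


def build_caslcnet(config: NetworkConfig) -> CASLCNet:
    return CASLCNet(config)


def trace_widths(config: NetworkConfig, input_length: int) -> list[int]:
    """Temporal widths after the stem, each residual layer, and the CAS layer."""

    def conv_w(w, k, s, p):
        out = (w + 2 * p - k) // s + 1
        if out <= 0:
            raise ValueError(
                f"input length {input_length} collapses to width {out}"
            )
        return out

    widths = []
    w = conv_w(input_length, config.stem_kernel, config.stem_stride,
               config.stem_kernel // 2)
    widths.append(w)
    for _ in config.res_channels:
        for _ in range(config.blocks_per_layer):
            w = conv_w(w, 3, 2, 1)
        widths.append(w)
    for stride in config.cas_strides:
        w = conv_w(w, 3, stride, 1)
    widths.append(w)
    return widths


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: CASLCNet, path, metadata: dict | None = None):
    state = model.state_dict()
    header = {
        "schema": CHECKPOINT_SCHEMA,
        "config": asdict(model.config),
        "metadata": metadata or {},
    }
    np.savez(path, __header__=np.array(json.dumps(header)), **state)


def load_checkpoint(path) -> tuple[CASLCNet, dict]:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["__header__"]))
        if header.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema: {header.get('schema')}")
        cfg_dict = header["config"]
        cfg_dict["res_channels"] = tuple(cfg_dict["res_channels"])
        cfg_dict["head_widths"] = tuple(cfg_dict["head_widths"])
        config = NetworkConfig(**cfg_dict)
        model = CASLCNet(config)
        model.load_state_dict({k: z[k] for k in z.files if k != "__header__"})
    return model, header["metadata"]
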