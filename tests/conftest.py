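import numpy as np
import pytest

from caslcnet.ecg_data import ECGDataset, ECGRecord, STANDARD_12_LEADS
from caslcnet.model import NetworkConfig, build_caslcnet
from caslcnet.nn import Module, Tensor
from caslcnet.nn.layers import Linear
from caslcnet.synth_ecg import MorphologySpec, Bump, generate_beats


class LinearModel(Module):
    """Affine logits z = x W + b on flat inputs; oracle-friendly toy model."""

    def __init__(self, weight: np.ndarray, bias: np.ndarray | None = None):
        super().__init__()
        w = np.asarray(weight, dtype=np.float64)
        self.lin = Linear(w.shape[0], w.shape[1])
        self.lin.weight.data = w.copy()
        if bias is not None:
            self.lin.bias.data = np.asarray(bias, dtype=np.float64).copy()

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim == 3:
            x = x.reshape((x.shape[0], x.shape[1] * x.shape[2]))
        return self.lin(x)

    def predict(self, x, mask=None):
        return self.forward(x if isinstance(x, Tensor) else Tensor(x)).data.argmax(axis=1)


@pytest.fixture
def linear_model_factory():
    def make(d: int, m: int = 2, seed: int = 0, bias: bool = True):
        rng = np.random.default_rng(seed)
        w = rng.normal(size=(d, m))
        b = rng.normal(size=m) if bias else None
        return LinearModel(w, b)

    return make


@pytest.fixture(scope="session")
def beats_dataset():
    return generate_beats(20, 5, 187, seed=42)


@pytest.fixture(scope="session")
def tiny_model():
    cfg = NetworkConfig.small_beats(seed=0)
    return build_caslcnet(cfg).eval()


@pytest.fixture
def clean_spec():
    """Noise-free, wander-free two-class morphology (deterministic records)."""
    return MorphologySpec(
        class_bumps=[
            [Bump(0.3, 0.05, 1.0), Bump(0.6, 0.1, 0.4)],
            [Bump(0.5, 0.04, 0.9), Bump(0.2, 0.08, 0.3)],
        ],
        noise_sd=0.0,
        baseline_wander_amp=0.0,
    )


@pytest.fixture
def twelve_lead_record():
    rng = np.random.default_rng(7)
    return ECGRecord(
        signal=rng.normal(size=(12, 500)),
        label=0,
        sampling_rate=500.0,
        lead_names=list(STANDARD_12_LEADS),
    )
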