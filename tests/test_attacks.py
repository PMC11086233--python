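"""Attack suite: oracles on linear models, definitional reductions, invariants."""

import itertools

import numpy as np
import pytest

from caslcnet.attacks import (
    AttackConfig,
    cw,
    fgsm,
    gaussian_kernel_1d,
    get_attack,
    mi_fgsm,
    pgd,
    sap,
    white_noise,
)


def ce_loss_np(w, b, x, y):
    """Cross-entropy of an affine model at a single flat input."""
    z = x @ w + b
    z = z - z.max()
    return float(np.log(np.exp(z).sum()) - z[y])


def max_loss_over_ball(w, b, x, y, eps):
    """Enumerate all sign corners of the eps-ball (exact for convex losses)."""
    d = len(x)
    best = -np.inf
    for signs in itertools.product([-1.0, 1.0], repeat=d):
        val = ce_loss_np(w, b, x + eps * np.array(signs), y)
        best = max(best, val)
    return best


class TestGaussianKernel:
    def test_size_one_is_identity(self):
        assert np.array_equal(gaussian_kernel_1d(1, 1.0), [1.0])

    @pytest.mark.parametrize("s,sigma", [(3, 0.5), (5, 1.0), (11, 5.0), (19, 10.0)])
    def test_normalized_and_symmetric(self, s, sigma):
        k = gaussian_kernel_1d(s, sigma)
        assert k.shape == (s,)
        assert np.isclose(k.sum(), 1.0)
        assert np.allclose(k, k[::-1])

    def test_matches_closed_form(self):
        k = gaussian_kernel_1d(5, 1.0)
        raw = np.exp(-0.5 * np.arange(-2, 3) ** 2)
        assert np.allclose(k, raw / raw.sum())

    def test_even_size_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            gaussian_kernel_1d(4, 1.0)


class TestWhiteNoise:
    def test_zero_epsilon_is_identity(self, linear_model_factory):
        model = linear_model_factory(6)
        x = np.random.default_rng(0).normal(size=(3, 6)) * 0.3
        res = white_noise(model, x, np.zeros(3, dtype=int),
                          AttackConfig(epsilon=0.0, clip_range=None))
        assert np.array_equal(res.x_adv, x)

    def test_bound_and_determinism(self, linear_model_factory):
        model = linear_model_factory(6)
        x = np.random.default_rng(1).normal(size=(5, 6)) * 0.3
        cfg = AttackConfig(epsilon=0.07, seed=4, clip_range=None)
        a = white_noise(model, x, np.zeros(5, dtype=int), cfg)
        b = white_noise(model, x, np.zeros(5, dtype=int), cfg)
        assert np.all(a.achieved_linf <= 0.07 + 1e-6)
        assert np.array_equal(a.x_adv, b.x_adv)


class TestFGSM:
    def test_zero_epsilon_identity(self, linear_model_factory):
        model = linear_model_factory(5)
        x = np.random.default_rng(2).normal(size=(2, 5)) * 0.2
        res = fgsm(model, x, np.zeros(2, dtype=int),
                   AttackConfig(epsilon=0.0, clip_range=None))
        assert np.allclose(res.x_adv, x)

    def test_reaches_worst_corner_of_linear_model(self, linear_model_factory):
        model = linear_model_factory(6, m=3, seed=7)
        rng = np.random.default_rng(8)
        x = rng.normal(size=6) * 0.3
        y, eps = 1, 0.1
        res = fgsm(model, x[None], np.array([y]),
                   AttackConfig(epsilon=eps, clip_range=None))
        w, b = model.lin.weight.data, model.lin.bias.data
        achieved = ce_loss_np(w, b, res.x_adv[0], y)
        assert np.isclose(achieved, max_loss_over_ball(w, b, x, y, eps), rtol=1e-10)

    def test_equals_single_step_pgd(self, linear_model_factory):
        model = linear_model_factory(6, seed=3)
        x = np.random.default_rng(4).normal(size=(4, 6)) * 0.3
        y = np.array([0, 1, 0, 1])
        cfg = AttackConfig(epsilon=0.05, steps=1, step_size=0.05,
                           random_start=False, clip_range=None)
        assert np.allclose(fgsm(model, x, y, cfg).x_adv, pgd(model, x, y, cfg).x_adv)


class TestPGD:
    def test_zero_epsilon_identity_any_steps(self, linear_model_factory):
        model = linear_model_factory(5)
        x = np.random.default_rng(5).normal(size=(2, 5)) * 0.2
        cfg = AttackConfig(epsilon=0.0, steps=7, step_size=0.01, clip_range=None)
        assert np.allclose(pgd(model, x, np.zeros(2, dtype=int), cfg).x_adv, x)

    def test_converges_to_corner_maximum_on_linear_model(self, linear_model_factory):
        model = linear_model_factory(8, m=2, seed=11)
        rng = np.random.default_rng(12)
        x = rng.normal(size=8) * 0.2
        y, eps = 0, 0.08
        cfg = AttackConfig(epsilon=eps, steps=50, step_size=eps / 5,
                           random_start=False, clip_range=None)
        res = pgd(model, x[None], np.array([y]), cfg)
        w, b = model.lin.weight.data, model.lin.bias.data
        achieved = ce_loss_np(w, b, res.x_adv[0], y)
        assert np.isclose(achieved, max_loss_over_ball(w, b, x, y, eps), rtol=1e-6)

    def test_loss_monotone_on_linear_model(self, linear_model_factory):
        model = linear_model_factory(6, seed=13)
        x = np.random.default_rng(14).normal(size=(8, 6)) * 0.2
        y = np.zeros(8, dtype=int)
        cfg = AttackConfig(epsilon=0.1, steps=20, step_size=0.005,
                           random_start=False, clip_range=None)
        trace = pgd(model, x, y, cfg).loss_trace
        assert all(b >= a - 1e-10 for a, b in zip(trace, trace[1:]))

    def test_ball_and_clip_respected(self, tiny_model, beats_dataset):
        x = beats_dataset.signals()[:6]
        y = beats_dataset.labels()[:6]
        cfg = AttackConfig(epsilon=0.1, steps=5, step_size=0.03,
                           random_start=True, clip_range=(-1.0, 1.0), seed=0)
        res = pgd(tiny_model, x, y, cfg)
        assert np.all(res.achieved_linf <= 0.1 + 1e-6)
        assert res.x_adv.min() >= -1.0 and res.x_adv.max() <= 1.0

    def test_step_larger_than_epsilon_warns(self, linear_model_factory):
        model = linear_model_factory(4)
        x = np.zeros((1, 4))
        cfg = AttackConfig(epsilon=0.01, steps=2, step_size=0.05, clip_range=None,
                           random_start=False)
        with pytest.warns(RuntimeWarning, match="step size"):
            pgd(model, x, np.array([0]), cfg)


class TestMIFGSM:
    def test_zero_momentum_equals_pgd(self, linear_model_factory):
        model = linear_model_factory(6, seed=15)
        x = np.random.default_rng(16).normal(size=(5, 6)) * 0.2
        y = np.array([0, 1, 1, 0, 0])
        cfg = AttackConfig(epsilon=0.05, steps=10, step_size=0.01,
                           random_start=False, momentum_decay=0.0, clip_range=None)
        assert np.allclose(mi_fgsm(model, x, y, cfg).x_adv,
                           pgd(model, x, y, cfg).x_adv)

    def test_single_step_equals_fgsm_with_step_size(self, linear_model_factory):
        model = linear_model_factory(6, seed=17)
        x = np.random.default_rng(18).normal(size=(3, 6)) * 0.2
        y = np.array([1, 0, 1])
        cfg = AttackConfig(epsilon=0.05, steps=1, step_size=0.02,
                           random_start=False, momentum_decay=1.0, clip_range=None)
        ref = AttackConfig(epsilon=0.02, steps=1, step_size=0.02,
                           random_start=False, clip_range=None)
        assert np.allclose(mi_fgsm(model, x, y, cfg).x_adv,
                           fgsm(model, x, y, ref).x_adv)

    def test_respects_ball(self, linear_model_factory):
        model = linear_model_factory(6, seed=19)
        x = np.random.default_rng(20).normal(size=(4, 6)) * 0.2
        cfg = AttackConfig(epsilon=0.03, steps=25, step_size=0.01,
                           random_start=False, clip_range=None)
        res = mi_fgsm(model, x, np.zeros(4, dtype=int), cfg)
        assert np.all(res.achieved_linf <= 0.03 + 1e-6)


class TestCW:
    def test_zero_constant_keeps_input(self, linear_model_factory):
        model = linear_model_factory(5, seed=21)
        x = np.random.default_rng(22).normal(size=(3, 5)) * 0.3
        cfg = AttackConfig(cw_c=0.0, cw_iterations=50, clip_range=(-1.0, 1.0))
        res = cw(model, x, np.zeros(3, dtype=int), cfg)
        assert np.abs(res.x_adv - x).max() < 1e-6

    def test_matches_point_to_hyperplane_distance(self):
        # two-class affine model: decision boundary (w1-w0)x + (b1-b0) = 0
        from tests.conftest import LinearModel

        w = np.array([[1.0, 0.4], [-0.7, 1.1], [0.2, -0.3]])
        b = np.array([0.05, -0.1])
        model = LinearModel(w, b)
        x = np.array([[0.25, -0.1, 0.3]])
        y = np.array([0])
        z = x[0] @ w + b
        assert z.argmax() == 0
        normal = w[:, 0] - w[:, 1]
        analytic = (z[0] - z[1]) / np.linalg.norm(normal)
        cfg = AttackConfig(cw_c=5.0, cw_iterations=400, cw_lr=0.005,
                           clip_range=(-1.0, 1.0))
        res = cw(model, x, y, cfg)
        assert res.success[0]
        achieved = np.linalg.norm(res.x_adv[0] - x[0])
        assert achieved <= analytic * 1.05

    def test_confidence_margin_on_success(self, linear_model_factory):
        model = linear_model_factory(6, seed=23)
        rng = np.random.default_rng(24)
        x = rng.normal(size=(4, 6)) * 0.2
        y = model.predict(x)
        kappa = 0.3
        cfg = AttackConfig(cw_c=10.0, cw_iterations=300, cw_kappa=kappa,
                           cw_lr=0.01, clip_range=(-1.0, 1.0))
        res = cw(model, x, y, cfg)
        z = res.x_adv.reshape(len(y), -1) @ model.lin.weight.data + model.lin.bias.data
        for i in np.flatnonzero(res.success):
            others = np.delete(z[i], y[i])
            assert others.max() - z[i, y[i]] >= kappa - 1e-6

    def test_requires_finite_clip_range(self, linear_model_factory):
        model = linear_model_factory(4)
        with pytest.raises(ValueError, match="clip_range"):
            cw(model, np.zeros((1, 4)), np.array([0]),
               AttackConfig(clip_range=None))


class TestSAP:
    def test_kernel_size_one_equals_pgd(self, linear_model_factory):
        model = linear_model_factory(8, seed=25)
        x = np.random.default_rng(26).normal(size=(3, 8)) * 0.2
        y = np.array([0, 1, 0])
        cfg = AttackConfig(epsilon=0.05, steps=10, step_size=0.01,
                           random_start=False, sap_kernel=(1, 1.0), clip_range=None)
        assert np.allclose(sap(model, x, y, cfg).x_adv, pgd(model, x, y, cfg).x_adv)

    def test_smoother_than_pgd_above_quarter_nyquist(self, tiny_model, beats_dataset):
        x = beats_dataset.signals()[:8]
        y = beats_dataset.labels()[:8]
        base = dict(epsilon=0.1, steps=10, step_size=0.02, random_start=False,
                    clip_range=(-1.0, 1.0), seed=1)
        p_pgd = pgd(tiny_model, x, y, AttackConfig(**base)).x_adv - x
        p_sap = sap(tiny_model, x, y,
                    AttackConfig(sap_kernel=(11, 5.0), **base)).x_adv - x

        def hf_energy(p):
            spec = np.abs(np.fft.rfft(p, axis=-1)) ** 2
            cut = spec.shape[-1] // 4
            return spec[..., cut:].sum(axis=-1).mean()

        assert hf_energy(p_sap) <= hf_energy(p_pgd)

    def test_kernel_longer_than_signal_rejected(self, linear_model_factory):
        model = linear_model_factory(5)
        cfg = AttackConfig(sap_kernel=(7, 2.0), clip_range=None)
        with pytest.raises(ValueError, match="exceeds"):
            sap(model, np.zeros((1, 5)), np.array([0]), cfg)


def test_registry_rejects_unknown_attack():
    with pytest.raises(KeyError, match="unknown attack"):
        get_attack("rainbow")


def test_attacks_deterministic_given_seed(tiny_model, beats_dataset):
    x = beats_dataset.signals()[:4]
    y = beats_dataset.labels()[:4]
    cfg = AttackConfig(epsilon=0.05, steps=5, step_size=0.01, random_start=True,
                       clip_range=(-1.0, 1.0), seed=3)
    a = pgd(tiny_model, x, y, cfg)
    b = pgd(tiny_model, x, y, cfg)
    assert np.array_equal(a.x_adv, b.x_adv)
    assert np.array_equal(a.success, b.success)
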