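"""Loss identities, reductions, additivity, and the training-loop contract."""

import numpy as np
import pytest

from caslcnet.attacks import AttackConfig
from caslcnet.losses import (
    LossConfig,
    TrainConfig,
    at_loss,
    boosted_ce,
    cas_loss,
    ce_loss,
    mart_loss,
    total_loss,
    trades_loss,
    train,
)
from caslcnet.model import NetworkConfig, build_caslcnet
from caslcnet.nn import Tensor, softmax
from caslcnet.synth_ecg import generate_beats


def val(t):
    return float(t.data)


class TestBoostedCE:
    def test_one_hot_gives_zero(self):
        assert val(boosted_ce(np.array([0.0, 1.0, 0.0]), 1)) == pytest.approx(0.0, abs=1e-9)

    def test_hand_value_uniform_binary(self):
        assert val(boosted_ce(np.array([0.5, 0.5]), 0)) == pytest.approx(2 * np.log(2))

    def test_dominates_plain_cross_entropy(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.dirichlet(np.ones(5))
            y = rng.integers(5)
            assert val(boosted_ce(p, y)) >= val(ce_loss(p, y)) - 1e-12

    def test_zero_probability_clamped(self):
        out = val(boosted_ce(np.array([0.0, 0.5, 0.5]), 0))
        assert np.isfinite(out)


class TestMartLoss:
    def test_equal_distributions_reduce_to_bce(self):
        p = np.array([[0.7, 0.2, 0.1], [0.2, 0.5, 0.3]])
        y = np.array([0, 1])
        assert val(mart_loss(p, p, y, lam=5.0)) == pytest.approx(
            val(boosted_ce(p, y)), abs=1e-9
        )

    def test_confident_natural_prediction_zeroes_soft_factor(self):
        p_nat = np.array([[1.0, 0.0]])
        p_adv = np.array([[0.6, 0.4]])
        y = np.array([0])
        assert val(mart_loss(p_nat, p_adv, y, lam=7.0)) == pytest.approx(
            val(boosted_ce(p_adv, y)), abs=1e-6
        )

    def test_hand_computed_binary_case(self):
        p_nat = np.array([[0.8, 0.2]])
        p_adv = np.array([[0.6, 0.4]])
        y = np.array([0])
        lam = 5.0
        bce = -np.log(0.6) - np.log(1 - 0.4)
        kl = 0.8 * np.log(0.8 / 0.6) + 0.2 * np.log(0.2 / 0.4)
        expected = bce + lam * kl * (1 - 0.8)
        assert val(mart_loss(p_nat, p_adv, y, lam)) == pytest.approx(expected, abs=1e-9)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            mart_loss(np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]]),
                      np.array([0]), lam=-1.0)


class TestCasLoss:
    def _pairs(self, k=2, seed=0):
        rng = np.random.default_rng(seed)
        return [
            (Tensor(rng.dirichlet(np.ones(3), size=4)),
             Tensor(rng.dirichlet(np.ones(3), size=4)))
            for _ in range(k)
        ]

    def test_zero_alpha_gives_zero(self):
        pairs = self._pairs()
        y = np.array([0, 1, 2, 0])
        base = lambda p, q, yy, cfg: mart_loss(p, q, yy, 5.0)
        assert val(cas_loss(pairs, y, 0.0, base)) == 0.0

    def test_linear_in_alpha(self):
        pairs = self._pairs(seed=1)
        y = np.array([0, 1, 2, 0])
        base = lambda p, q, yy, cfg: mart_loss(p, q, yy, 5.0)
        one = val(cas_loss(pairs, y, 1.0, base))
        two = val(cas_loss(pairs, y, 2.0, base))
        assert two == pytest.approx(2 * one, abs=1e-12)

    def test_identical_heads_average_to_single_head(self):
        (p, q), = self._pairs(k=1, seed=2)
        y = np.array([0, 1, 2, 0])
        base = lambda pp, qq, yy, cfg: mart_loss(pp, qq, yy, 5.0)
        two_same = val(cas_loss([(p, q), (p, q)], y, 1.5, base))
        assert two_same == pytest.approx(1.5 * val(base(p, q, y, None)), abs=1e-12)

    def test_empty_head_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            cas_loss([], np.array([0]), 1.0, lambda *a: None)


class TestTotalLoss:
    def _batch(self, seed=0):
        rng = np.random.default_rng(seed)
        p_nat = Tensor(rng.dirichlet(np.ones(3), size=2))
        p_adv = Tensor(rng.dirichlet(np.ones(3), size=2))
        aux = [
            (Tensor(rng.dirichlet(np.ones(3), size=2)),
             Tensor(rng.dirichlet(np.ones(3), size=2)))
            for _ in range(2)
        ]
        y = np.array([0, 2])
        return p_nat, p_adv, aux, y

    def test_reduces_to_mart_without_cas_and_mse(self):
        p_nat, p_adv, aux, y = self._batch()
        cfg = LossConfig(name="mart", alpha=0.0, lam=5.0)
        assert val(total_loss((p_nat, p_adv), aux, y, cfg)) == pytest.approx(
            val(mart_loss(p_nat, p_adv, y, 5.0)), abs=1e-12
        )

    def test_perfect_natural_predictions_zero_mse_term(self):
        onehot = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([0, 1])
        cfg_with = LossConfig(name="mart", alpha=0.0, use_mse_aux=True)
        cfg_without = LossConfig(name="mart", alpha=0.0, use_mse_aux=False)
        p_adv = Tensor(np.array([[0.7, 0.3], [0.4, 0.6]]))
        a = val(total_loss((Tensor(onehot), p_adv), [], y, cfg_with))
        b = val(total_loss((Tensor(onehot), p_adv), [], y, cfg_without))
        assert a == pytest.approx(b, abs=1e-9)

    def test_additivity_of_three_terms(self):
        p_nat, p_adv, aux, y = self._batch(seed=3)
        lam, alpha = 5.0, 1.7
        cfg = LossConfig(name="mart", alpha=alpha, lam=lam, use_mse_aux=True)
        total = val(total_loss((p_nat, p_adv), aux, y, cfg))
        mart = val(mart_loss(p_nat, p_adv, y, lam))
        cas = val(cas_loss(aux, y, alpha,
                           lambda p, q, yy, c: mart_loss(p, q, yy, lam), cfg))
        onehot = np.zeros((2, 3))
        onehot[np.arange(2), y] = 1.0
        mse = float(((p_nat.data - onehot) ** 2).sum(axis=1).mean())
        assert total == pytest.approx(mart + cas + mse, abs=1e-9)

    def test_alpha_linearity_exact(self):
        p_nat, p_adv, aux, y = self._batch(seed=4)
        vals = [
            val(total_loss((p_nat, p_adv), aux, y,
                           LossConfig(name="mart", alpha=a)))
            for a in (0.0, 1.0, 2.0)
        ]
        assert vals[2] - vals[1] == pytest.approx(vals[1] - vals[0], abs=1e-9)


class TestTrades:
    def test_beta_zero_reduces_to_natural_ce(self):
        rng = np.random.default_rng(5)
        p_nat = Tensor(rng.dirichlet(np.ones(4), size=3))
        p_adv = Tensor(rng.dirichlet(np.ones(4), size=3))
        y = np.array([0, 3, 1])
        cfg = LossConfig(name="trades", beta=0.0)
        assert val(trades_loss(p_nat, p_adv, y, cfg)) == pytest.approx(
            val(ce_loss(p_nat, y)), abs=1e-12
        )

    def test_at_loss_ignores_natural_distribution(self):
        rng = np.random.default_rng(6)
        p_adv = Tensor(rng.dirichlet(np.ones(3), size=2))
        y = np.array([1, 2])
        a = val(at_loss(Tensor(rng.dirichlet(np.ones(3), size=2)), p_adv, y, LossConfig()))
        assert a == pytest.approx(val(ce_loss(p_adv, y)), abs=1e-12)


def test_losses_non_negative_and_mart_dominates_bce():
    rng = np.random.default_rng(7)
    for _ in range(50):
        p = Tensor(rng.dirichlet(np.ones(4), size=3))
        q = Tensor(rng.dirichlet(np.ones(4), size=3))
        y = rng.integers(4, size=3)
        m = val(mart_loss(p, q, y, lam=5.0))
        assert m >= -1e-12
        assert m >= val(boosted_ce(q, y)) - 1e-9


def test_h_gradient_linear_in_alpha():
    """Gradient reaching the CAS weights H decomposes into the reweighting
    path plus alpha times the auxiliary-loss path."""
    cfg = NetworkConfig.small_beats(seed=1)
    ds = generate_beats(4, 5, 187, seed=2)
    x, y = ds.signals(), ds.labels()

    def h_grad(alpha):
        model = build_caslcnet(cfg)  # same seed -> same init
        model.train()
        logits, aux = model.forward(x, labels=y)
        p = softmax(logits, axis=1)
        loss = total_loss((p, p), [(a, a) for a in aux], y,
                          LossConfig(name="mart", alpha=alpha))
        model.zero_grad()
        loss.backward()
        return [m.H.grad.copy() for m in model.cas_modules]

    g0, g1, g2 = h_grad(0.0), h_grad(1.0), h_grad(2.0)
    for a, b, c in zip(g0, g1, g2):
        assert np.allclose(c - b, b - a, atol=1e-9)
        # alpha=0 still reaches H through the reweighting path
        assert np.abs(a).max() > 0


def test_train_zero_epochs_leaves_model_unchanged():
    cfg = NetworkConfig.small_beats(seed=5)
    model = build_caslcnet(cfg)
    before = {k: v.copy() for k, v in model.state_dict().items()}
    ds = generate_beats(4, 5, 187, seed=6)
    _, history = train(model, ds, TrainConfig(epochs=0, batch_size=4))
    assert history == []
    for k, v in model.state_dict().items():
        assert np.array_equal(before[k], v)


def test_one_step_training_decreases_loss_and_records_history():
    cfg = NetworkConfig.small_beats(seed=7)
    model = build_caslcnet(cfg)
    ds = generate_beats(8, 5, 187, seed=8)
    inner = AttackConfig(epsilon=0.05, steps=2, step_size=0.01, seed=0,
                         clip_range=(-1.0, 1.0))
    tc = TrainConfig(loss=LossConfig(name="mart", inner_attack=inner),
                     epochs=2, batch_size=20, lr=1e-3, seed=9)
    _, history = train(model, ds, tc)
    assert len(history) == 2
    assert {"loss", "clean_accuracy", "robust_accuracy"} <= set(history[0])
    assert history[1]["loss"] < history[0]["loss"]
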