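"""Meta-training loop: closed-form toys, ERM reduction, schedule, determinism."""

import numpy as np
import pytest

from mfnet.autodiff import Tensor, grad
from mfnet.exceptions import ConfigError, InvalidInputError, TrainingDivergenceError
from mfnet.layers import SGD
from mfnet.losses_metrics import dice_loss
from mfnet.meta_trainer import (
    TrainConfig,
    evaluate,
    inner_update,
    meta_objective,
    poly_lr,
    train,
    train_one_seed,
)
from mfnet.seg_model import ModelConfig, build_model

TINY_MODEL = ModelConfig(base_channels=4, depth=2)


def quadratic(target):
    """Toy loss: L(theta) = (theta - target)^2 over a single scalar param."""

    def fn(params):
        d = params[0] - target
        return d * d

    return fn


class TestPolyLR:
    def test_start_is_base_lr(self):
        assert poly_lr(0, 100, 0.01, 0.9) == 0.01

    def test_end_is_zero(self):
        assert poly_lr(100, 100, 0.01, 0.9) == 0.0

    def test_printed_value(self):
        assert poly_lr(50, 100, 0.01, 0.9) == pytest.approx(0.005358867, abs=1e-8)

    def test_monotone_nonincreasing(self):
        vals = [poly_lr(t, 50, 0.1, 0.9) for t in range(51)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_clamps_beyond_end_with_warning(self):
        with pytest.warns(UserWarning):
            assert poly_lr(101, 100, 0.01, 0.9) == 0.0


class TestInnerUpdate:
    def test_zero_gamma_identity(self):
        theta = Tensor(1.0, requires_grad=True)
        adapted, _ = inner_update([theta], quadratic(0.0), inner_lr=0.0)
        assert adapted[0] is theta

    def test_closed_form_quadratic(self):
        # theta_hat = 1 - 0.1 * 2 * 1 = 0.8
        theta = Tensor(1.0, requires_grad=True)
        adapted, loss = inner_update([theta], quadratic(0.0), inner_lr=0.1)
        assert adapted[0].item() == pytest.approx(0.8)
        assert loss.item() == pytest.approx(1.0)
        assert theta.item() == 1.0  # original untouched

    def test_step_linear_in_gamma(self):
        theta = Tensor(1.0, requires_grad=True)
        a1, _ = inner_update([theta], quadratic(0.0), inner_lr=0.1)
        a2, _ = inner_update([theta], quadratic(0.0), inner_lr=0.2)
        d1 = theta.item() - a1[0].item()
        d2 = theta.item() - a2[0].item()
        assert d2 == pytest.approx(2 * d1)

    def test_nonfinite_loss_raises(self):
        theta = Tensor(np.inf, requires_grad=True)
        with pytest.raises(TrainingDivergenceError):
            inner_update([theta], quadratic(0.0), inner_lr=0.1)


class TestMetaObjective:
    def setup_method(self):
        self.config = TrainConfig(
            alpha=1.0, beta=1.0, inner_lr=0.1, seeds=(0,), epochs=1
        )

    def test_erm_limit(self):
        cfg = TrainConfig(alpha=1.0, beta=0.0, inner_lr=0.1, seeds=(0,), epochs=1)
        theta = Tensor(1.0, requires_grad=True)
        total, l_init, l_mix = meta_objective(
            [theta], quadratic(0.0), None, cfg
        )
        assert total.item() == pytest.approx(1.0)
        assert l_mix.item() == 0.0

    def test_closed_form_objective(self):
        # theta_hat = 0.8; L = 1^2 + 0.8^2 = 1.64
        theta = Tensor(1.0, requires_grad=True)
        total, l_init, l_mix = meta_objective(
            [theta], quadratic(0.0), quadratic(0.0), self.config
        )
        assert total.item() == pytest.approx(1.64)
        assert l_init.item() == pytest.approx(1.0)
        assert l_mix.item() == pytest.approx(0.64)

    def test_first_order_gradient(self):
        # d/dtheta [theta^2 + theta_hat^2] with theta_hat detached = 2*1 + 2*0.8
        theta = Tensor(1.0, requires_grad=True)
        total, _, _ = meta_objective(
            [theta], quadratic(0.0), quadratic(0.0), self.config
        )
        (g,) = grad(total, [theta])
        assert g.item() == pytest.approx(3.6, abs=1e-6)

    def test_second_order_gradient(self):
        # full: 2*theta + 2*theta_hat*(1 - 2*gamma) = 2 + 1.6*0.8 = 3.28
        cfg = TrainConfig(
            alpha=1.0, beta=1.0, inner_lr=0.1, second_order=True, seeds=(0,), epochs=1
        )
        theta = Tensor(1.0, requires_grad=True)
        total, _, _ = meta_objective([theta], quadratic(0.0), quadratic(0.0), cfg)
        (g,) = grad(total, [theta])
        assert g.item() == pytest.approx(3.28, abs=1e-6)

    def test_second_order_matches_finite_differences(self):
        cfg = TrainConfig(
            alpha=1.0, beta=1.0, inner_lr=0.1, second_order=True, seeds=(0,), epochs=1
        )

        def objective(theta_val):
            theta = Tensor(theta_val, requires_grad=True)
            total, _, _ = meta_objective([theta], quadratic(0.0), quadratic(0.0), cfg)
            return total.item()

        eps = 1e-6
        fd = (objective(1.0 + eps) - objective(1.0 - eps)) / (2 * eps)
        assert fd == pytest.approx(3.28, abs=1e-5)

    def test_sgd_step_from_closed_form(self):
        # momentum 0: theta <- 1 - lr * 3.6 in first-order mode
        theta = Tensor(1.0, requires_grad=True)
        opt = SGD([theta], lr=0.05, momentum=0.0, weight_decay=0.0)
        total, _, _ = meta_objective(
            [theta], quadratic(0.0), quadratic(0.0), self.config
        )
        gs = grad(total, [theta])
        opt.step(gs)
        assert theta.item() == pytest.approx(1.0 - 0.05 * 3.6)


class TestTrainConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigError):
            TrainConfig(base_lr=0.0)
        with pytest.raises(ConfigError):
            TrainConfig(momentum=1.0)
        with pytest.raises(ConfigError):
            TrainConfig(seeds=())
        with pytest.raises(ConfigError):
            TrainConfig(epochs=0)

    def test_dict_roundtrip(self):
        cfg = TrainConfig(seeds=(1, 2), lam_range=(0.1, 0.9))
        assert TrainConfig.from_dict(cfg.to_dict()) == cfg


def _plain_reference_training(seed, images, model_config, config):
    """Independent plain Dice-loss loop mirroring the documented recipe."""
    model = build_model(model_config, seed)
    params = model.parameters()
    velocity = [np.zeros(p.shape) for p in params]
    rng_data = np.random.default_rng([seed, 17])
    steps_per_epoch = (len(images) + config.batch_size - 1) // config.batch_size
    total_steps = config.epochs * steps_per_epoch
    step = 0
    for _ in range(config.epochs):
        order = rng_data.permutation(len(images))
        shuffled = [images[i] for i in order]
        for i in range(0, len(shuffled), config.batch_size):
            batch = shuffled[i : i + config.batch_size]
            x = np.stack([b.pixels for b in batch])[:, None]
            y = np.stack([b.mask for b in batch])[:, None]
            loss = config.alpha * dice_loss(model(Tensor(x)), y, eps=config.dice_eps)
            gs = grad(loss, params)
            lr = config.base_lr * (1 - step / total_steps) ** config.poly_power
            for p, g, v in zip(params, gs, velocity):
                gd = g.data + config.weight_decay * p.data
                v *= config.momentum
                v += gd
                p.data -= lr * v
            step += 1
    return model


class TestTraining:
    def _config(self, **kw):
        base = dict(
            epochs=2, seeds=(0,), batch_size=4, base_lr=0.1, inner_lr=0.02,
            eval_every=0,
        )
        base.update(kw)
        return TrainConfig(**base)

    def test_erm_reduction_bit_identical(self, tiny_images_a):
        cfg = self._config(beta=0.0, epochs=3)
        model, _ = train_one_seed(0, tiny_images_a, [], TINY_MODEL, cfg)
        ref = _plain_reference_training(0, tiny_images_a, TINY_MODEL, cfg)
        for a, b in zip(model.parameters(), ref.parameters()):
            np.testing.assert_array_equal(a.data, b.data)

    def test_same_seed_identical_parameters(self, tiny_images_a):
        cfg = self._config(beta=1.0)
        m1, h1 = train_one_seed(1, tiny_images_a, [], TINY_MODEL, cfg)
        m2, h2 = train_one_seed(1, tiny_images_a, [], TINY_MODEL, cfg)
        for a, b in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a.data, b.data)
        for e1, e2 in zip(h1.epochs, h2.epochs):
            assert e1["loss"] == e2["loss"]
            assert e1["loss_init"] == e2["loss_init"]
            assert e1["loss_mix"] == e2["loss_mix"]

    def test_lr_schedule_recorded_exactly(self, tiny_images_a):
        cfg = self._config(epochs=2)
        _, history = train_one_seed(0, tiny_images_a, [], TINY_MODEL, cfg)
        steps_per_epoch = (len(tiny_images_a) + cfg.batch_size - 1) // cfg.batch_size
        total = cfg.epochs * steps_per_epoch
        expected = [
            poly_lr(t, total, cfg.base_lr, cfg.poly_power) for t in range(total)
        ]
        assert history.lr_per_step == expected

    def test_single_step_bookkeeping(self, tiny_images_a):
        cfg = self._config(epochs=1, batch_size=4)
        _, history = train_one_seed(0, tiny_images_a[:4], [], TINY_MODEL, cfg)
        assert len(history.lr_per_step) == 1
        assert len(history.epochs) == 1

    def test_multi_seed_averaging(self, tiny_images_a):
        cfg = self._config(seeds=(0, 1, 2), epochs=1, eval_every=1)
        val = tiny_images_a[:3]
        result = train(tiny_images_a[3:], val, TINY_MODEL, cfg)
        assert len(result.histories) == 3
        per_seed = [r.dice_mean for r in result.val_reports.values()]
        assert result.mean_val_dice == pytest.approx(np.mean(per_seed))

    def test_loss_decreases_on_small_task(self, tiny_images_a):
        cfg = self._config(epochs=8, seeds=(0, 1, 2), base_lr=0.3, beta=1.0)
        improved = 0
        for seed in cfg.seeds:
            _, history = train_one_seed(seed, tiny_images_a, [], TINY_MODEL, cfg)
            if history.epochs[-1]["loss_init"] < history.epochs[0]["loss_init"]:
                improved += 1
        assert improved >= 2

    def test_empty_dataset_rejected(self):
        with pytest.raises(InvalidInputError):
            train_one_seed(0, [], [], TINY_MODEL, self._config())

    def test_history_and_outputs_written(self, tiny_images_a, tmp_path):
        cfg = self._config(epochs=1, eval_every=1)
        train(tiny_images_a[3:], tiny_images_a[:3], TINY_MODEL, cfg, out_dir=tmp_path)
        assert (tmp_path / "history_seed0.csv").exists()
        assert (tmp_path / "model_seed0.npz").exists()
        assert (tmp_path / "summary.json").exists()

    def test_evaluate_modes(self, tiny_images_a):
        model = build_model(TINY_MODEL, seed=0).eval()
        rep_fg = evaluate(model, tiny_images_a[:3], miou_mode="foreground")
        rep_2c = evaluate(model, tiny_images_a[:3], miou_mode="two_class")
        for r in rep_fg.per_image:
            assert r.iou <= r.dice + 1e-12
        assert rep_2c.miou >= rep_fg.miou
        with pytest.raises(InvalidInputError):
            evaluate(model, tiny_images_a[:3], miou_mode="bogus")
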