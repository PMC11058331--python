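"""Two-task meta-training loop.

One step:  (1) evaluate the Dice loss on an original batch at the
current parameters; (2) take a single plain gradient step of size
``inner_lr`` to obtain adapted parameters; (3) evaluate the Dice loss of
an amplitude-mixed batch at the adapted parameters; (4) optimize the
weighted sum ``alpha * L_init + beta * L_mix`` with SGD (momentum,
weight decay, polynomial learning-rate decay).

With ``beta = 0`` the loop reduces exactly — step for step — to plain
Dice-loss training, which serves as the ERM baseline.  The meta-gradient
is first-order by default (the adapted parameters are treated as
constants with respect to the inner gradient); ``second_order=True``
back-propagates through the inner step.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, grad
from .data_io import DataStreams, ModalityImage
from .exceptions import ConfigError, InvalidInputError, TrainingDivergenceError
from .layers import SGD
from .losses_metrics import (
    MetricsReport,
    PerImageResult,
    aggregate,
    dice_coefficient,
    dice_loss,
    iou,
    two_class_iou,
)
from .seg_model import ModelConfig, UNet, build_model

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "TrainResult",
    "poly_lr",
    "inner_update",
    "meta_objective",
    "train_step",
    "train",
    "evaluate",
]


@dataclass(frozen=True)
class TrainConfig:
    """All training hyperparameters.

    Defaults follow the full-scale recipe (SGD momentum 0.9, weight
    decay 5e-4, batch 4, polynomial decay with power 0.9); desk runs
    shrink epochs/seeds, not the update rule.
    """

    alpha: float = 1.0
    beta: float = 1.0
    inner_lr: float = 0.01
    base_lr: float = 0.01
    poly_power: float = 0.9
    momentum: float = 0.9
    weight_decay: float = 5e-4
    batch_size: int = 4
    epochs: int = 30
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    second_order: bool = False
    lam_range: tuple[float, float] = (0.0, 1.0)
    dice_eps: float = 1e-6
    eval_every: int = 1

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ConfigError("alpha and beta must be non-negative")
        if self.inner_lr < 0 or self.base_lr <= 0 or self.poly_power <= 0:
            raise ConfigError("learning rates and poly_power must be positive")
        if not (0.0 <= self.momentum < 1.0) or self.weight_decay < 0:
            raise ConfigError("invalid momentum or weight decay")
        if self.epochs < 1 or self.batch_size < 1 or not self.seeds:
            raise ConfigError("epochs/batch_size must be >= 1 and seeds non-empty")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        for key in ("seeds", "lam_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TrainHistory:
    """Per-epoch loss records plus the exact learning rate per step."""

    epochs: list[dict] = field(default_factory=list)
    lr_per_step: list[float] = field(default_factory=list)

    def record_epoch(self, **kwargs) -> None:
        self.epochs.append(dict(kwargs))

    def to_csv(self, path) -> None:
        if not self.epochs:
            return
        keys = list(self.epochs[0].keys())
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(self.epochs)


@dataclass
class TrainResult:
    models: dict[int, UNet]
    histories: dict[int, TrainHistory]
    val_reports: dict[int, MetricsReport]
    mean_val_dice: float
    mean_val_miou: float


def poly_lr(step: int, total_steps: int, base_lr: float, power: float) -> float:
    """Polynomial decay ``base_lr * (1 - step/total_steps)**power``."""
    if total_steps <= 0:
        raise InvalidInputError("total_steps must be positive")
    if step < 0:
        raise InvalidInputError("step must be non-negative")
    if step > total_steps:
        warnings.warn(
            f"poly_lr: step {step} beyond total_steps {total_steps}; clamping to 0",
            stacklevel=2,
        )
        return 0.0
    return float(base_lr * (1.0 - step / total_steps) ** power)


def _check_finite(loss: Tensor, context: str) -> None:
    if not np.all(np.isfinite(loss.data)):
        raise TrainingDivergenceError(f"non-finite loss at {context}")


def inner_update(
    params: list[Tensor],
    loss_fn,
    inner_lr: float,
    second_order: bool = False,
    context: str = "inner step",
):
    """One plain gradient step: ``adapted = p - inner_lr * dL/dp``.

    ``loss_fn(params)`` must return a scalar Tensor.  The input
    parameters are never modified.  Returns ``(adapted_params, loss)``;
    with ``second_order=True`` the adapted parameters keep their
    differentiable dependence on the originals.
    """
    loss = loss_fn(params)
    _check_finite(loss, context)
    if inner_lr == 0.0:
        return list(params), loss
    gs = grad(loss, params, create_graph=second_order)
    if not second_order:
        gs = [g.detach() for g in gs]
    for g in gs:
        if not np.all(np.isfinite(g.data)):
            raise TrainingDivergenceError(f"non-finite gradient at {context}")
    adapted = [p - float(inner_lr) * g for p, g in zip(params, gs)]
    return adapted, loss


def meta_objective(
    params: list[Tensor],
    loss_init_fn,
    loss_mix_fn,
    config: TrainConfig,
    context: str = "meta step",
):
    """Combined objective ``alpha * L_init + beta * L_mix``.

    ``L_init`` is evaluated at the current parameters on the original
    task; ``L_mix`` at the one-step-adapted parameters on the mixed
    task.  With ``beta = 0`` the mixed branch (including the inner
    update) is skipped entirely, so the ERM baseline is this same code
    path.
    """
    if config.beta == 0.0:
        l_init = loss_init_fn(params)
        _check_finite(l_init, context)
        total = config.alpha * l_init
        return total, l_init, Tensor(0.0)
    adapted, l_init = inner_update(
        params,
        loss_init_fn,
        config.inner_lr,
        second_order=config.second_order,
        context=context,
    )
    l_mix = loss_mix_fn(adapted)
    _check_finite(l_mix, context)
    total = config.alpha * l_init + config.beta * l_mix
    return total, l_init, l_mix


def _batch_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([s.pixels if hasattr(s, "pixels") else s.image for s in samples])
    ys = np.stack([s.mask for s in samples])
    return xs[:, None, :, :].astype(np.float64), ys[:, None, :, :].astype(np.float64)


def _model_loss_fn(model: UNet, x: np.ndarray, y: np.ndarray, eps: float):
    xt = Tensor(x)

    def fn(params):
        pred = model(xt, params)
        return dice_loss(pred, y, eps=eps)

    return fn


def train_step(
    model: UNet,
    optimizer: SGD,
    orig_batch,
    mixed_batch,
    config: TrainConfig,
    lr: float,
    context: str = "step",
) -> tuple[float, float, float]:
    """One SGD step on the combined objective; returns (L, L_init, L_mix)."""
    params = model.parameters()
    ox, oy = _batch_arrays(orig_batch)
    loss_init_fn = _model_loss_fn(model, ox, oy, config.dice_eps)
    if config.beta == 0.0 or not mixed_batch:
        loss_mix_fn = None
        cfg = config if config.beta == 0.0 else TrainConfig(**{**config.to_dict(), "beta": 0.0})
        total, l_init, l_mix = meta_objective(params, loss_init_fn, loss_mix_fn, cfg, context)
    else:
        mx, my = _batch_arrays(mixed_batch)
        loss_mix_fn = _model_loss_fn(model, mx, my, config.dice_eps)
        total, l_init, l_mix = meta_objective(params, loss_init_fn, loss_mix_fn, config, context)
    gs = grad(total, params)
    for g in gs:
        if not np.all(np.isfinite(g.data)):
            raise TrainingDivergenceError(f"non-finite update at {context}")
    optimizer.lr = lr
    optimizer.step(gs)
    return float(total.data), float(l_init.data), float(l_mix.data)


def _batches(items, batch_size):
    for i in range(0, len(items), batch_size):
        yield items[i : i + batch_size]


def train_one_seed(
    seed: int,
    train_images: list[ModalityImage],
    val_images: list[ModalityImage],
    model_config: ModelConfig,
    config: TrainConfig,
) -> tuple[UNet, TrainHistory]:
    """One full training run; fully deterministic in ``seed``."""
    if not train_images:
        raise InvalidInputError("empty training set")
    model = build_model(model_config, seed)
    optimizer = SGD(
        model.parameters(),
        lr=config.base_lr,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
    )
    rng_data = np.random.default_rng([seed, 17])
    rng_mix = np.random.default_rng([seed, 31])
    streams = DataStreams(
        train_images, rng_data, lam_range=config.lam_range
    )
    streams_mix_rng = rng_mix  # mixing draws come from their own generator
    history = TrainHistory()
    steps_per_epoch = (len(train_images) + config.batch_size - 1) // config.batch_size
    total_steps = config.epochs * steps_per_epoch
    global_step = 0
    for epoch in range(config.epochs):
        model.train()
        order = rng_data.permutation(len(train_images))
        originals = [train_images[i] for i in order]
        if config.beta != 0.0:
            saved_rng = streams.rng
            streams.rng = streams_mix_rng
            mixed = [
                m
                for m in (streams._sample_mixed(im) for im in originals)
                if m is not None
            ]
            streams.rng = saved_rng
        else:
            mixed = []
        l_tot = l_in = l_mx = 0.0
        mixed_batches = list(_batches(mixed, config.batch_size)) if mixed else []
        for bi, ob in enumerate(_batches(originals, config.batch_size)):
            mb = mixed_batches[bi % len(mixed_batches)] if mixed_batches else []
            lr = poly_lr(global_step, total_steps, config.base_lr, config.poly_power)
            history.lr_per_step.append(lr)
            lt, li, lm = train_step(
                model,
                optimizer,
                ob,
                mb,
                config,
                lr,
                context=f"epoch {epoch} step {bi} (seed {seed})",
            )
            l_tot += lt
            l_in += li
            l_mx += lm
            global_step += 1
        val_dice = float("nan")
        if val_images and config.eval_every and (epoch + 1) % config.eval_every == 0:
            val_dice = evaluate(model, val_images, batch_size=config.batch_size).dice_mean
        history.record_epoch(
            epoch=epoch,
            loss=l_tot / steps_per_epoch,
            loss_init=l_in / steps_per_epoch,
            loss_mix=l_mx / steps_per_epoch,
            lr=history.lr_per_step[-1],
            val_dice=val_dice,
        )
        logger.info(
            "seed %d epoch %d: L=%.4f L_init=%.4f L_mix=%.4f val_dice=%s",
            seed, epoch, l_tot / steps_per_epoch, l_in / steps_per_epoch,
            l_mx / steps_per_epoch, f"{val_dice:.4f}",
        )
    return model, history


def train(
    train_images: list[ModalityImage],
    val_images: list[ModalityImage],
    model_config: ModelConfig,
    config: TrainConfig,
    out_dir=None,
) -> TrainResult:
    """Train once per seed and average validation metrics across seeds."""
    models, histories, reports = {}, {}, {}
    for seed in config.seeds:
        model, history = train_one_seed(
            seed, train_images, val_images, model_config, config
        )
        models[seed] = model
        histories[seed] = history
        if val_images:
            reports[seed] = evaluate(model, val_images, batch_size=config.batch_size)
    if reports:
        mean_dice = float(np.mean([r.dice_mean for r in reports.values()]))
        mean_miou = float(np.mean([r.miou for r in reports.values()]))
    else:
        mean_dice = mean_miou = float("nan")
    result = TrainResult(
        models=models,
        histories=histories,
        val_reports=reports,
        mean_val_dice=mean_dice,
        mean_val_miou=mean_miou,
    )
    if out_dir is not None:
        _write_outputs(result, config, out_dir)
    return result


def _write_outputs(result: TrainResult, config: TrainConfig, out_dir) -> None:
    from .seg_model import save_checkpoint

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for seed, history in result.histories.items():
        history.to_csv(out_dir / f"history_seed{seed}.csv")
        save_checkpoint(result.models[seed], out_dir / f"model_seed{seed}.npz")
    summary = {
        "config": config.to_dict(),
        "mean_val_dice": result.mean_val_dice,
        "mean_val_miou": result.mean_val_miou,
        "per_seed_val_dice": {
            str(s): r.dice_mean for s, r in result.val_reports.items()
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))


def evaluate(
    model: UNet,
    images: list[ModalityImage],
    batch_size: int = 8,
    threshold: float = 0.5,
    miou_mode: str = "foreground",
) -> MetricsReport:
    """Hard-threshold predictions and aggregate Dice / mean IoU.

    ``miou_mode='two_class'`` averages foreground and background IoU per
    image instead of the foreground IoU alone.
    """
    if not images:
        raise InvalidInputError("empty evaluation set")
    if miou_mode not in ("foreground", "two_class"):
        raise InvalidInputError(f"unknown miou_mode {miou_mode!r}")
    was_training = model.training
    model.eval()
    rows = []
    for batch in _batches(images, batch_size):
        x, _ = _batch_arrays(batch)
        pred = model(Tensor(x)).data
        for im, p in zip(batch, pred):
            pm = (p[0] >= threshold).astype(np.float64)
            d = dice_coefficient(pm, im.mask)
            i = (
                iou(pm, im.mask)
                if miou_mode == "foreground"
                else two_class_iou(pm, im.mask)
            )
            rows.append(
                PerImageResult(
                    case_id=im.case_id, modality_id=im.modality_id, dice=d, iou=i
                )
            )
    if was_training:
        model.train()
    return aggregate(rows)
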