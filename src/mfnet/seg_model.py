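"""U-Net segmentation backbone producing per-pixel foreground probabilities.

Classic 2-convolutions-per-stage encoder/decoder with batch
normalization, 2x2 max pooling, bilinear upsampling and skip
connections; a 1x1 convolution plus sigmoid head yields a single-channel
probability map.  Two ready-made profiles are provided: a desk-scale
configuration small enough for CPU testing and the full-scale one
(base 64, depth 4, 512x512 inputs).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, sigmoid
from .exceptions import ConfigError, InvalidInputError
from .layers import (
    BatchNorm2d,
    Conv2d,
    Module,
    ReLU,
    Sequential,
    concat,
    maxpool2x2,
    upsample_bilinear2x,
)

__all__ = [
    "ModelConfig",
    "UNet",
    "build_model",
    "forward",
    "parameter_count",
    "save_checkpoint",
    "load_checkpoint",
    "DESK_CONFIG",
    "FULL_SCALE_CONFIG",
]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 1
    base_channels: int = 16
    depth: int = 3
    out_channels: int = 1

    def __post_init__(self):
        if self.in_channels < 1 or self.base_channels < 1 or self.depth < 1:
            raise ConfigError(f"invalid model config: {self}")
        if self.out_channels != 1:
            raise ConfigError("only single-channel (binary) output is supported")

    def validate_spatial(self, h: int, w: int) -> None:
        div = 2**self.depth
        if h % div or w % div:
            raise ConfigError(
                f"input size {h}x{w} not divisible by 2^depth = {div}"
            )


DESK_CONFIG = ModelConfig(base_channels=16, depth=3)
FULL_SCALE_CONFIG = ModelConfig(base_channels=64, depth=4)


def _double_conv(cin: int, cout: int, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, 3, rng),
        BatchNorm2d(cout),
        ReLU(),
        Conv2d(cout, cout, 3, rng),
        BatchNorm2d(cout),
        ReLU(),
    )


class UNet(Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        b, d = config.base_channels, config.depth
        self.enc = [_double_conv(config.in_channels, b, rng)]
        for i in range(d):
            self.enc.append(_double_conv(b * 2**i, b * 2 ** (i + 1), rng))
        self.dec = []
        for i in range(d, 0, -1):
            cin = b * 2**i + b * 2 ** (i - 1)  # upsampled + skip
            self.dec.append(_double_conv(cin, b * 2 ** (i - 1), rng))
        self.head = Conv2d(b, config.out_channels, 1, rng, pad=0)
        self._training = True

    # -- mode handling (batch-norm statistics) ------------------------------
    def train(self) -> "UNet":
        self._set_training(True)
        return self

    def eval(self) -> "UNet":
        self._set_training(False)
        return self

    def _set_training(self, flag: bool) -> None:
        self._training = flag
        for seq in self.enc + self.dec:
            for m in seq.modules:
                if isinstance(m, BatchNorm2d):
                    m.training = flag

    @property
    def training(self) -> bool:
        return self._training

    def parameters(self) -> list[Tensor]:
        ps = [p for seq in self.enc for p in seq.parameters()]
        ps += [p for seq in self.dec for p in seq.parameters()]
        ps += self.head.parameters()
        return ps

    def bn_state(self) -> list[np.ndarray]:
        state = []
        for seq in self.enc + self.dec:
            for m in seq.modules:
                if isinstance(m, BatchNorm2d):
                    state += [m.running_mean.copy(), m.running_var.copy()]
        return state

    def set_bn_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for seq in self.enc + self.dec:
            for m in seq.modules:
                if isinstance(m, BatchNorm2d):
                    m.running_mean = np.array(next(it))
                    m.running_var = np.array(next(it))

    def forward(self, x: Tensor, params) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 4:
            raise InvalidInputError(
                f"expected a (N, C, H, W) batch, got shape {x.shape}"
            )
        self.config.validate_spatial(x.shape[2], x.shape[3])
        skips = []
        h = self.enc[0].forward(x, params)
        for stage in self.enc[1:]:
            skips.append(h)
            h = stage.forward(maxpool2x2(h), params)
        for stage, skip in zip(self.dec, reversed(skips)):
            h = upsample_bilinear2x(h)
            h = stage.forward(concat([skip, h], axis=1), params)
        logits = self.head.forward(h, params)
        return sigmoid(logits)


def build_model(config: ModelConfig, seed: int) -> UNet:
    """Instantiate a U-Net with parameters reproducibly drawn from ``seed``."""
    rng = np.random.default_rng(seed)
    return UNet(config, rng)


def forward(model: UNet, batch) -> Tensor:
    """Probability maps for a batch of images (arrays or a Tensor)."""
    if not isinstance(batch, Tensor):
        batch = Tensor(np.asarray(batch, dtype=np.float64))
    return model(batch)


def parameter_count(model: UNet) -> int:
    return sum(p.size for p in model.parameters())


def save_checkpoint(model: UNet, path) -> None:
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    arrays.update({f"bn_{i}": a for i, a in enumerate(model.bn_state())})
    np.savez(
        path,
        config=np.frombuffer(
            json.dumps(asdict(model.config)).encode(), dtype=np.uint8
        ),
        **arrays,
    )


def load_checkpoint(path) -> UNet:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["config"]).decode()))
        model = build_model(cfg, seed=0)
        params = model.parameters()
        for i, p in enumerate(params):
            p.data = data[f"param_{i}"].astype(np.float64)
        bn = []
        i = 0
        while f"bn_{i}" in data:
            bn.append(data[f"bn_{i}"].astype(np.float64))
            i += 1
        model.set_bn_state(bn)
    return model.eval()
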