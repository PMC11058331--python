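"""Soft Dice training loss and Dice / mean-IoU evaluation metrics."""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, tsum
from .exceptions import InvalidInputError, RangeError

__all__ = [
    "dice_loss",
    "dice_coefficient",
    "iou",
    "two_class_iou",
    "aggregate",
    "MetricsReport",
    "PerImageResult",
]


def dice_loss(pred, gt, eps: float = 1e-6):
    """Soft Dice loss ``1 - (2*sum(p*g) + eps) / (sum(p^2) + sum(g^2) + eps)``.

    ``pred`` holds per-pixel foreground probabilities in [0, 1] and may be
    an autodiff :class:`Tensor` (the loss is then differentiable w.r.t. it)
    or a plain array.  ``gt`` is a binary mask.  The ``eps`` smoothing term
    keeps the loss defined when both prediction and mask are empty; with
    ``eps=0`` and binary ``pred`` the loss is exactly
    ``1 - dice_coefficient``.
    """
    is_tensor = isinstance(pred, Tensor)
    p_data = pred.data if is_tensor else np.asarray(pred, dtype=np.float64)
    g = np.asarray(gt, dtype=np.float64)
    if p_data.shape != g.shape:
        raise InvalidInputError(
            f"pred shape {p_data.shape} != gt shape {g.shape}"
        )
    if p_data.size and (p_data.min() < -1e-12 or p_data.max() > 1 + 1e-12):
        raise RangeError("pred values must lie in [0, 1]")
    if not np.all(np.isin(g, (0.0, 1.0))):
        raise InvalidInputError("gt must be binary")
    if eps < 0:
        raise RangeError("eps must be non-negative")
    if is_tensor:
        gt_t = Tensor(g)
        num = 2.0 * tsum(pred * gt_t) + eps
        den = tsum(pred * pred) + tsum(gt_t * gt_t) + eps
        return 1.0 - num / den
    num = 2.0 * float((p_data * g).sum()) + eps
    den = float((p_data**2).sum() + (g**2).sum()) + eps
    if den == 0.0:
        return 0.0  # eps = 0 and both empty: perfect (vacuous) agreement
    return 1.0 - num / den


def _check_binary_pair(pred_mask, gt_mask):
    p = np.asarray(pred_mask, dtype=np.float64)
    g = np.asarray(gt_mask, dtype=np.float64)
    if p.shape != g.shape:
        raise InvalidInputError(f"mask shapes differ: {p.shape} vs {g.shape}")
    for name, arr in (("pred_mask", p), ("gt_mask", g)):
        if not np.all(np.isin(arr, (0.0, 1.0))):
            raise InvalidInputError(f"{name} must be binary")
    return p.astype(bool), g.astype(bool)


def dice_coefficient(pred_mask, gt_mask) -> float:
    """Hard Dice overlap ``2|gt ∩ pred| / (|gt| + |pred|)``; empty/empty -> 1."""
    p, g = _check_binary_pair(pred_mask, gt_mask)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def iou(pred_mask, gt_mask) -> float:
    """Foreground intersection-over-union ``|gt ∩ pred| / |gt ∪ pred|``."""
    p, g = _check_binary_pair(pred_mask, gt_mask)
    union = int((p | g).sum())
    if union == 0:
        return 1.0
    return int((p & g).sum()) / union


def two_class_iou(pred_mask, gt_mask) -> float:
    """Mean of foreground and background IoU (two-class mean IoU).

    Provided as an alternative aggregate because some reported "mIoU"
    figures include the background class, which can exceed the Dice score
    of the foreground alone.
    """
    p, g = _check_binary_pair(pred_mask, gt_mask)
    fg = iou(p.astype(float), g.astype(float))
    bg = iou((~p).astype(float), (~g).astype(float))
    return 0.5 * (fg + bg)


@dataclass(frozen=True)
class PerImageResult:
    case_id: str
    modality_id: str
    dice: float
    iou: float


@dataclass(frozen=True)
class MetricsReport:
    """Per-image Dice/IoU rows plus per-modality and overall means."""

    per_image: list[PerImageResult]
    dice_mean: float
    miou: float
    n_images: int
    per_modality: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["case_id", "modality_id", "dice", "iou"])
            for r in self.per_image:
                writer.writerow([r.case_id, r.modality_id, f"{r.dice:.6f}", f"{r.iou:.6f}"])

    def to_json(self, path) -> None:
        summary = {
            "n_images": self.n_images,
            "dice_mean": self.dice_mean,
            "miou": self.miou,
            "per_modality": self.per_modality,
        }
        Path(path).write_text(json.dumps(summary, indent=2))


def aggregate(per_image: list[PerImageResult]) -> MetricsReport:
    """Arithmetic means of the per-image columns, overall and per modality."""
    if not per_image:
        raise InvalidInputError("aggregate requires at least one per-image result")
    dice_mean = float(np.mean([r.dice for r in per_image]))
    miou = float(np.mean([r.iou for r in per_image]))
    per_modality: dict[str, dict[str, float]] = {}
    for mod in sorted({r.modality_id for r in per_image}):
        rows = [r for r in per_image if r.modality_id == mod]
        per_modality[mod] = {
            "dice_mean": float(np.mean([r.dice for r in rows])),
            "miou": float(np.mean([r.iou for r in rows])),
            "n_images": len(rows),
        }
    return MetricsReport(
        per_image=list(per_image),
        dice_mean=dice_mean,
        miou=miou,
        n_images=len(per_image),
        per_modality=per_modality,
    )
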