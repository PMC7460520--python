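"""Encoder-decoder segmentation of uterus and endometrial lesion.

One multi-output U-Net predicts both structures (independent sigmoids per
channel; lesion containment in the uterus is enforced after thresholding).
Training uses stochastic gradient descent on the soft-Dice loss, with the
best-validation-loss checkpoint retained as the final model. Evaluation is
by Intersection over Union.

Encoder families reproduce the architectural pattern of the study's
candidates (plain VGG-style stacks of 1 or 2 convolutions per stage, or
residual blocks for the ResNet-style encoder) at desk-scale channel widths;
ImageNet-pretrained weights are intentionally unsupported — initialization
is always random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._nn import SGD, UNet

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "SegmentationOutput",
    "MetricRecord",
    "dice_loss",
    "dice_coefficient",
    "iou",
    "build_model",
    "train",
    "predict_masks",
    "TrainingDivergedError",
]

STRUCTURES = ("uterus", "lesion")

DICE_EPS = 1.0  # smoothing term in the soft-Dice loss

#: family -> (channel multipliers, convs per stage, residual, default base)
_FAMILIES: dict[str, tuple[tuple[int, ...], int, bool, int]] = {
    "tiny": ((1, 2, 4), 1, False, 8),
    "vgg11-like": ((1, 2, 4, 8), 1, False, 16),
    "vgg16-like": ((1, 2, 4, 8), 2, False, 16),
    "resnet34-like": ((1, 2, 4, 8), 2, True, 16),
}


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class ModelSpec:
    encoder_family: str = "tiny"
    base_channels: int | None = None
    in_channels: int = 1
    structures: tuple[str, ...] = STRUCTURES
    pretrained: bool = False

    def validate(self) -> None:
        if self.encoder_family not in _FAMILIES:
            raise ValueError(
                f"unsupported encoder family {self.encoder_family!r}; "
                f"choose from {sorted(_FAMILIES)}"
            )
        if self.pretrained:
            raise ValueError(
                "pretrained encoder weights are not available in this "
                "offline implementation; use random initialization"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults follow the study's settings."""

    batch_size: int = 16
    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 150
    clip_norm: float | None = 1.0  # global gradient-norm clip; None disables
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")


@dataclass
class SegmentationOutput:
    case_id: str
    probabilities: dict[str, np.ndarray]  # structure -> float map in [0,1]
    masks: dict[str, np.ndarray]  # structure -> bool mask
    flags: list[str] = field(default_factory=list)


@dataclass
class MetricRecord:
    iou: dict[str, float]
    dice: dict[str, float]
    curves: pd.DataFrame | None = None  # epoch, train_loss, val_loss, val IoUs
    best_epoch: int | None = None


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice_coefficient(pred: np.ndarray, target: np.ndarray,
                     eps: float = DICE_EPS) -> float:
    """Soft Dice 2|A.B|/(|A|+|B|), smoothed by ``eps`` in both terms."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    _check_shapes(pred, target)
    inter = float((pred * target).sum())
    return (2.0 * inter + eps) / (float(pred.sum()) + float(target.sum()) + eps)


def dice_loss(prob_map: np.ndarray, target_mask: np.ndarray,
              eps: float = DICE_EPS) -> float:
    """Soft-Dice training loss ``1 - Dice``; lies in [0, 1)."""
    return 1.0 - dice_coefficient(prob_map, target_mask, eps)


def iou(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Intersection over Union of two binary masks.

    Two empty masks agree perfectly on absence and score 1.0.
    """
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(true_mask).astype(bool)
    _check_shapes(a, b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def _batch_dice_loss_grad(probs: np.ndarray, targets: np.ndarray,
                          eps: float = DICE_EPS) -> tuple[float, np.ndarray]:
    """Mean per-sample per-structure soft-Dice loss and its gradient."""
    p = probs.astype(np.float64)
    t = targets.astype(np.float64)
    inter = (p * t).sum(axis=(2, 3))
    sums = p.sum(axis=(2, 3)) + t.sum(axis=(2, 3)) + eps
    dice = (2.0 * inter + eps) / sums
    loss = float(np.mean(1.0 - dice))
    # d(1 - dice)/dp = -(2 t sums - (2 inter + eps)) / sums^2
    num = 2.0 * t * sums[:, :, None, None] - (2.0 * inter + eps)[:, :, None, None]
    grad = -num / (sums ** 2)[:, :, None, None]
    grad /= p.shape[0] * p.shape[1]
    return loss, grad.astype(np.float32)


# ---------------------------------------------------------------------------
# model construction and training
# ---------------------------------------------------------------------------

def build_model(spec: ModelSpec, seed: int = 0) -> UNet:
    """Instantiate the U-Net described by ``spec`` with He-initialized weights."""
    spec.validate()
    mults, n_convs, residual, default_base = _FAMILIES[spec.encoder_family]
    base = spec.base_channels or default_base
    channels = tuple(base * m for m in mults)
    rng = np.random.default_rng(seed)
    model = UNet(spec.in_channels, len(spec.structures), channels, n_convs,
                 rng, residual=residual)
    # Start predictions near-empty (p ~ 0.12): a sigmoid head initialized at
    # p ~ 0.5 sits next to the all-ones attractor of the Dice loss, where
    # large structures can plateau for many epochs.
    model.head.b[:] = -2.0
    model.spec = spec
    return model


def _as_batches(n: int, batch_size: int, rng: np.random.Generator | None):
    idx = np.arange(n)
    if rng is not None:
        rng.shuffle(idx)
    for start in range(0, n, batch_size):
        yield idx[start:start + batch_size]


def _forward_loss(model: UNet, x: np.ndarray, y: np.ndarray,
                  batch_size: int) -> tuple[float, np.ndarray]:
    losses, probs = [], []
    for batch in _as_batches(len(x), batch_size, None):
        p = model.forward(x[batch])
        loss, _ = _batch_dice_loss_grad(p, y[batch])
        losses.append(loss * len(batch))
        probs.append(p)
    return float(np.sum(losses) / len(x)), np.concatenate(probs)


def train(model: UNet, train_images: np.ndarray, train_masks: np.ndarray,
          val_images: np.ndarray, val_masks: np.ndarray,
          cfg: TrainConfig) -> MetricRecord:
    """SGD training on soft-Dice loss with best-validation checkpointing.

    ``train_images``: (N, C, H, W) float; ``train_masks``: (N, S, H, W)
    binary, one channel per structure. Logs per-epoch train loss,
    validation loss and per-structure validation IoU; on completion the
    model holds the weights of the epoch with the smallest validation
    loss (not the last epoch). Deterministic given ``cfg.seed`` in
    single-threaded execution.
    """
    cfg.validate()
    structures = getattr(model, "spec", ModelSpec()).structures
    x_tr = np.ascontiguousarray(train_images, dtype=np.float32)
    y_tr = np.ascontiguousarray(train_masks, dtype=np.float32)
    x_va = np.ascontiguousarray(val_images, dtype=np.float32)
    y_va = np.ascontiguousarray(val_masks, dtype=np.float32)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("train and validation sets must be non-empty")

    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.params(), lr=cfg.learning_rate, momentum=cfg.momentum,
              clip_norm=cfg.clip_norm)
    rows = []
    best_state = model.state()
    best_loss = np.inf
    best_epoch = -1
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for batch in _as_batches(len(x_tr), cfg.batch_size, rng):
            probs = model.forward(x_tr[batch])
            loss, grad = _batch_dice_loss_grad(probs, y_tr[batch])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch}"
                )
            model.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_losses.append(loss * len(batch))
        train_loss = float(np.sum(epoch_losses) / len(x_tr))

        val_loss, val_probs = _forward_loss(model, x_va, y_va, cfg.batch_size)
        val_ious = {
            s: float(np.mean([
                iou(val_probs[i, j] >= 0.5, y_va[i, j] >= 0.5)
                for i in range(len(x_va))
            ]))
            for j, s in enumerate(structures)
        }
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss,
                     **{f"val_iou_{s}": v for s, v in val_ious.items()}})
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state()
            best_epoch = epoch

    if cfg.epochs > 0:
        model.load_state(best_state)
    curves = pd.DataFrame(rows)
    if len(rows):
        final = rows[best_epoch if best_epoch >= 0 else -1]
        final_iou = {s: final[f"val_iou_{s}"] for s in structures}
    else:
        final_iou = {s: float("nan") for s in structures}
    return MetricRecord(
        iou=final_iou,
        dice={s: float("nan") for s in structures},
        curves=curves,
        best_epoch=best_epoch if best_epoch >= 0 else None,
    )


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def predict_masks(model: UNet, image: np.ndarray,
                  case_id: str = "case") -> SegmentationOutput:
    """Probability maps and cleaned binary masks for one standardized image.

    Thresholds at 0.5, keeps the largest connected component per structure,
    and intersects the lesion mask with the uterus mask (a lesion pixel
    outside the uterus is anatomically impossible). Empty masks are flagged
    rather than raised, so downstream staging can handle the case.
    """
    structures = getattr(model, "spec", ModelSpec()).structures
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = img[None]
    if img.ndim != 3:
        raise ValueError(f"expected (H, W) or (C, H, W) image, got {img.shape}")
    if img.shape[0] != model.in_channels:
        raise ValueError(
            f"model expects {model.in_channels} input channel(s), got {img.shape[0]}"
        )
    probs = model.forward(img[None])[0]
    masks: dict[str, np.ndarray] = {}
    flags: list[str] = []
    for j, s in enumerate(structures):
        m = probs[j] >= 0.5
        if m.any():
            m = _largest_component(m)
        else:
            flags.append(f"empty_{s}_mask")
        masks[s] = m
    if "uterus" in masks and "lesion" in masks:
        masks["lesion"] = masks["lesion"] & masks["uterus"]
        if not masks["lesion"].any() and "empty_lesion_mask" not in flags:
            flags.append("empty_lesion_mask")
    return SegmentationOutput(
        case_id=case_id,
        probabilities={s: probs[j].astype(np.float64)
                       for j, s in enumerate(structures)},
        masks=masks,
        flags=flags,
    )
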