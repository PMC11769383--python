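"""Training and evaluation loops.

Optimization follows the protocol the architecture was designed around:
AdamW (β₁ = 0.9, decoupled weight decay 1e-2) at initial learning rate
1e-3, cosine-annealed per epoch to 1e-5, batch size 8, inputs resized to
256×256 with random rotation/flip/scale augmentation.  Every default is
overridable through :class:`TrainConfig`; the MoNuSeg-style preset (Adam,
224×224, batch 4) is available via the config file presets.

Runs are seed-deterministic: the augmentation stream, batch order, split
membership and parameter initialization all derive from ``config.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .data import (
    DatasetHandle,
    IntensityStats,
    augment_batch,
    compute_intensity_stats,
    split_ids,
)
from .errors import ConfigurationError, ContractViolation
from .losses import LossWeights, aflm_total
from .metrics import MetricsReport, evaluate_masks
from .model import AFNNet, ModelConfig, build_afn_net, load_checkpoint, save_checkpoint

__all__ = ["TrainConfig", "train", "evaluate", "predict_dataset", "overfit_single_batch"]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adamw"
    lr: float = 1e-3
    min_lr: float = 1e-5
    beta1: float = 0.9
    weight_decay: float = 1e-2
    batch_size: int = 8
    epochs: int = 200
    input_size: int = 256
    rotate: bool = True
    flip: bool = True
    scale: bool = True
    rot_range: float = 90.0
    scale_range: tuple = (0.8, 1.25)
    loss: LossWeights = field(default_factory=LossWeights)
    gradient_scheme: str = "forward"
    normalize_distance: bool = False
    normalize: bool = True
    seed: int = 0
    train_fraction: float = 0.8
    threshold: float = 0.5
    metrics_mode: str = "per_image"

    def __post_init__(self):
        if self.lr <= 0 or self.min_lr <= 0:
            raise ConfigurationError("learning rates must be positive")
        if self.min_lr > self.lr:
            raise ConfigurationError("min_lr must not exceed the initial lr")
        if self.batch_size < 1:
            raise ConfigurationError("batch size must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train fraction must be in (0, 1)")
        if self.optimizer not in ("adamw", "adam"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scale_range"] = list(d["scale_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "loss" in d and isinstance(d["loss"], dict):
            d["loss"] = LossWeights(**d["loss"])
        if "scale_range" in d:
            d["scale_range"] = tuple(d["scale_range"])
        return cls(**d)


def _make_optimizer(config: TrainConfig, params):
    if config.optimizer == "adamw":
        return nn.AdamW(params, lr=config.lr, betas=(config.beta1, 0.999),
                        weight_decay=config.weight_decay)
    return nn.Adam(params, lr=config.lr, betas=(config.beta1, 0.999))


def _batches(ids, batch_size):
    for i in range(0, len(ids), batch_size):
        yield ids[i : i + batch_size]


def _gather(data: DatasetHandle, wanted_ids):
    index = {sid: i for i, sid in enumerate(data.ids)}
    out = []
    for sid in wanted_ids:
        image, mask, _ = data.get(index[sid])
        out.append((image, mask, sid))
    return out


def _predict_batched(model, images: np.ndarray, batch: int = 8) -> np.ndarray:
    # self-attention memory grows with (tokens)^2; cap the micro-batch on
    # large inputs so inference stays within a few hundred MB
    if images.shape[-1] * images.shape[-2] >= 128 * 128:
        batch = min(batch, 2)
    probs = []
    for i in range(0, len(images), batch):
        probs.append(model.predict_proba(images[i : i + batch].astype(np.float32)))
    return np.concatenate(probs, axis=0)


def train(config: TrainConfig, data: DatasetHandle,
          model_config: ModelConfig | None = None,
          out_dir=None, verbose: bool = False):
    """Optimize the composite loss on `data`; returns (model, history, info).

    Splits train/val deterministically by (seed, id), standardizes
    intensities with training-split statistics, logs per-epoch loss
    components and validation metrics, and — when `out_dir` is given —
    saves the best-validation-Dice and final checkpoints plus a history
    CSV and plain-text log.
    """
    if len(data) == 0:
        raise ContractViolation("dataset is empty")
    data.lazy = False  # cache decoded samples across epochs

    model_config = model_config or ModelConfig(seed=config.seed)
    model = build_afn_net(model_config)
    optimizer = _make_optimizer(config, model.parameters())
    scheduler = nn.CosineAnnealingLR(optimizer, config.epochs, config.min_lr)

    train_ids, val_ids = split_ids(data.ids, config.seed, config.train_fraction)
    if not train_ids:
        train_ids, val_ids = list(data.ids), list(data.ids)
    if not val_ids:
        val_ids = list(train_ids)

    stats = compute_intensity_stats(data, train_ids) if config.normalize else None

    aug_rng = np.random.default_rng([config.seed, 1])
    order_rng = np.random.default_rng([config.seed, 2])

    val_samples = _gather(data, val_ids)
    val_imgs, val_masks, _ = augment_batch(
        [s[0] for s in val_samples], [s[1] for s in val_samples],
        config.input_size, train=False, stats=stats,
    )
    val_truth = [m[0] for m in val_masks]

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = []

    history_rows = []
    best = {"dice": -1.0, "epoch": -1}
    info = {"train_ids": train_ids, "val_ids": val_ids, "stats": stats,
            "first_step_loss": None}
    step = 0
    for epoch in range(config.epochs):
        lr = scheduler.set_epoch(epoch)
        order = list(train_ids)
        order_rng.shuffle(order)
        model.train()
        comp_sums = {"total": 0.0, "bce": 0.0, "dice": 0.0, "boundary": 0.0}
        n_batches = 0
        for batch_ids in _batches(order, config.batch_size):
            samples = _gather(data, batch_ids)
            imgs, masks, _ = augment_batch(
                [s[0] for s in samples], [s[1] for s in samples],
                config.input_size, rng=aug_rng, train=True, stats=stats,
                rotate=config.rotate, flip=config.flip, scale=config.scale,
                rot_range=config.rot_range, scale_range=config.scale_range,
            )
            x = nn.Tensor(imgs.astype(np.float32))
            logits = model(x)
            breakdown = aflm_total(logits, masks.astype(np.float32),
                                   weights=config.loss,
                                   scheme=config.gradient_scheme,
                                   normalize_distance=config.normalize_distance)
            loss_val = breakdown.total.item()
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss {loss_val} at epoch {epoch} on batch "
                    f"{batch_ids}; components {breakdown.as_floats()}"
                )
            optimizer.zero_grad()
            breakdown.total.backward()
            optimizer.step()
            step += 1
            if info["first_step_loss"] is None:
                info["first_step_loss"] = loss_val
            for k, v in breakdown.as_floats().items():
                comp_sums[k] += v
            n_batches += 1

        model.eval()
        probs = _predict_batched(model, val_imgs, batch=config.batch_size)
        pred_masks = [(p[0] >= config.threshold).astype(np.uint8) for p in probs]
        report = evaluate_masks(pred_masks, val_truth, ids=val_ids,
                                mode=config.metrics_mode)
        row = {"epoch": epoch, "lr": lr, "step": step}
        row.update({f"loss_{k}": v / max(n_batches, 1) for k, v in comp_sums.items()})
        row.update({f"val_{k}": v for k, v in report.summary.items()})
        history_rows.append(row)
        log_lines.append(
            f"epoch {epoch:4d} lr {lr:.3e} loss {row['loss_total']:.4f} "
            f"val_dice {row['val_dice']:.4f} val_iou {row['val_iou']:.4f}"
        )
        if verbose:
            print(log_lines[-1])

        if report.summary["dice"] > best["dice"]:
            best = {"dice": report.summary["dice"], "epoch": epoch}
            if out_dir is not None:
                save_checkpoint(out_dir / "best.npz", model, extra={
                    "train_config": config.to_dict(), "epoch": epoch,
                    "val_dice": report.summary["dice"],
                    "stats": None if stats is None else
                    {"mean": list(stats.mean), "std": list(stats.std)},
                })

    history = pd.DataFrame(history_rows)
    info["best"] = best
    if out_dir is not None:
        save_checkpoint(out_dir / "final.npz", model, extra={
            "train_config": config.to_dict(), "epoch": config.epochs - 1,
            "stats": None if stats is None else
            {"mean": list(stats.mean), "std": list(stats.std)},
        })
        history.to_csv(out_dir / "history.csv", index=False)
        (out_dir / "train.log").write_text("\n".join(log_lines) + "\n")
        info["checkpoints"] = {"best": out_dir / "best.npz", "final": out_dir / "final.npz"}
    return model, history, info


def evaluate(model_or_checkpoint, data: DatasetHandle, config: TrainConfig,
             stats: IntensityStats | None = None,
             out_csv=None, out_json=None) -> MetricsReport:
    """Inference (resize + normalize only) and metric aggregation.

    Accepts a model (anything with ``predict_proba``) or a checkpoint path.
    """
    if hasattr(model_or_checkpoint, "predict_proba"):
        model = model_or_checkpoint
    else:
        model = load_checkpoint(model_or_checkpoint)
    imgs, masks, sids = [], [], []
    for image, mask, sid in data:
        imgs.append(image)
        masks.append(mask)
        sids.append(sid)
    batch_imgs, batch_masks, _ = augment_batch(imgs, masks, config.input_size,
                                               train=False, stats=stats)
    probs = _predict_batched(model, batch_imgs, batch=config.batch_size)
    pred_masks = [(p[0] >= config.threshold).astype(np.uint8) for p in probs]
    truth = [m[0] for m in batch_masks]
    report = evaluate_masks(pred_masks, truth, ids=sids, mode=config.metrics_mode)
    if out_csv is not None:
        report.to_csv(out_csv)
    if out_json is not None:
        import json

        Path(out_json).write_text(json.dumps(report.to_json_dict(), indent=2))
    return report


def predict_dataset(model_or_checkpoint, data: DatasetHandle, config: TrainConfig,
                    out_dir, stats: IntensityStats | None = None):
    """Write per-image probability and binary-mask PNGs."""
    from PIL import Image

    if hasattr(model_or_checkpoint, "predict_proba"):
        model = model_or_checkpoint
    else:
        model = load_checkpoint(model_or_checkpoint)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for image, mask, sid in data:
        img_t, _, _ = augment_batch([image], [mask], config.input_size,
                                    train=False, stats=stats)
        prob = _predict_batched(model, img_t, batch=1)[0, 0]
        Image.fromarray(np.round(prob * 255).astype(np.uint8), mode="L").save(
            out / f"{sid}_prob.png"
        )
        Image.fromarray(((prob >= config.threshold) * 255).astype(np.uint8),
                        mode="L").save(out / f"{sid}_mask.png")
    return out


def overfit_single_batch(model: AFNNet, images: np.ndarray, masks: np.ndarray,
                         steps: int = 300, lr: float = 3e-3,
                         weight_decay: float = 0.0,
                         weights: LossWeights | None = None,
                         target_dice: float | None = None,
                         threshold: float = 0.5):
    """Fit one fixed batch; returns the per-step training Dice trajectory.

    A scaled-down learning check: a correctly wired network with working
    gradients should memorize a handful of tiles quickly.  Defaults differ
    from the full protocol on purpose: no weight decay (memorization is
    the goal) and a higher learning rate suited to a few hundred steps.
    Stops early once `target_dice` is reached.
    """
    optimizer = nn.AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)
    x = nn.Tensor(images.astype(np.float32))
    dices = []
    model.train()
    for _ in range(steps):
        logits = model(x)
        breakdown = aflm_total(logits, masks.astype(np.float32), weights=weights)
        optimizer.zero_grad()
        breakdown.total.backward()
        optimizer.step()
        probs = 1.0 / (1.0 + np.exp(-logits.data))
        pred = (probs >= threshold).astype(np.uint8)
        report = evaluate_masks([p[0] for p in pred], [m[0] for m in masks])
        dices.append(report.summary["dice"])
        if target_dice is not None and dices[-1] >= target_dice:
            break
    return dices
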