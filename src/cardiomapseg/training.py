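"""Training: case-level splits, soft-Jaccard loss, cosine-restart schedule,
two-phase map/weighted-image curriculum, augmentations, and the Adam loop.

The curriculum mirrors the two-phase protocol of the mapping study: during
the first phase both the parametric maps and the weighted images they were
computed from are used (many samples, robust features); in the second phase
training is restricted to the T1/T2 parametric maps to fine-tune for map
segmentation. The phase switch coincides with a restart of the cosine
learning-rate schedule.

Images are normalized by a fixed per-map-kind scale (not per-image
statistics) so photometric augmentation is not cancelled by normalization:
T1 maps ~1000 ms, T2 maps ~50 ms and weighted signals ~1e3 all land at O(1).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize

from .geometry import SegmentationMask
from .network import Segmenter
from .nn import Adam, softmax_channels

MAP_KINDS = ("T1map", "T2map", "T1weighted", "T2weighted")
#: fixed normalization scale per map kind (divisor), keeps inputs at O(1)
KIND_SCALE = {"T1map": 1500.0, "T2map": 250.0, "T1weighted": 2000.0, "T2weighted": 2000.0}


class TrainingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# data splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """case_id -> partition mapping; every image of a case inherits it."""

    assignment: dict[str, str]
    ratios: tuple[float, float, float]
    seed: int

    def cases(self, partition: str) -> list[str]:
        return [c for c, p in self.assignment.items() if p == partition]

    def __getitem__(self, case_id: str) -> str:
        return self.assignment[case_id]


def split_cases(
    case_ids: Sequence[str],
    ratios: tuple[float, float, float] = (0.65, 0.20, 0.15),
    seed: int = 0,
) -> SplitAssignment:
    """Deterministic case-level train/val/test split.

    Partition sizes follow largest-remainder rounding of ``ratios``; each
    case lands in exactly one partition so no image of a held-out subject can
    leak into training.
    """
    if len(case_ids) < 3:
        raise ValueError("need at least 3 cases to form three partitions")
    if len(set(case_ids)) != len(case_ids):
        raise ValueError("case_ids must be unique")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    n = len(case_ids)
    exact = np.asarray(ratios) * n
    counts = np.floor(exact).astype(int)
    # distribute the remainder to the largest fractional parts
    for i in np.argsort(-(exact - counts))[: n - counts.sum()]:
        counts[i] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    names = ("train", "val", "test")
    assignment: dict[str, str] = {}
    pos = 0
    for name, count in zip(names, counts):
        for idx in order[pos:pos + count]:
            assignment[case_ids[idx]] = name
        pos += count
    return SplitAssignment(assignment, tuple(ratios), seed)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _one_hot(labels: np.ndarray, num_classes: int) -> np.ndarray:
    flat = np.eye(num_classes, dtype=np.float32)[labels.reshape(-1)]
    return flat.reshape(*labels.shape, num_classes)


def jaccard_loss(
    pred_probs: np.ndarray,
    target,
    eps: float = 1e-6,
    foreground_classes: tuple[int, ...] = (1, 2),
) -> float:
    """Soft-Jaccard loss: 1 - mean over foreground classes of soft IoU.

    ``pred_probs`` has classes on the last axis and must lie in [0, 1];
    ``target`` is an integer label grid (or a :class:`SegmentationMask`).
    For one-hot predictions this equals 1 - mean hard IoU. The background
    class is excluded so it cannot dominate the average.
    """
    probs = np.asarray(pred_probs, dtype=np.float64)
    labels = target.labels if isinstance(target, SegmentationMask) else np.asarray(target)
    if probs.shape[:-1] != labels.shape:
        raise ValueError("prediction and target shapes do not match")
    if probs.min() < -1e-6 or probs.max() > 1 + 1e-6:
        raise ValueError("pred_probs must lie in [0, 1]")
    loss = 0.0
    for c in foreground_classes:
        p = probs[..., c]
        t = (labels == c).astype(np.float64)
        inter = float(np.sum(p * t))
        union = float(np.sum(p + t - p * t))
        loss += 1.0 - (inter + eps) / (union + eps)
    return loss / len(foreground_classes)


def jaccard_loss_and_grad(
    logits: np.ndarray,
    labels: np.ndarray,
    eps: float = 1e-6,
    foreground_classes: tuple[int, ...] = (1, 2),
) -> tuple[float, np.ndarray]:
    """Loss and d(loss)/d(logits) for a (N, C, H, W) logit batch."""
    probs = softmax_channels(logits.astype(np.float64))
    n, c, h, w = probs.shape
    onehot = _one_hot(labels, c).transpose(0, 3, 1, 2)
    dldp = np.zeros_like(probs)
    loss = 0.0
    k = len(foreground_classes)
    for cls in foreground_classes:
        p, t = probs[:, cls], onehot[:, cls]
        inter = float(np.sum(p * t)) + eps
        union = float(np.sum(p + t - p * t)) + eps
        loss += 1.0 - inter / union
        # d/dp of -(I/U): -(t*U - I*(1-t)) / U^2
        dldp[:, cls] = -(t * union - inter * (1.0 - t)) / (union * union)
    loss /= k
    dldp /= k
    # softmax backward
    dlogits = probs * (dldp - np.sum(dldp * probs, axis=1, keepdims=True))
    return loss, dlogits.astype(np.float32)


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------

def cosine_lr(t: float, period: float, lr_max: float, lr_min: float) -> float:
    """Cosine annealing within one restart period of length ``period``."""
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * t / period))


@dataclass
class TrainConfig:
    epochs: int = 150
    curriculum_switch_epoch: int = 70
    restart_periods: tuple[int, ...] = (70, 80)
    lr_max: float = 1e-3
    lr_min: float = 1e-6
    batch_size: int = 8
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.0
    crop_fraction: tuple[float, float] = (0.85, 1.0)
    contrast_jitter: tuple[float, float] = (0.9, 1.1)
    intensity_jitter: tuple[float, float] = (-0.05, 0.05)
    input_size: tuple[int, int] = (224, 224)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.restart_periods) != self.epochs:
            raise ValueError(
                f"restart_periods {self.restart_periods} must sum to epochs ({self.epochs})"
            )
        boundaries = np.concatenate([[0], np.cumsum(self.restart_periods)])
        if self.curriculum_switch_epoch not in boundaries:
            raise ValueError(
                "curriculum_switch_epoch must coincide with a learning-rate "
                f"restart boundary {list(boundaries)}"
            )


def lr_at(epoch: float, config: TrainConfig) -> float:
    """Learning rate at a (possibly fractional) epoch in [0, epochs).

    Restart boundaries belong to the new period (the rate resets to lr_max).
    """
    if not (0 <= epoch <= config.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs}]")
    start = 0.0
    for i, period in enumerate(config.restart_periods):
        is_last = i == len(config.restart_periods) - 1
        if epoch < start + period or is_last:
            return cosine_lr(epoch - start, period, config.lr_max, config.lr_min)
        start += period
    return config.lr_min


# ---------------------------------------------------------------------------
# curriculum and augmentation
# ---------------------------------------------------------------------------

def curriculum_filter(manifest: pd.DataFrame, epoch: int, switch_epoch: int) -> pd.DataFrame:
    """Two-phase sample schedule: all kinds before the switch, maps only after."""
    kinds = manifest["map_kind"] if len(manifest) else pd.Series([], dtype=str)
    unknown = set(kinds) - set(MAP_KINDS)
    if unknown:
        raise ValueError(f"unknown map_kind values {sorted(unknown)}")
    if epoch < switch_epoch:
        return manifest
    return manifest[manifest["map_kind"].isin(["T1map", "T2map"])]


def _resize_pair(image: np.ndarray, mask: np.ndarray | None, out_size):
    img = resize(image, out_size, order=1, preserve_range=True,
                 anti_aliasing=False).astype(np.float32)
    msk = None
    if mask is not None:
        msk = resize(mask, out_size, order=0, preserve_range=True,
                     anti_aliasing=False).astype(mask.dtype)
    return img, msk


def augment(
    image: np.ndarray,
    mask: np.ndarray | None,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Random crop + resize (shared by image and mask) and photometric jitter
    (image only; nearest-neighbor keeps mask labels intact)."""
    h, w = image.shape
    frac = rng.uniform(*config.crop_fraction)
    if frac > 1.0:
        raise ValueError("crop fraction cannot exceed 1")
    side = max(int(round(frac * min(h, w))), 8)
    top = rng.integers(0, h - side + 1)
    left = rng.integers(0, w - side + 1)
    img = image[top:top + side, left:left + side]
    msk = mask[top:top + side, left:left + side] if mask is not None else None
    img, msk = _resize_pair(img, msk, config.input_size)
    c = rng.uniform(*config.contrast_jitter)
    shift = rng.uniform(*config.intensity_jitter)
    center = img.mean()
    img = (img - center) * c + center + shift
    return img.astype(np.float32), msk


def preprocess_inference(image: np.ndarray, input_size) -> np.ndarray:
    """Fixed (full-frame) crop and resize used at inference time."""
    img, _ = _resize_pair(image, None, input_size)
    return img


# ---------------------------------------------------------------------------
# samples and the training loop
# ---------------------------------------------------------------------------

class Sample(NamedTuple):
    case_id: str
    slice_position: str
    map_kind: str
    image: np.ndarray  # 2D float image, raw units
    mask: np.ndarray   # 2D uint8 labels


def samples_from_cases(cases, include_weighted: bool = True,
                       use_fitted_maps: bool = True) -> list[Sample]:
    """Flatten phantom cases into training samples (maps and, optionally,
    the weighted images the maps were computed from)."""
    samples: list[Sample] = []
    for case in cases:
        for sl in case.slices:
            labels = sl.mask.labels
            t1 = sl.fitted_t1.data if (use_fitted_maps and sl.fitted_t1 is not None) else sl.true_t1
            t2 = sl.fitted_t2.data if (use_fitted_maps and sl.fitted_t2 is not None) else sl.true_t2
            pos = sl.geometry.slice_position
            samples.append(Sample(case.case_id, pos, "T1map",
                                  np.nan_to_num(t1).astype(np.float32), labels))
            samples.append(Sample(case.case_id, pos, "T2map",
                                  np.nan_to_num(t2).astype(np.float32), labels))
            if include_weighted:
                for frame in sl.t1_weighted:
                    samples.append(Sample(case.case_id, pos, "T1weighted",
                                          frame.astype(np.float32), labels))
                for frame in sl.t2_weighted:
                    samples.append(Sample(case.case_id, pos, "T2weighted",
                                          frame.astype(np.float32), labels))
    return samples


def samples_manifest(samples: list[Sample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "index": np.arange(len(samples)),
            "case_id": [s.case_id for s in samples],
            "slice_position": [s.slice_position for s in samples],
            "map_kind": [s.map_kind for s in samples],
        }
    )


def _normalized(image: np.ndarray, map_kind: str) -> np.ndarray:
    return (image / KIND_SCALE[map_kind]).astype(np.float32)


def _mean_foreground_dice(pred_labels: np.ndarray, true_labels: np.ndarray) -> float:
    scores = []
    for cls in (1, 2):
        p = pred_labels == cls
        t = true_labels == cls
        denom = int(p.sum()) + int(t.sum())
        if denom == 0:
            continue
        scores.append(2.0 * int(np.sum(p & t)) / denom)
    return float(np.mean(scores)) if scores else float("nan")


def evaluate_dice(model: Segmenter, samples: list[Sample],
                  input_size=None) -> pd.DataFrame:
    """Per-sample mean foreground Dice with fixed inference preprocessing."""
    input_size = input_size or model.config.input_size
    rows = []
    for s in samples:
        img = preprocess_inference(_normalized(s.image, s.map_kind), input_size)
        pred = model.predict_labels(img)
        _, truth_mask = _resize_pair(s.image, s.mask, input_size)
        rows.append(
            {
                "case_id": s.case_id,
                "slice_position": s.slice_position,
                "map_kind": s.map_kind,
                "dice": _mean_foreground_dice(pred, truth_mask),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TrainResult:
    model: Segmenter
    history: pd.DataFrame
    best_epoch: int
    best_val_dice: float


def train(
    model: Segmenter,
    samples: list[Sample],
    split: SplitAssignment,
    config: TrainConfig,
    verbose: bool = False,
) -> TrainResult:
    """Train the segmenter with Adam, the cosine-restart schedule and the
    two-phase curriculum; returns the best-validation-Dice checkpoint.

    Fully deterministic given ``config.seed`` (and the model's own init
    seed). Validation Dice is computed on parametric maps only, matching the
    evaluation protocol. Raises on divergence (non-finite loss).
    """
    train_samples = [s for s in samples if split[s.case_id] == "train"]
    val_samples = [s for s in samples if split[s.case_id] == "val"
                   and s.map_kind in ("T1map", "T2map")]
    if not train_samples or not val_samples:
        raise TrainingError("empty train or val partition")
    manifest = samples_manifest(train_samples)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model, betas=config.betas, weight_decay=config.weight_decay)
    history_rows = []
    best_state, best_dice, best_epoch = None, -1.0, -1
    for epoch in range(config.epochs):
        subset = curriculum_filter(manifest, epoch, config.curriculum_switch_epoch)
        indices = subset["index"].to_numpy()
        rng.shuffle(indices)
        lr = lr_at(epoch, config)
        losses = []
        for start in range(0, len(indices), config.batch_size):
            batch_idx = indices[start:start + config.batch_size]
            images, masks = [], []
            for i in batch_idx:
                s = train_samples[i]
                img, msk = augment(_normalized(s.image, s.map_kind), s.mask, config, rng)
                images.append(img)
                masks.append(msk)
            x = np.stack(images)[:, None]
            if model.config.in_channels > 1:
                x = np.repeat(x, model.config.in_channels, axis=1)
            y = np.stack(masks)
            model.zero_grads()
            logits = model.forward(x, train=True)
            loss, dlogits = jaccard_loss_and_grad(logits, y)
            if not np.isfinite(loss):
                raise TrainingError(f"training diverged: loss={loss} at epoch {epoch}")
            model.backward(dlogits)
            optimizer.step(lr)
            losses.append(loss)
        val = evaluate_dice(model, val_samples, config.input_size)
        val_dice = float(val["dice"].mean())
        history_rows.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "val_dice": val_dice,
             "lr": lr, "n_samples": len(indices)}
        )
        if verbose:
            print(f"epoch {epoch:3d} loss {np.mean(losses):.4f} "
                  f"val_dice {val_dice:.4f} lr {lr:.2e} n {len(indices)}")
        if val_dice > best_dice:
            best_dice, best_epoch = val_dice, epoch
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    return TrainResult(model=model, history=pd.DataFrame(history_rows),
                       best_epoch=best_epoch, best_val_dice=best_dice)


def predict_mask(model: Segmenter, image: np.ndarray, map_kind: str,
                 pixel_spacing_mm=(1.5, 1.5)) -> SegmentationMask:
    """Segment one raw map image: normalize, fixed crop/resize, argmax, and
    resize the label grid back to the native resolution."""
    img = preprocess_inference(_normalized(image, map_kind), model.config.input_size)
    labels = model.predict_labels(img)
    if labels.shape != image.shape:
        labels = resize(labels, image.shape, order=0, preserve_range=True,
                        anti_aliasing=False).astype(np.uint8)
    return SegmentationMask(labels, pixel_spacing_mm)
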