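"""Training recipe and sliding-window inference.

The recipe: AdamW (lr 1e-4, weight decay 0.01), random rotation/scaling/
elastic augmentation, an 80/20 train/test split, early stopping within a
150-epoch budget.  The objective is equally weighted soft-Dice plus
cross-entropy computed from logits; early stopping monitors validation mean
Dice with patience 20; validation items are carved from the training
portion (90/10) so the held-out test fraction is never touched.

Inference tiles a volume with fixed-size blocks at a stride controlled by
the overlap fraction, blends per-window class probabilities with a Gaussian
importance map, and normalises by the accumulated weight so the blended
weights form a partition of unity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .decoder import SegmentationResult
from .io import LabelMap, Volume
from .metrics import evaluate
from .model import SegmentationModel
from .nn import AdamW, Tensor, no_grad, ops
from .phantoms import Phantom

__all__ = [
    "AugmentParams",
    "TrainConfig",
    "TrainHistory",
    "split_dataset",
    "augment",
    "segmentation_loss",
    "train",
    "sliding_window_predict",
]


@dataclass
class AugmentParams:
    """Magnitudes of the three augmentations; all-zero means identity."""

    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    elastic_sigma: float = 4.0   # smoothing of the displacement field, voxels
    elastic_alpha: float = 10.0  # displacement magnitude, voxels

    def is_identity(self) -> bool:
        return (self.rotation_deg == 0.0
                and self.scale_range == (1.0, 1.0)
                and self.elastic_alpha == 0.0)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    max_epochs: int = 150
    max_steps: int | None = None
    early_stop_patience: int = 20
    batch_size: int = 2
    train_fraction: float = 0.8
    val_fraction: float = 0.1    # carved from the training portion
    seed: int = 0
    dice_weight: float = 1.0
    ce_weight: float = 1.0
    augment: AugmentParams | None = field(default_factory=AugmentParams)

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class TrainHistory:
    records: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = "max_epochs"

    @property
    def train_losses(self) -> list[float]:
        return [r["train_loss"] for r in self.records]

    @property
    def val_losses(self) -> list[float]:
        return [r["val_loss"] for r in self.records]

    @property
    def val_dices(self) -> list[float]:
        return [r["val_mean_dice"] for r in self.records]


def split_dataset(items: list, fraction: float, seed: int):
    """Seeded shuffle then split; train size = round(fraction · n)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    items = list(items)
    n = len(items)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fraction * n))
    if n > 0 and n_train == n:
        warnings.warn(f"test split is empty (n={n}, fraction={fraction})")
    train = [items[i] for i in order[:n_train]]
    test = [items[i] for i in order[n_train:]]
    return train, test


def augment(vol: Volume, labels: LabelMap, params: AugmentParams,
            seed: int) -> tuple[Volume, LabelMap]:
    """Seeded rotation + isotropic scale + elastic warp of an aligned pair.

    The identical spatial transform is applied to the volume (trilinear
    interpolation) and the labels (nearest neighbour, so label values stay
    a subset of the originals).  Zero-magnitude parameters return the
    inputs unchanged.
    """
    if labels.spatial_shape != vol.spatial_shape:
        raise ValueError("volume and labels are not aligned")
    if params.is_identity():
        return vol, labels
    rng = np.random.default_rng(seed)
    shape = vol.spatial_shape
    angles = np.deg2rad(rng.uniform(-params.rotation_deg, params.rotation_deg,
                                    size=3))
    scale = rng.uniform(*params.scale_range)

    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    # inverse map for output->input sampling: rotate back, unscale
    m = (rx @ ry @ rz).T / scale

    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    coords = np.indices(shape, dtype=np.float64)
    rel = coords - center[:, None, None, None]
    base = np.einsum("ij,j...->i...", m, rel) + center[:, None, None, None]

    if params.elastic_alpha > 0:
        disp = np.empty_like(base)
        for a in range(3):
            f = rng.normal(size=shape)
            f = ndimage.gaussian_filter(f, params.elastic_sigma)
            s = f.std()
            disp[a] = params.elastic_alpha * (f / s if s > 0 else f)
        base = base + disp

    out_data = np.empty_like(vol.data)
    for c in range(vol.num_channels):
        out_data[..., c] = ndimage.map_coordinates(
            vol.data[..., c].astype(np.float64), base, order=1, mode="constant",
            cval=0.0).astype(vol.data.dtype)
    out_labels = ndimage.map_coordinates(labels.labels, base, order=0,
                                         mode="constant", cval=0)
    return (
        Volume(data=out_data, spacing=vol.spacing,
               origin_note=f"augmented({vol.origin_note})"),
        LabelMap(labels=out_labels, num_classes=labels.num_classes,
                 spacing=labels.spacing),
    )


def _one_hot(labels: np.ndarray, num_classes: int, dtype) -> np.ndarray:
    return (labels[..., None] == np.arange(num_classes)).astype(dtype)


def segmentation_loss(logits: Tensor, gt: LabelMap | np.ndarray,
                      num_classes: int | None = None,
                      dice_weight: float = 1.0, ce_weight: float = 1.0,
                      eps: float = 1e-5) -> Tensor:
    """Soft-Dice (foreground classes) plus voxel cross-entropy, from logits.

    CE uses a numerically stable log-softmax; the soft-Dice term is
    ``1 − mean_c (2·Σ p_c t_c + ε) / (Σ p_c + Σ t_c + ε)`` over foreground
    classes c.
    """
    labels = gt.labels if isinstance(gt, LabelMap) else np.asarray(gt)
    k = num_classes or (gt.num_classes if isinstance(gt, LabelMap)
                        else int(labels.max()) + 1)
    onehot = _one_hot(labels, k, logits.data.dtype)
    logp = ops.log_softmax(logits, axis=-1)
    ce = ops.mul(ops.sum(ops.mul(logp, onehot)), -1.0 / labels.size)

    probs = ops.softmax(logits, axis=-1)
    inter = ops.sum(ops.mul(probs, onehot), axis=(0, 1, 2))   # (K,)
    psum = ops.sum(probs, axis=(0, 1, 2))
    tsum = onehot.sum(axis=(0, 1, 2))
    dice_vec = ops.div(ops.add(ops.mul(inter, 2.0), eps),
                       ops.add(ops.add(psum, tsum), eps))
    fg = np.zeros(k, dtype=logits.data.dtype)
    fg[1:] = 1.0 / (k - 1)
    soft_dice = ops.sum(ops.mul(dice_vec, fg))
    dice_loss = ops.sub(1.0, soft_dice)
    return ops.add(ops.mul(dice_loss, dice_weight), ops.mul(ce, ce_weight))


class EarlyStopper:
    """Stop after ``patience`` epochs without improvement of the monitor."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch = -1
        self.bad_epochs = 0

    def update(self, metric: float, epoch: int) -> bool:
        """Record a new value; returns True when training should stop."""
        if metric > self.best:
            self.best = metric
            self.best_epoch = epoch
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def _as_pair(item) -> tuple[Volume, LabelMap]:
    if isinstance(item, Phantom):
        return item.volume, item.labels
    return item


def _mean_val_metrics(model: SegmentationModel, items, config: TrainConfig):
    losses, dices = [], []
    with no_grad():
        for item in items:
            vol, lm = _as_pair(item)
            logits = model.forward(vol.data)
            loss = segmentation_loss(logits, lm, model.config.num_classes,
                                     config.dice_weight, config.ce_weight)
            losses.append(float(loss.data))
            pred = np.argmax(logits.data, axis=-1)
            rep = evaluate(pred, lm.labels, spacing=lm.spacing,
                           num_classes=model.config.num_classes)
            dices.append(rep.mean_dice)
    return float(np.mean(losses)), float(np.mean(dices))


def train(model: SegmentationModel, dataset: list,
          config: TrainConfig) -> tuple[SegmentationModel, TrainHistory]:
    """Train in place; returns the model restored to its best epoch.

    ``dataset`` is a list of phantoms or ``(Volume, LabelMap)`` pairs used
    for training; validation items are carved from it (``val_fraction``),
    falling back to monitoring the training items when the dataset is too
    small to spare any.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    n_val = int(round(config.val_fraction * len(dataset)))
    if 0 < n_val < len(dataset):
        order = rng.permutation(len(dataset))
        val_items = [dataset[i] for i in order[:n_val]]
        train_items = [dataset[i] for i in order[n_val:]]
    else:
        train_items = list(dataset)
        val_items = list(dataset)

    opt = AdamW(model.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    stopper = EarlyStopper(config.early_stop_patience)
    history = TrainHistory()
    best_state = model.state_dict()
    steps = 0
    do_augment = config.augment is not None and not config.augment.is_identity()

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_items))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_items[i] for i in order[start:start + config.batch_size]]
            opt.zero_grad()
            batch_loss = 0.0
            for item in batch:
                vol, lm = _as_pair(item)
                if do_augment:
                    vol, lm = augment(vol, lm, config.augment,
                                      seed=int(rng.integers(2 ** 31)))
                logits = model.forward(vol.data)
                loss = segmentation_loss(logits, lm, model.config.num_classes,
                                         config.dice_weight, config.ce_weight)
                loss = ops.mul(loss, 1.0 / len(batch))
                loss.backward()
                batch_loss += float(loss.data) * len(batch)
            opt.step()
            epoch_losses.append(batch_loss / len(batch))
            steps += 1
            if config.max_steps is not None and steps >= config.max_steps:
                break

        val_loss, val_dice = _mean_val_metrics(model, val_items, config)
        history.records.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": val_loss,
            "val_mean_dice": val_dice,
        })
        improved = val_dice > stopper.best
        stop = stopper.update(val_dice, epoch)
        if improved:
            best_state = model.state_dict()
        if stop:
            history.stop_reason = "early_stop"
            break
        if config.max_steps is not None and steps >= config.max_steps:
            history.stop_reason = "max_steps"
            break
    else:
        history.stop_reason = "max_epochs"

    history.best_epoch = stopper.best_epoch
    model.load_state_dict(best_state)
    return model, history


def _gaussian_importance(window: tuple[int, int, int],
                         sigma_scale: float = 0.125) -> np.ndarray:
    grids = []
    for w in window:
        x = np.arange(w, dtype=np.float64) - (w - 1) / 2.0
        sigma = max(w * sigma_scale, 1e-3)
        grids.append(np.exp(-0.5 * (x / sigma) ** 2))
    g = grids[0][:, None, None] * grids[1][None, :, None] * grids[2][None, None, :]
    return np.maximum(g, g.max() * 1e-4)


def _tile_starts(size: int, window: int, stride: int) -> list[int]:
    if size <= window:
        return [0]
    starts = list(range(0, size - window + 1, stride))
    if starts[-1] != size - window:
        starts.append(size - window)
    return starts


def sliding_window_predict(model: SegmentationModel, vol: Volume,
                           window: tuple[int, int, int] = (64, 64, 64),
                           overlap: float = 0.5) -> SegmentationResult:
    """Tile, predict per window, blend probabilities, normalise, crop.

    A volume that fits in a single window is forwarded directly (the output
    is then bit-identical to ``model.predict``).  Otherwise per-window class
    probabilities are blended with a Gaussian importance map and divided by
    the accumulated weight, so the effective blending weights sum to one at
    every voxel.
    """
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    window = tuple(int(w) for w in window)
    m = model.config.encoder.min_input_size()
    if any(w < m for w in window):
        raise ValueError(f"window {window} below the model minimum {m}")
    shape = vol.spatial_shape
    if all(s <= w for s, w in zip(shape, window)):
        return model.predict(vol)

    pad = [max(w - s, 0) for s, w in zip(shape, window)]
    data = np.pad(vol.data, tuple((0, p) for p in pad) + ((0, 0),))
    pshape = data.shape[:3]
    k = model.config.num_classes
    acc = np.zeros(pshape + (k,), dtype=np.float64)
    den = np.zeros(pshape + (1,), dtype=np.float64)
    wmap = _gaussian_importance(window)[..., None]

    strides = [max(1, int(round(w * (1.0 - overlap)))) for w in window]
    for i in _tile_starts(pshape[0], window[0], strides[0]):
        for j in _tile_starts(pshape[1], window[1], strides[1]):
            for l in _tile_starts(pshape[2], window[2], strides[2]):
                tile = data[i:i + window[0], j:j + window[1], l:l + window[2]]
                probs = model.predict_proba(tile)
                sl = (slice(i, i + window[0]), slice(j, j + window[1]),
                      slice(l, l + window[2]))
                acc[sl] += probs * wmap
                den[sl] += wmap
    probs = (acc / den)[: shape[0], : shape[1], : shape[2]]
    labels = LabelMap(labels=np.argmax(probs, axis=3), num_classes=k,
                      spacing=vol.spacing)
    return SegmentationResult(probabilities=probs.astype(np.float32),
                              labels=labels)
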