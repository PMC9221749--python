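"""Multi-label soft-Dice training with plateau LR reduction and early stop.

The schedule is a two-stage state machine driven by validation loss: after
``patience`` consecutive epochs without improvement the learning rate drops
from ``initial_lr`` to ``reduced_lr``; after another ``patience`` epochs
without improvement, training stops.  Weights from the best-validation epoch
are restored at the end.

"Momentum 0.9" from the original protocol maps to Adam's first-moment decay
beta1 (Adam has no classical momentum).  The learning rates 10x10^-4 and
10x10^-5 are read literally as 1e-3 and 1e-4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from tileseg.model import Normalizer, UNet, make_optimizer, _to_unit_interval

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "AugmentConfig",
    "TrainingHistory",
    "PlateauSchedule",
    "dice_loss",
    "augment",
    "fit",
]


@dataclass(frozen=True)
class TrainConfig:
    initial_lr: float = 1e-3
    reduced_lr: float = 1e-4
    beta1: float = 0.9
    batch_size: int = 8
    patience: int = 5
    max_epochs: int = 60
    dice_eps: float = 1.0
    min_delta: float = 1e-4  # improvement = val_loss < best - min_delta
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.reduced_lr < self.initial_lr):
            raise ValueError("need 0 < reduced_lr < initial_lr")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation probabilities and magnitudes.

    Geometric transforms (flip, rotation) are applied identically to image
    and mask — the mask via nearest-neighbor so it stays binary.  Photometric
    transforms touch the image only.
    """

    p_hflip: float = 0.5
    p_rotate: float = 0.5
    max_rotate_deg: float = 10.0
    p_brightness: float = 0.2
    max_brightness: float = 0.2  # +-20% additive shift of full range
    p_contrast: float = 0.2
    max_contrast: float = 0.2  # gain in [0.8, 1.2]
    p_blur: float = 0.2
    max_blur_sigma: float = 1.5
    p_sharpen: float = 0.2
    p_noise: float = 0.2
    max_noise_sd: float = 5.0 / 255.0


@dataclass
class TrainingHistory:
    """Per-epoch loss/LR trajectory with schedule landmarks."""

    epochs: list = field(default_factory=list)  # {epoch, train_loss, val_loss, lr}
    stop_epoch: int = 0
    lr_reduction_epoch: int | None = None
    best_epoch: int = 0

    def append(self, epoch: int, train_loss: float, val_loss: float, lr: float) -> None:
        self.epochs.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "lr": lr}
        )

    def to_rows(self) -> list[dict]:
        return list(self.epochs)


def dice_loss(probs: np.ndarray, targets: np.ndarray, eps: float = 1.0) -> float:
    """1 minus the mean smoothed soft-Dice over batch entries and channels.

    ``dice = (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)`` per (entry,
    channel) plane; inputs are ``(N, C, H, W)`` (or a single ``(C, H, W)``
    pair, promoted to a batch of one).
    """
    probs = np.asarray(probs, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if probs.ndim == 3:
        probs, targets = probs[None], targets[None]
    if probs.shape != targets.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {targets.shape}")
    if probs.ndim != 4:
        raise ValueError("expected (N, C, H, W) inputs")
    inter = (probs * targets).sum(axis=(2, 3))
    sums = probs.sum(axis=(2, 3)) + targets.sum(axis=(2, 3))
    dice = (2.0 * inter + eps) / (sums + eps)
    return float(1.0 - dice.mean())


def dice_loss_grad(probs: np.ndarray, targets: np.ndarray, eps: float = 1.0) -> np.ndarray:
    """dL/dprobs for :func:`dice_loss` (mean over N*C planes)."""
    probs = probs.astype(np.float64)
    targets = targets.astype(np.float64)
    inter = (probs * targets).sum(axis=(2, 3), keepdims=True)
    sums = probs.sum(axis=(2, 3), keepdims=True) + targets.sum(axis=(2, 3), keepdims=True)
    num = 2.0 * inter + eps
    den = sums + eps
    ddice = (2.0 * targets * den - num) / den**2
    n_planes = probs.shape[0] * probs.shape[1]
    return (-ddice / n_planes).astype(np.float32)


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    aug: AugmentConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly transform an image/mask pair (image in [0,1] floats).

    Returns new arrays; the mask remains strictly binary.
    """
    img = _to_unit_interval(image).copy()
    msk = np.asarray(mask).astype(bool).copy()
    if img.shape != msk.shape[-2:]:
        raise ValueError("image and mask extents differ")

    if rng.random() < aug.p_hflip:
        img = img[:, ::-1].copy()
        msk = msk[..., ::-1].copy()
    if rng.random() < aug.p_rotate:
        angle = rng.uniform(-aug.max_rotate_deg, aug.max_rotate_deg)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        msk = np.stack(
            [
                ndimage.rotate(ch.astype(np.uint8), angle, reshape=False, order=0,
                               mode="constant", cval=0).astype(bool)
                for ch in msk
            ]
        )
    if rng.random() < aug.p_brightness:
        img = img + rng.uniform(-aug.max_brightness, aug.max_brightness)
    if rng.random() < aug.p_contrast:
        gain = 1.0 + rng.uniform(-aug.max_contrast, aug.max_contrast)
        img = 0.5 + gain * (img - 0.5)
    if rng.random() < aug.p_blur:
        img = ndimage.gaussian_filter(img, sigma=rng.uniform(0.3, aug.max_blur_sigma))
    if rng.random() < aug.p_sharpen:
        blurred = ndimage.gaussian_filter(img, sigma=1.0)
        img = img + rng.uniform(0.5, 1.5) * (img - blurred)
    if rng.random() < aug.p_noise:
        img = img + rng.normal(0.0, rng.uniform(0.0, aug.max_noise_sd), size=img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32), msk


class PlateauSchedule:
    """The two-stage validation-loss state machine.

    ``update`` returns one of ``"continue"``, ``"reduce"`` (this epoch
    triggered the LR drop) or ``"stop"``.
    """

    def __init__(self, patience: int, min_delta: float = 1e-4):
        self.patience = patience
        self.min_delta = min_delta
        self.best = float("inf")
        self.bad_epochs = 0
        self.reduced = False

    def update(self, val_loss: float) -> str:
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.bad_epochs = 0
            return "continue"
        self.bad_epochs += 1
        if self.bad_epochs >= self.patience:
            if not self.reduced:
                self.reduced = True
                self.bad_epochs = 0
                return "reduce"
            return "stop"
        return "continue"


def _prepare_tiles(tiles, input_size: int, normalizer: Normalizer):
    """Resample (image, mask) tile pairs to the working resolution.

    Images go bilinear, masks nearest-neighbor (stay binary).  Returns float32
    arrays ``(N, 1, s, s)`` and ``(N, 4, s, s)``.
    """
    n = len(tiles)
    xs = np.empty((n, 1, input_size, input_size), dtype=np.float32)
    ys = np.empty((n, 4, input_size, input_size), dtype=np.float32)
    for k, (img, msk) in enumerate(tiles):
        x = normalizer(_to_unit_interval(img))
        if x.shape != (input_size, input_size):
            x = resize(x, (input_size, input_size), order=1, preserve_range=True,
                       anti_aliasing=False)
        xs[k, 0] = x
        msk = np.asarray(msk)
        if msk.shape[-2:] != (input_size, input_size):
            msk = np.stack(
                [
                    resize(ch.astype(np.float32), (input_size, input_size), order=0,
                           preserve_range=True, anti_aliasing=False)
                    for ch in msk
                ]
            )
        ys[k] = (msk > 0.5).astype(np.float32)
    return xs, ys


def fit(model: UNet, train_tiles, val_tiles, config: TrainConfig,
        aug: AugmentConfig | None = None):
    """Train a model on (image, mask) tile pairs; returns (model, history).

    Each epoch: seeded shuffle, per-pair augmentation, minibatch Adam steps
    on the dice loss; then un-augmented validation loss drives the plateau
    schedule.  Weights from the best-validation epoch are restored before
    returning.
    """
    if not train_tiles or not val_tiles:
        raise ValueError("train and validation tile sets must be non-empty")
    if aug is None:
        aug = AugmentConfig()

    input_size = model.config.input_size
    # intensity statistics from the training split only
    flat = np.concatenate([_to_unit_interval(img).ravel() for img, _ in train_tiles])
    model.normalizer = Normalizer(mean=float(flat.mean()), sd=float(flat.std()) or 1.0)

    val_x, val_y = _prepare_tiles(val_tiles, input_size, model.normalizer)
    optimizer = make_optimizer(model, lr=config.initial_lr, beta1=config.beta1)
    schedule = PlateauSchedule(config.patience, config.min_delta)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA46]))
    history = TrainingHistory()

    best_val = float("inf")
    best_weights = [p.value.copy() for p in model.params()]
    history.best_epoch = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_tiles))
        augmented = [augment(*train_tiles[i], aug, rng) for i in order]
        train_x, train_y = _prepare_tiles(augmented, input_size, model.normalizer)

        train_losses = []
        for start in range(0, len(augmented), config.batch_size):
            xb = train_x[start : start + config.batch_size]
            yb = train_y[start : start + config.batch_size]
            probs = model.forward(xb)
            loss = dice_loss(probs, yb, config.dice_eps)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            optimizer.zero_grad()
            model.backward(dice_loss_grad(probs, yb, config.dice_eps))
            optimizer.step()
            train_losses.append(loss)

        val_losses = []
        for start in range(0, len(val_tiles), config.batch_size):
            probs = model.forward(val_x[start : start + config.batch_size])
            val_losses.append(
                dice_loss(probs, val_y[start : start + config.batch_size], config.dice_eps)
                * len(probs)
            )
        val_loss = float(np.sum(val_losses) / len(val_tiles))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")

        history.append(epoch, float(np.mean(train_losses)), val_loss, optimizer.lr)
        logger.info(
            "epoch=%d train_loss=%.6f val_loss=%.6f lr=%.2e",
            epoch, float(np.mean(train_losses)), val_loss, optimizer.lr,
        )

        if val_loss < best_val:
            best_val = val_loss
            best_weights = [p.value.copy() for p in model.params()]
            history.best_epoch = epoch

        action = schedule.update(val_loss)
        history.stop_epoch = epoch
        if action == "reduce":
            optimizer.lr = config.reduced_lr
            history.lr_reduction_epoch = epoch
        elif action == "stop":
            break

    model.load_state_arrays(best_weights)
    return model, history
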