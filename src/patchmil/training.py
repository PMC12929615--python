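"""End-to-end training of the patch classifier from image-level labels.

Each optimization step augments a batch of images, partitions them into
patches, pushes all ``B * P^2`` patches through the shared encoder in one
batch, averages patch logits per image into the global logits ``Z``, and
applies multi-label binary cross-entropy between ``sigmoid(Z)`` and the
label vector.  The loss is computed **only** on the global output — there
are no per-patch auxiliary losses — and backpropagates through every
patch's shared parameters (each patch receives gradient ``(y_hat - y) /
(B * C * P^2)`` on its logits).  Optimization uses AdamW with a one-cycle
learning-rate schedule rising to the peak over the first 5% of steps.

Augmentation follows common radiograph practice: random square crop
covering 50-100% of the area (resized back), rotation within +/-5 degrees
(bilinear, zero fill), and brightness scaling by a factor in [0.7, 1.3]
with clipping to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core import stable_sigmoid
from .nn import AdamW, one_cycle_lr

__all__ = ["TrainConfig", "AugmentConfig", "augment", "train", "predict_scores", "bce_loss"]


@dataclass(frozen=True)
class AugmentConfig:
    """Random crop / rotation / brightness ranges."""

    crop_area_range: tuple[float, float] = (0.5, 1.0)
    rotation_deg: float = 5.0
    brightness_range: tuple[float, float] = (0.7, 1.3)

    def __post_init__(self) -> None:
        lo, hi = self.crop_area_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("crop_area_range must satisfy 0 < lo <= hi <= 1")
        if self.rotation_deg < 0:
            raise ValueError("rotation_deg must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults: 20 epochs, batches of 16 images (an effective patch batch of
    ``16 * P^2``), AdamW with peak learning rate 1e-4 reached after the
    first 5% of steps (one-cycle), weight decay 1e-2.  The loss is fixed:
    multi-label binary cross-entropy on the global logits.
    """

    epochs: int = 20
    batch_size: int = 16
    peak_lr: float = 1e-4
    warmup_frac: float = 0.05
    weight_decay: float = 1e-2
    betas: tuple[float, float] = (0.9, 0.999)
    patch_side: int = 16
    image_side: int = 128
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.warmup_frac < 1.0):
            raise ValueError("warmup_frac must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.image_side % self.patch_side != 0:
            raise ValueError("image_side must be divisible by patch_side")

    def to_dict(self) -> dict:
        return asdict(self)


def augment(
    img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Apply crop -> rotate -> brightness; deterministic given the rng state.

    The degenerate draw (full-area crop, zero angle, unit brightness) is an
    exact identity: resampling is skipped when it would be a no-op.
    """
    from skimage.transform import resize, rotate

    S = img.shape[0]
    out = img
    frac = rng.uniform(*cfg.crop_area_range)
    side = int(round(S * np.sqrt(frac)))
    side = max(1, min(S, side))
    if side < S:
        top = int(rng.integers(0, S - side + 1))
        left = int(rng.integers(0, S - side + 1))
        crop = out[top : top + side, left : left + side]
        out = resize(crop, (S, S), order=1, mode="edge", anti_aliasing=False)
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg)
    if angle != 0.0:
        out = rotate(out, angle, order=1, mode="constant", cval=0.0)
    factor = rng.uniform(*cfg.brightness_range)
    if factor != 1.0 or out is img:
        out = out * factor
    return np.clip(out, 0.0, 1.0)


def bce_loss(global_logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean multi-label binary cross-entropy and its gradient wrt the logits.

    Uses the logit-stable form ``max(Z, 0) - Z*y + log(1 + exp(-|Z|))``.
    """
    Z = np.asarray(global_logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    loss = np.maximum(Z, 0.0) - Z * y + np.log1p(np.exp(-np.abs(Z)))
    grad = (stable_sigmoid(Z) - y) / Z.size
    return float(loss.mean()), grad


def _batch_forward(enc, images: np.ndarray, patch_side: int) -> tuple[np.ndarray, int]:
    """Forward a (B, S, S) image batch; returns global logits (B, C) and P^2."""
    B, S, _ = images.shape
    p = patch_side
    P = S // p
    patches = (
        images.reshape(B, P, p, P, p).transpose(0, 1, 3, 2, 4).reshape(B * P * P, p, p)
    )
    logits = enc.forward(patches)  # (B*P^2, C)
    Z = logits.reshape(B, P * P, -1).mean(axis=1)
    return Z, P * P


def predict_scores(enc, images: np.ndarray, patch_side: int) -> np.ndarray:
    """Global probabilities ``y_hat`` for a stack of images (no augmentation)."""
    probs = []
    for start in range(0, images.shape[0], 64):
        Z, _ = _batch_forward(enc, images[start : start + 64], patch_side)
        probs.append(stable_sigmoid(Z))
    return np.concatenate(probs, axis=0)


def train(
    dataset: tuple[np.ndarray, np.ndarray],
    enc,
    cfg: TrainConfig,
    val_dataset: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[object, dict]:
    """Train the shared encoder; returns (encoder, history).

    ``dataset`` is ``(images (n, S, S), labels (n, C))``.  History records
    the per-epoch mean training loss and, when a validation split is given,
    the label-mean validation AUROC.  Fully seeded: equal seeds and configs
    reproduce equal loss curves.
    """
    images, labels = dataset
    n, S, _ = images.shape
    C = enc.n_labels
    if labels.shape != (n, C):
        raise ValueError(
            f"label matrix shape {labels.shape} does not match "
            f"{n} images x {C} labels"
        )
    if S != cfg.image_side:
        raise ValueError(f"images have side {S}, config says {cfg.image_side}")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(
        enc.params, enc.grads,
        lr=cfg.peak_lr, betas=cfg.betas, weight_decay=cfg.weight_decay,
    )
    steps_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_steps = max(1, cfg.epochs * steps_per_epoch)
    history: dict = {"epoch_loss": [], "val_auroc": [], "lr": []}
    step = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = np.stack([augment(images[i], cfg.augment, rng) for i in idx])
            Z, P2 = _batch_forward(enc, batch, cfg.patch_side)
            loss, dZ = bce_loss(Z, labels[idx])
            # each patch logit contributes 1/P^2 to its image's global logit
            B = len(idx)
            grad_patches = np.repeat(dZ / P2, P2, axis=0).reshape(B * P2, C)
            enc.backward(grad_patches)
            opt.lr = one_cycle_lr(step, total_steps, cfg.peak_lr, cfg.warmup_frac)
            opt.step()
            epoch_losses.append(loss)
            step += 1
        history["epoch_loss"].append(float(np.mean(epoch_losses)))
        history["lr"].append(float(opt.lr))
        if val_dataset is not None:
            from .evaluation import auroc

            val_images, val_labels = val_dataset
            scores = predict_scores(enc, val_images, cfg.patch_side)
            aucs = []
            for k in range(C):
                if len(np.unique(val_labels[:, k])) == 2:
                    aucs.append(auroc(scores[:, k], val_labels[:, k]))
            history["val_auroc"].append(float(np.mean(aucs)) if aucs else float("nan"))
    return enc, history
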