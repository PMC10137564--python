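"""Training for the segmentation network: loss, augmentation, loop, predict.

The loss is the sum over classes (background, lung, heart) of the soft
Jaccard loss 1 − (Σ p·g + ε)/(Σ p + Σ g − Σ p·g + ε), with p the predicted
class probability and g the one-hot target; it is zero exactly when the
prediction one-hot-equals the target (up to ε) and bounded by the number
of classes.  Optimisation is plain SGD with momentum (defaults lr 1e-4,
momentum 0.99), no schedule, best-validation checkpointing only.

Augmentation covers random resized crop, shift/scale/rotate, random
brightness/contrast, image inversion, elastic transform, grid distortion,
and optical distortion.  Geometric transforms apply the identical warp to
image (bilinear) and mask (nearest neighbour — labels are never
interpolated); photometric transforms touch the image only.  Per-sample
augmentation parameters come from a seeded stream independent of batch
composition, so a fixed seed reproduces the run.

Images and masks are resized to ``input_size_px`` (bilinear / nearest)
before entering the network; predicted label maps are upscaled back to the
original resolution with nearest neighbour, and the CTR is computed on
that full-resolution map.  Because the CTR is a ratio of two horizontal
spans, any (even anisotropic) resize multiplies both spans equally and
leaves the CTR unchanged up to discretisation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from . import io, nn
from .errors import ParameterError
from .metrics import confusion, seg_metrics
from .model import AlbuNet, ModelConfig, build_model

ALL_AUGMENTATIONS = frozenset({
    "random_resized_crop", "shift_scale_rotate", "random_brightness_contrast",
    "invert", "elastic_transform", "grid_distortion", "optical_distortion",
})


@dataclass(frozen=True)
class AugmentConfig:
    """Which augmentations run, with what probability and magnitude."""

    enabled: frozenset = ALL_AUGMENTATIONS
    p_random_resized_crop: float = 0.5
    crop_scale: tuple = (0.8, 1.0)        # area fraction of the crop
    crop_ratio: tuple = (0.9, 1.111)      # aspect-ratio range
    p_shift_scale_rotate: float = 0.5
    shift_limit: float = 0.0625           # fraction of side
    scale_limit: float = 0.10
    rotate_limit: float = 10.0            # degrees
    p_random_brightness_contrast: float = 0.5
    brightness_limit: float = 0.2
    contrast_limit: float = 0.2
    p_invert: float = 0.5
    p_elastic_transform: float = 0.3
    elastic_alpha: float = 15.0           # displacement scale, px
    elastic_sigma: float = 4.0            # smoothing of the field, px
    p_grid_distortion: float = 0.3
    grid_steps: int = 5
    grid_limit: float = 0.3
    p_optical_distortion: float = 0.3
    optical_limit: float = 0.3

    def __post_init__(self):
        unknown = set(self.enabled) - ALL_AUGMENTATIONS
        if unknown:
            raise ParameterError(f"unknown augmentation(s): {sorted(unknown)}")
        for name in ALL_AUGMENTATIONS:
            p = getattr(self, f"p_{name}")
            if not (0.0 <= p <= 1.0):
                raise ParameterError(f"p_{name} must lie in [0, 1], got {p}")


NO_AUGMENT = AugmentConfig(enabled=frozenset())


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    momentum: float = 0.99
    epochs: int = 15
    batch_size: int = 8
    input_size_px: int = 512
    seed: int = 0
    augment: AugmentConfig = field(default_factory=lambda: NO_AUGMENT)
    smooth_eps: float = 1e-6

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        if not (0.0 <= self.momentum < 1.0):
            raise ParameterError("momentum must lie in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ParameterError("epochs and batch_size must be >= 1")


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    return np.moveaxis(np.eye(n_classes, dtype=nn.DTYPE)[target], -1, 1) \
        if target.ndim == 3 else np.eye(n_classes, dtype=nn.DTYPE)[target]


def soft_jaccard_with_grad(
    prob_map: np.ndarray,
    target: np.ndarray,
    smooth_eps: float = 1e-6,
    reduction: str = "mean",
) -> tuple[float, np.ndarray]:
    """Soft Jaccard loss, summed over classes, and its probability gradient.

    Intersections and unions are accumulated per image; the class-summed
    per-image losses are then averaged over the batch (``reduction='mean'``,
    the reported loss, bounded by the number of classes) or summed
    (``reduction='sum'``, the training objective — summing keeps the
    per-image gradient scale independent of batch size).
    """
    probs = np.asarray(prob_map)
    if probs.ndim == 3:
        probs = probs[None]
    target = np.asarray(target)
    if target.ndim == 2:
        target = target[None]
    if probs.shape[0] != target.shape[0] or probs.shape[2:] != target.shape[1:]:
        raise ValueError(
            f"shape mismatch: probs {probs.shape} vs target {target.shape}"
        )
    k = probs.shape[1]
    if target.min() < 0 or target.max() >= k:
        raise ValueError("target labels outside the class range")
    if reduction not in ("mean", "sum"):
        raise ValueError(f"unknown reduction {reduction!r}")
    g = np.moveaxis(np.eye(k, dtype=probs.dtype)[target], -1, 1)
    axes = (2, 3)
    inter = (probs * g).sum(axis=axes)            # (N, K)
    union = probs.sum(axis=axes) + g.sum(axis=axes) - inter
    terms = 1.0 - (inter + smooth_eps) / (union + smooth_eps)
    loss = float(terms.sum())
    dprobs = -(
        g * (union + smooth_eps)[:, :, None, None]
        - (1.0 - g) * (inter + smooth_eps)[:, :, None, None]
    ) / ((union + smooth_eps) ** 2)[:, :, None, None]
    if reduction == "mean":
        n = probs.shape[0]
        loss /= n
        dprobs /= n
    return loss, dprobs.astype(probs.dtype)


def jaccard_loss(
    prob_map: np.ndarray, target: np.ndarray, smooth_eps: float = 1e-6
) -> float:
    """Sum over classes of the soft Jaccard loss (see module docstring).

    For batched input this is the per-image average of the class-summed
    loss, so the value is always bounded by the number of classes.
    """
    return soft_jaccard_with_grad(prob_map, target, smooth_eps)[0]


# ---------------------------------------------------------------------------
# resizing
# ---------------------------------------------------------------------------

def resize_image(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a [0, 1] float image."""
    if image.shape == tuple(shape):
        return np.asarray(image, dtype=np.float64)
    return _sk_resize(np.asarray(image, dtype=np.float64), shape, order=1,
                      preserve_range=True, anti_aliasing=True)


def resize_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resize of a label mask (no interpolated classes)."""
    mask = io.validate_mask(mask)
    h0, w0 = mask.shape
    h1, w1 = shape
    if (h0, w0) == (h1, w1):
        return mask
    rows = np.minimum((np.arange(h1) + 0.5) * h0 / h1, h0 - 1).astype(np.intp)
    cols = np.minimum((np.arange(w1) + 0.5) * w0 / w1, w0 - 1).astype(np.intp)
    return mask[np.ix_(rows, cols)]


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _warp(image, mask, row_map, col_map):
    """Apply an inverse coordinate map to the pair (bilinear / nearest)."""
    coords = np.stack([row_map, col_map])
    img = ndimage.map_coordinates(image, coords, order=1, mode="nearest")
    msk = ndimage.map_coordinates(mask, coords, order=0, mode="nearest")
    return img, msk


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    cfg: AugmentConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the configured augmentations to an image/mask pair.

    Deterministic for fixed ``(cfg, seed)``; disabling every transform
    yields the identity.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = io.validate_mask(mask)
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} != mask shape {mask.shape}"
        )
    rng = np.random.default_rng(seed)
    h, w = image.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    if "random_resized_crop" in cfg.enabled and rng.random() < cfg.p_random_resized_crop:
        area = rng.uniform(*cfg.crop_scale)
        ratio = rng.uniform(*cfg.crop_ratio)
        ch = min(h, int(round(h * np.sqrt(area / ratio))))
        cw = min(w, int(round(w * np.sqrt(area * ratio))))
        top = rng.integers(0, h - ch + 1)
        left = rng.integers(0, w - cw + 1)
        rows = top + (np.arange(h) + 0.5) * ch / h - 0.5
        cols = left + (np.arange(w) + 0.5) * cw / w - 0.5
        image, mask = _warp(image, mask, *np.meshgrid(rows, cols, indexing="ij"))

    if "shift_scale_rotate" in cfg.enabled and rng.random() < cfg.p_shift_scale_rotate:
        ang = np.deg2rad(rng.uniform(-cfg.rotate_limit, cfg.rotate_limit))
        scale = 1.0 + rng.uniform(-cfg.scale_limit, cfg.scale_limit)
        dy = rng.uniform(-cfg.shift_limit, cfg.shift_limit) * h
        dx = rng.uniform(-cfg.shift_limit, cfg.shift_limit) * w
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        # inverse map: output pixel -> source pixel
        yr = (yy - cy - dy) / scale
        xr = (xx - cx - dx) / scale
        row_map = cy + yr * np.cos(ang) - xr * np.sin(ang)
        col_map = cx + yr * np.sin(ang) + xr * np.cos(ang)
        image, mask = _warp(image, mask, row_map, col_map)

    if "elastic_transform" in cfg.enabled and rng.random() < cfg.p_elastic_transform:
        dr = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)),
                                     cfg.elastic_sigma) * cfg.elastic_alpha
        dc = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)),
                                     cfg.elastic_sigma) * cfg.elastic_alpha
        image, mask = _warp(image, mask, yy + dr, xx + dc)

    if "grid_distortion" in cfg.enabled and rng.random() < cfg.p_grid_distortion:
        def axis_map(n):
            mult = 1.0 + rng.uniform(-cfg.grid_limit, cfg.grid_limit,
                                     cfg.grid_steps)
            steps = np.r_[0.0, np.cumsum(mult)]
            nodes_out = steps / steps[-1] * (n - 1)
            nodes_in = np.linspace(0.0, n - 1, cfg.grid_steps + 1)
            return np.interp(np.arange(n), nodes_out, nodes_in)
        row_axis = axis_map(h)
        col_axis = axis_map(w)
        image, mask = _warp(image, mask,
                            *np.meshgrid(row_axis, col_axis, indexing="ij"))

    if "optical_distortion" in cfg.enabled and rng.random() < cfg.p_optical_distortion:
        k = rng.uniform(-cfg.optical_limit, cfg.optical_limit)
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        u = (xx - cx) / cx
        v = (yy - cy) / cy
        r2 = u ** 2 + v ** 2
        image, mask = _warp(image, mask,
                            cy + v * (1 + k * r2) * cy,
                            cx + u * (1 + k * r2) * cx)

    if ("random_brightness_contrast" in cfg.enabled
            and rng.random() < cfg.p_random_brightness_contrast):
        b = rng.uniform(-cfg.brightness_limit, cfg.brightness_limit)
        c = rng.uniform(-cfg.contrast_limit, cfg.contrast_limit)
        image = np.clip((image - 0.5) * (1.0 + c) + 0.5 + b, 0.0, 1.0)

    if "invert" in cfg.enabled and rng.random() < cfg.p_invert:
        image = 1.0 - image

    return image, mask


# ---------------------------------------------------------------------------
# data loading
# ---------------------------------------------------------------------------

def load_pairs(manifest_path, input_size: int):
    """Load all image/mask pairs of a manifest, resized for the network.

    Returns (images (N,1,S,S) float32, masks (N,S,S) uint8, manifest df).
    Relative manifest paths are resolved against the manifest location.
    """
    manifest = io.read_manifest(manifest_path)
    if len(manifest) == 0:
        raise ParameterError(f"manifest {manifest_path} is empty")
    base = Path(manifest_path).parent
    imgs, masks = [], []
    for rec in manifest.itertuples():
        img = io.read_image(base / rec.image_path)
        msk = io.read_mask(base / rec.mask_path)
        imgs.append(resize_image(img, (input_size, input_size)))
        masks.append(resize_mask(msk, (input_size, input_size)))
    x = np.asarray(imgs, dtype=nn.DTYPE)[:, None]
    y = np.asarray(masks, dtype=np.uint8)
    return x, y, manifest


def _foreground_miou(model: AlbuNet, x: np.ndarray, y: np.ndarray,
                     batch: int) -> tuple[float, float]:
    """(summed val loss per batch avg, foreground mIoU) in eval mode."""
    total = None
    losses = []
    for i in range(0, len(x), batch):
        probs = model.forward(x[i:i + batch], train=False)
        losses.append(jaccard_loss(probs, y[i:i + batch]))
        pred = probs.argmax(axis=1).astype(np.uint8)
        for p, t in zip(pred, y[i:i + batch]):
            cc = confusion(p, t)
            total = cc if total is None else total + cc
    return float(np.mean(losses)), seg_metrics(total).miou


def train(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    train_manifest,
    val_manifest,
) -> tuple[AlbuNet, pd.DataFrame]:
    """Train the network; return the best-validation model and history.

    History has one row per epoch: epoch, train_loss, val_loss, val_miou.
    Fully reproducible for a fixed seed (single-threaded deterministic
    mode is the only mode).
    """
    if model_cfg.input_size_px != train_cfg.input_size_px:
        model_cfg = replace(model_cfg, input_size_px=train_cfg.input_size_px)
    s = train_cfg.input_size_px
    x_tr, y_tr, _ = load_pairs(train_manifest, s)
    x_va, y_va, _ = load_pairs(val_manifest, s)

    root = np.random.SeedSequence(train_cfg.seed)
    init_seed, shuffle_seed, aug_root = root.spawn(3)
    model = build_model(model_cfg,
                        seed=int(init_seed.generate_state(1, np.uint32)[0]))
    opt = nn.SGD(model.params(), lr=train_cfg.learning_rate,
                 momentum=train_cfg.momentum)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    augment_on = bool(train_cfg.augment.enabled)

    history = []
    best = (-np.inf, None, None)
    n = len(x_tr)
    for epoch in range(1, train_cfg.epochs + 1):
        perm = shuffle_rng.permutation(n)
        batch_losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = perm[start:start + train_cfg.batch_size]
            if augment_on:
                xb = np.empty((len(idx), 1, s, s), dtype=nn.DTYPE)
                yb = np.empty((len(idx), s, s), dtype=np.uint8)
                for j, i in enumerate(idx):
                    # per-sample stream independent of batch composition
                    aug_seed = int(np.random.SeedSequence(
                        entropy=train_cfg.seed,
                        spawn_key=(epoch, int(i)),
                    ).generate_state(1, np.uint32)[0])
                    img, msk = augment_pair(x_tr[i, 0], y_tr[i],
                                            train_cfg.augment, aug_seed)
                    xb[j, 0] = img
                    yb[j] = msk
            else:
                xb, yb = x_tr[idx], y_tr[idx]
            probs = model.forward(xb, train=True)
            loss, dprobs = soft_jaccard_with_grad(
                probs, yb, train_cfg.smooth_eps, reduction="sum"
            )
            batch_losses.append(loss / len(idx))
            opt.zero_grad()
            model.backward(dprobs)
            opt.step()
        val_loss, val_miou = _foreground_miou(model, x_va, y_va,
                                              train_cfg.batch_size)
        history.append(dict(epoch=epoch,
                            train_loss=float(np.mean(batch_losses)),
                            val_loss=val_loss, val_miou=val_miou))
        if val_miou > best[0]:
            best = (val_miou, copy.deepcopy(model.get_state()), epoch)

    if best[1] is not None:
        model.set_state(best[1])
    history_df = pd.DataFrame(history)
    model.training_meta = dict(
        epochs=train_cfg.epochs,
        best_epoch=best[2],
        best_val_miou=float(best[0]),
        final_train_loss=history[-1]["train_loss"],
        seed=train_cfg.seed,
    )
    return model, history_df


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_mask(model, image: np.ndarray) -> np.ndarray:
    """Segment one image; label map returned at the original resolution.

    ``model`` is a network instance or a checkpoint path.  The image is
    resized to the network input size (bilinear), the argmax label map is
    upscaled back with nearest neighbour.  CTR extraction operates on this
    full-resolution map.
    """
    if not isinstance(model, AlbuNet):
        from .model import load_checkpoint
        model, _ = load_checkpoint(model)
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got {image.shape}")
    s = model.cfg.input_size_px
    x = resize_image(image, (s, s)).astype(nn.DTYPE)[None, None]
    probs = model.forward(x, train=False)
    labels = probs.argmax(axis=1)[0].astype(np.uint8)
    return resize_mask(labels, image.shape)
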