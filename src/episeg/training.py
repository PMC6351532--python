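"""Patch sampling, class-occurrence loss weighting, augmentation, training loop.

The two networks are trained the same way apart from their sampling strategy
and schedule patience:

* IHC net — patches sampled over tissue with annotated artefact regions
  oversampled (to drive down false positives on stained debris), patience 5;
* H&E net — patch centres sampled uniformly over the two classes, patience 10,
  plus per-pixel *class-occurrence* loss weights: each pixel's loss is scaled
  by the inverse frequency of its class within the patch, so patches whose
  epithelium consists of a few isolated tumour cells still contribute strongly
  to the gradient.

Optimisation is Adam with beta1 = beta2 = 0.99, learning rate 5e-4, batch
size 1; the learning rate is halved after every `patience` consecutive epochs
without validation improvement, and the best-validation checkpoint is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, zoom

from . import nn
from .stains import STAIN_PRESETS, stain_space_augment
from .unet import UNet

__all__ = [
    "PatchSample",
    "SamplerConfig",
    "AugmentConfig",
    "TrainingSchedule",
    "sample_patch",
    "pixel_weights",
    "augment",
    "simulate_lr_schedule",
    "train",
]

logger = logging.getLogger(__name__)


@dataclass
class PatchSample:
    """Co-registered image patch, binary label patch and per-pixel loss
    weights (mean exactly 1); ``origin`` records (slide id, row, col)."""

    image: np.ndarray
    labels: np.ndarray
    weights: np.ndarray
    origin: tuple = ("", 0, 0)
    resolution_um_per_px: float = 0.48

    def __post_init__(self):
        if not (self.image.shape[:2] == self.labels.shape == self.weights.shape):
            raise ValueError("image/labels/weights spatial shapes differ")


@dataclass(frozen=True)
class SamplerConfig:
    """``uniform_over_classes`` draws the centre-pixel class uniformly from
    {epithelium, background}; ``artefact_oversampled`` samples centres over
    tissue with annotated artefact regions weighted ``oversample_factor``-fold.
    """

    mode: str = "uniform_over_classes"
    patch_size: int = 512
    oversample_factor: float = 3.0

    def __post_init__(self):
        if self.mode not in ("uniform_over_classes", "artefact_oversampled"):
            raise ValueError(f"unknown sampler mode {self.mode!r}")
        if self.oversample_factor < 1:
            raise ValueError("oversample_factor must be >= 1")


def pixel_weights(labels: np.ndarray, f_min: float | None = None) -> np.ndarray:
    """Class-occurrence loss weights: ``w = 1 / (2 * max(f_c, f_min))`` where
    ``f_c`` is the fraction of the patch occupied by the pixel's class.

    The floor ``f_min`` (default ``1 / patch area``) bounds the weight when a
    class covers only a handful of pixels; the map is then renormalised to
    mean exactly 1, which keeps the loss magnitude independent of the class
    mix (a balanced 50/50 patch gets all-ones).
    """
    labels = np.asarray(labels).astype(bool)
    if labels.size == 0:
        raise ValueError("empty patch")
    if f_min is None:
        f_min = 1.0 / labels.size
    f_pos = float(labels.mean())
    w_pos = 1.0 / (2.0 * max(f_pos, f_min))
    w_neg = 1.0 / (2.0 * max(1.0 - f_pos, f_min))
    w = np.where(labels, w_pos, w_neg)
    return w / w.mean()


def _mirror_pad(arr: np.ndarray, pad: int) -> np.ndarray:
    widths = ((pad, pad), (pad, pad)) + ((0, 0),) * (arr.ndim - 2)
    return np.pad(arr, widths, mode="reflect")


def sample_patch(
    image: np.ndarray,
    mask: np.ndarray,
    config: SamplerConfig,
    rng: np.random.Generator | int | None = None,
    artefact_mask: np.ndarray | None = None,
    tissue_mask: np.ndarray | None = None,
    slide_id: str = "",
    resolution_um_per_px: float = 0.48,
) -> PatchSample:
    """Draw one training patch; borders are mirror-padded so any pixel can be
    a patch centre.

    If the requested class has no pixels in the slide, sampling falls back to
    the other class and logs a warning.
    """
    rng = np.random.default_rng(rng)
    mask = np.asarray(mask, dtype=bool)
    if config.mode == "uniform_over_classes":
        want = bool(rng.integers(2))  # True = epithelium
        candidates = np.flatnonzero(mask == want)
        if candidates.size == 0:
            logger.warning(
                "slide %r has no %s pixels; sampling the other class instead",
                slide_id, "epithelium" if want else "background",
            )
            candidates = np.flatnonzero(mask == (not want))
    else:
        base = (np.asarray(tissue_mask, dtype=bool) if tissue_mask is not None
                else np.ones_like(mask))
        density = base.astype(float)
        if artefact_mask is not None:
            density += (config.oversample_factor - 1.0) * (np.asarray(artefact_mask, bool) & base)
        candidates = np.flatnonzero(density > 0)
        probs = density.ravel()[candidates]
        probs = probs / probs.sum()
        pick = int(rng.choice(candidates, p=probs))
        return _extract(image, mask, pick, config.patch_size, slide_id, resolution_um_per_px)
    pick = int(rng.choice(candidates))
    return _extract(image, mask, pick, config.patch_size, slide_id, resolution_um_per_px)


def _extract(image, mask, flat_index, patch, slide_id, res) -> PatchSample:
    r, c = np.unravel_index(flat_index, mask.shape)
    half = patch // 2
    img_p = _mirror_pad(np.asarray(image, dtype=float), half)
    msk_p = _mirror_pad(mask, half)
    img = img_p[r:r + patch, c:c + patch]
    lab = msk_p[r:r + patch, c:c + patch]
    return PatchSample(image=img, labels=lab, weights=pixel_weights(lab),
                       origin=(slide_id, int(r), int(c)), resolution_um_per_px=res)


@dataclass(frozen=True)
class AugmentConfig:
    """Which augmentations run, with their ranges.  Geometric transforms are
    applied identically to image, labels (nearest) and weights; photometric
    transforms touch the image only."""

    flip: bool = True
    rotate90: bool = True
    scaling: tuple[float, float] | None = None  # e.g. (0.9, 1.1); H&E training
    noise_sigma: float = 0.0
    blur_sigma: tuple[float, float] | None = None
    brightness: tuple[float, float] | None = None  # additive
    contrast: tuple[float, float] | None = None  # multiplicative about the mean
    saturation: tuple[float, float] | None = None
    he_stain: tuple[float, float] | None = None  # concentration scale range

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        return cls(flip=False, rotate90=False)


def _rescale_keep_size(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Zoom by ``factor`` about the patch centre, cropping/padding (reflect)
    back to the original shape."""
    h, w = arr.shape[:2]
    zoomed = zoom(arr.astype(float), (factor, factor) + (1,) * (arr.ndim - 2), order=order)
    zh, zw = zoomed.shape[:2]
    if zh >= h:
        r0, c0 = (zh - h) // 2, (zw - w) // 2
        return zoomed[r0:r0 + h, c0:c0 + w]
    pr, pc = h - zh, w - zw
    widths = ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)) + ((0, 0),) * (arr.ndim - 2)
    return np.pad(zoomed, widths, mode="reflect")


def augment(
    sample: PatchSample,
    config: AugmentConfig = AugmentConfig(),
    rng: np.random.Generator | int | None = None,
) -> PatchSample:
    """Random geometric + photometric augmentation of one patch; reproducible
    under a fixed ``rng`` seed."""
    rng = np.random.default_rng(rng)
    img = np.asarray(sample.image, dtype=float).copy()
    lab = sample.labels.copy()
    wgt = sample.weights.copy()

    if config.flip and rng.integers(2):
        img, lab, wgt = img[::-1], lab[::-1], wgt[::-1]
    if config.flip and rng.integers(2):
        img, lab, wgt = img[:, ::-1], lab[:, ::-1], wgt[:, ::-1]
    if config.rotate90:
        k = int(rng.integers(4))
        img = np.rot90(img, k)
        lab = np.rot90(lab, k)
        wgt = np.rot90(wgt, k)
    if config.scaling is not None:
        factor = rng.uniform(*config.scaling)
        img = _rescale_keep_size(img, factor, order=1)
        lab = _rescale_keep_size(lab.astype(float), factor, order=0) > 0.5
        wgt = _rescale_keep_size(wgt, factor, order=1)

    if config.blur_sigma is not None:
        sigma = rng.uniform(*config.blur_sigma)
        if sigma > 0:
            img = gaussian_filter(img, (sigma, sigma, 0))
    if config.noise_sigma > 0:
        img = img + rng.normal(0, config.noise_sigma, img.shape)
    if config.brightness is not None:
        img = img + rng.uniform(*config.brightness)
    if config.contrast is not None:
        img = (img - img.mean()) * rng.uniform(*config.contrast) + img.mean()
    if config.saturation is not None:
        gray = img.mean(axis=2, keepdims=True)
        img = gray + (img - gray) * rng.uniform(*config.saturation)
    if config.he_stain is not None:
        img = stain_space_augment(
            np.clip(img, 0, 1), STAIN_PRESETS["he"], scale_range=config.he_stain,
            rng=rng, channels=("haematoxylin", "eosin"),
        )
    img = np.clip(img, 0.0, 1.0)
    return replace(sample, image=np.ascontiguousarray(img),
                   labels=np.ascontiguousarray(lab),
                   weights=np.ascontiguousarray(wgt))


@dataclass(frozen=True)
class TrainingSchedule:
    """Adam schedule with plateau halving (patience 5 for the IHC net, 10 for
    the H&E net)."""

    initial_lr: float = 5e-4
    beta1: float = 0.99
    beta2: float = 0.99
    batch_size: int = 1
    plateau_patience: int = 5
    lr_halving_factor: float = 0.5
    improvement_tol: float = 1e-4
    max_epochs: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.initial_lr <= 0 or self.plateau_patience < 1:
            raise ValueError("lr must be > 0 and patience >= 1")


def simulate_lr_schedule(
    val_metrics, initial_lr: float = 5e-4, patience: int = 5,
    factor: float = 0.5, tol: float = 1e-4, baseline: float | None = None,
) -> list[float]:
    """Learning rate in force *during* each epoch, given that epoch's
    validation metric (lower is better).

    The best value starts at ``baseline`` (the pre-training validation metric;
    +inf if None, matching a freshly initialised net with no evaluation).  The
    rate is halved after every ``patience`` consecutive epochs without
    improvement; the counter resets both on improvement and after a halving.
    """
    best = np.inf if baseline is None else baseline
    lr = initial_lr
    out = []
    stall = 0
    for v in val_metrics:
        out.append(lr)
        if v < best - tol:
            best = v
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                lr *= factor
                stall = 0
    return out


def _epoch_pass(model, samples, optimiser=None):
    """One pass over samples; returns the mean weighted cross-entropy.  With
    an optimiser, backpropagates and steps per sample (batch size 1)."""
    losses = []
    train = optimiser is not None
    for s in samples:
        x = np.ascontiguousarray(s.image.transpose(2, 0, 1), dtype=np.float32)[None]
        y = s.labels[None]
        w = s.weights[None].astype(np.float32)
        logits = model.forward(x, train=train)
        loss, dlogits = nn.weighted_cross_entropy(logits, y, w)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at patch origin {s.origin}"
            )
        if train:
            optimiser.zero_grad()
            model.backward(dlogits)
            optimiser.step()
        losses.append(loss)
    return float(np.mean(losses))


def train(
    model: UNet,
    train_sampler,
    val_sampler,
    schedule: TrainingSchedule = TrainingSchedule(),
    augment_config: AugmentConfig | None = None,
) -> pd.DataFrame:
    """Train a U-Net with per-pixel weighted cross-entropy and plateau halving.

    ``train_sampler``/``val_sampler`` are either fixed sequences of
    :class:`PatchSample` or callables ``(epoch, rng) -> sequence``.  Validation
    runs before training (the plateau baseline) and after every epoch; the
    learning rate follows :func:`simulate_lr_schedule` exactly; the
    best-validation weights are restored into ``model`` at the end.  Returns a
    history frame with per-epoch train loss, validation loss and learning rate.
    """
    rng = np.random.default_rng(schedule.seed)
    optimiser = nn.Adam(model.params(), lr=schedule.initial_lr,
                        beta1=schedule.beta1, beta2=schedule.beta2)

    def draw(sampler, epoch):
        return sampler(epoch, rng) if callable(sampler) else sampler

    def maybe_augment(samples, epoch):
        if augment_config is None:
            return samples
        return [augment(s, augment_config, np.random.default_rng(rng.integers(2**31)))
                for s in samples]

    best_val = _epoch_pass(model, draw(val_sampler, -1))
    best_state = model.get_state()
    stall = 0
    rows = []
    for epoch in range(1, schedule.max_epochs + 1):
        train_loss = _epoch_pass(model, maybe_augment(draw(train_sampler, epoch), epoch),
                                 optimiser)
        val_loss = _epoch_pass(model, draw(val_sampler, epoch))
        rows.append({"epoch": epoch, "train_loss": train_loss,
                     "val_loss": val_loss, "lr": optimiser.lr})
        if val_loss < best_val - schedule.improvement_tol:
            best_val = val_loss
            best_state = model.get_state()
            stall = 0
        else:
            stall += 1
            if stall >= schedule.plateau_patience:
                optimiser.lr *= schedule.lr_halving_factor
                stall = 0
    model.set_state(best_state)
    return pd.DataFrame(rows)
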