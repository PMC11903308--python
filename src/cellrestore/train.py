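"""Training orchestration: schedules, augmentation, and the two trainers.

``train_segmentation`` fits a flow-field segmentation network directly on
(optionally degraded) images — with clean inputs it produces the frozen
network that the restoration losses look through; with ``degrade_inputs``
it reproduces the retrain-on-noisy baseline.  ``train_restoration`` fits a
restoration network on freshly degraded inputs against a weighted
combination of reconstruction, segmentation and perceptual losses.

The learning-rate schedule ramps linearly from 0 to ``base_lr`` over the
warmup epochs, plateaus, then halves every ``halving_period`` epochs over
the final ``10 * halving_period`` epochs (at the reference scale of 2000
epochs: warmup 10, halving every 10 over the last 100).  Degradations are
resampled fresh every epoch so the noise differs between visits to the
same image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .degrade import DegradeConfig, apply_degradation, normalize_percentile, sample_degradation
from .flows import FlowTarget, masks_to_flows, relabel
from .losses import LossWeights, seg_output_loss, total_loss
from .nets import NetConfig, UNet, build_net
from .simcells import LabeledImage


@dataclass
class TrainConfig:
    epochs: int = 2000
    batch_size: int = 8
    base_lr: float = 0.001
    warmup_epochs: int = 10
    halving_period: int = 10
    optimizer: str = "adamw"
    momentum: float = 0.9
    weight_decay: float = 1e-5
    weights: LossWeights = field(default_factory=LossWeights)
    degrade: DegradeConfig = field(default_factory=DegradeConfig)
    net: NetConfig | None = None
    crop_pre: int | None = 340
    crop_final: int = 224
    diameter_target: float = 30.0
    resize_pre_range: tuple = (0.5, 2.0)
    resize_aug_range: tuple = (0.75, 1.25)
    rotate: bool = True
    sample_weights: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.crop_pre is not None and self.crop_final > self.crop_pre:
            raise ValueError("crop_final must not exceed crop_pre")
        if self.epochs < self.warmup_epochs:
            raise ValueError("epochs must be >= warmup_epochs")
        if self.optimizer not in ("adamw", "sgd"):
            raise ValueError("optimizer must be 'adamw' or 'sgd'")

    @classmethod
    def sgd_baseline(cls, **overrides) -> "TrainConfig":
        """Classic from-scratch segmentation recipe: SGD, 500 epochs, batch 8,
        learning rate 0.2, momentum 0.9, weight decay 1e-5."""
        cfg = cls(
            epochs=500, batch_size=8, base_lr=0.2, optimizer="sgd",
            momentum=0.9, weight_decay=1e-5, warmup_epochs=10, halving_period=10,
        )
        return replace(cfg, **overrides)


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Learning rate at ``epoch``: linear warmup, plateau, then halvings."""
    if not 0 <= epoch < config.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.epochs})")
    if epoch < config.warmup_epochs:
        return config.base_lr * epoch / config.warmup_epochs
    decay_start = max(config.warmup_epochs, config.epochs - 10 * config.halving_period)
    if epoch >= decay_start:
        k = (epoch - decay_start) // config.halving_period + 1
        return config.base_lr / 2.0**k
    return config.base_lr


# -- optimizers ------------------------------------------------------------

class SGD:
    """Momentum SGD with L2 weight decay folded into the gradient."""

    def __init__(self, params, momentum: float = 0.9, weight_decay: float = 1e-5):
        self.params = [p for p in params if p.requires_grad]
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.buffers = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, buf in zip(self.params, self.buffers):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data = p.data - lr * buf

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class AdamW:
    """AdamW with decoupled weight decay."""

    def __init__(self, params, betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-5):
        self.params = [p for p in params if p.requires_grad]
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data = p.data - lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _make_optimizer(net: UNet, config: TrainConfig):
    if config.optimizer == "sgd":
        return SGD(net.parameters(), config.momentum, config.weight_decay)
    return AdamW(net.parameters(), weight_decay=config.weight_decay)


# -- augmentation ----------------------------------------------------------

@dataclass
class Transform:
    """One geometric augmentation applied identically to image, target, mask."""

    angle: float = 0.0  # degrees
    flip: bool = False
    scale: float = 1.0
    center: tuple[float, float] | None = None  # input-space crop center (y, x)

    @classmethod
    def identity(cls) -> "Transform":
        return cls()


def draw_transform(rng: np.random.Generator, config: TrainConfig, shape) -> Transform:
    h, w = shape[:2]
    return Transform(
        angle=float(rng.uniform(0, 360)) if config.rotate else 0.0,
        flip=bool(rng.random() < 0.5),
        scale=float(rng.uniform(*config.resize_aug_range)),
        center=(float(rng.uniform(0.3 * h, 0.7 * h)), float(rng.uniform(0.3 * w, 0.7 * w))),
    )


def _apply_transform(arr: np.ndarray, tf: Transform, out_size: int, order: int) -> np.ndarray:
    h, w = arr.shape[:2]
    cy, cx = tf.center if tf.center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    theta = np.deg2rad(tf.angle)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    flip = np.diag([1.0, -1.0 if tf.flip else 1.0])
    m = (rot @ flip) / tf.scale  # output -> input coordinates
    c_out = (out_size - 1) / 2.0
    offset = np.array([cy, cx]) - m @ np.array([c_out, c_out])
    return ndi.affine_transform(
        arr, m, offset=offset, output_shape=(out_size, out_size), order=order,
        mode="mirror", prefilter=(order > 1),
    )


def augment_pair(
    clean: LabeledImage,
    degraded: np.ndarray,
    rng: np.random.Generator,
    config: TrainConfig,
    transform: Transform | None = None,
):
    """Crop/rotate/flip/resize input, target and mask with one shared draw.

    Returns ``(input_crop, target_crop, flow_target)`` where the flow target
    is recomputed from the transformed mask (nearest-neighbour resampled so
    labels stay integral).
    """
    size = config.crop_final
    if size > min(clean.image.shape[:2]):
        raise ValueError("crop_final larger than the image")
    tf = transform if transform is not None else draw_transform(rng, config, clean.image.shape)
    inp = _apply_transform(np.asarray(degraded, np.float32), tf, size, order=1)
    tgt = _apply_transform(np.asarray(clean.image, np.float32), tf, size, order=1)
    m = _apply_transform(clean.masks.astype(np.int32), tf, size, order=0)
    ft = masks_to_flows(relabel(m))
    return inp, tgt, ft


# -- trainers --------------------------------------------------------------

def resize_to_diameter(li: LabeledImage, target: float) -> LabeledImage:
    """Resize an image/mask pair so its mean object diameter equals ``target``."""
    scale = target / li.diameter
    if abs(scale - 1.0) < 0.01:
        return li
    from skimage.transform import rescale

    img = rescale(li.image, scale, order=1, preserve_range=True, anti_aliasing=scale < 1)
    m = rescale(li.masks, scale, order=0, preserve_range=True, anti_aliasing=False)
    return LabeledImage(
        image=img.astype(np.float32), masks=relabel(m.astype(np.int32)), diameter=target
    )


def _prepare_clean(li: LabeledImage, config: TrainConfig) -> LabeledImage:
    if config.diameter_target is not None:
        li = resize_to_diameter(li, config.diameter_target)
    return LabeledImage(
        image=normalize_percentile(li.image), masks=li.masks, diameter=li.diameter
    )


def _pre_view(li: LabeledImage, rng: np.random.Generator, config: TrainConfig) -> LabeledImage:
    """Pre-degradation random resize (0.5-2x) and crop, so noise is added at
    varied spatial scales.  Skipped when ``crop_pre`` is None (desk scale)."""
    if config.crop_pre is None:
        return li
    from skimage.transform import rescale

    h, w = li.masks.shape
    lo, hi = config.resize_pre_range
    lo = max(lo, config.crop_pre / min(h, w))  # keep the crop feasible
    s = float(rng.uniform(lo, max(hi, lo)))
    img = rescale(li.image, s, order=1, preserve_range=True, anti_aliasing=s < 1)
    m = rescale(li.masks, s, order=0, preserve_range=True, anti_aliasing=False).astype(np.int32)
    hh, ww = m.shape
    cy = int(rng.integers(0, hh - config.crop_pre + 1))
    cx = int(rng.integers(0, ww - config.crop_pre + 1))
    sl = (slice(cy, cy + config.crop_pre), slice(cx, cx + config.crop_pre))
    return LabeledImage(
        image=img[sl].astype(np.float32), masks=relabel(m[sl]), diameter=li.diameter * s
    )


def _sample_indices(rng, n: int, config: TrainConfig) -> np.ndarray:
    if config.sample_weights is not None:
        p = np.asarray(config.sample_weights, dtype=np.float64)
        p = p / p.sum()
        return rng.choice(n, size=n, p=p)
    return rng.permutation(n)


def _epoch_batches(indices: np.ndarray, batch_size: int):
    for start in range(0, len(indices), batch_size):
        batch = indices[start : start + batch_size]
        if len(batch):
            yield batch


def train_segmentation(
    dataset: list[LabeledImage],
    config: TrainConfig,
    degrade_inputs: bool = False,
) -> tuple[UNet, list[dict]]:
    """Fit a flow-field segmentation network on (optionally degraded) images.

    With ``degrade_inputs`` the degradation sampler is the same one used for
    restoration training, reproducing the retrain-on-noisy baseline.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    net_cfg = config.net or NetConfig(out_mode="segment", seed=config.seed)
    if net_cfg.out_mode != "segment":
        raise ValueError("segmentation training needs a 'segment'-mode net config")
    net = build_net(net_cfg)
    opt = _make_optimizer(net, config)
    rng = np.random.default_rng(config.seed)
    clean = [_prepare_clean(li, config) for li in dataset]
    log: list[dict] = []
    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        losses = []
        for batch in _epoch_batches(_sample_indices(rng, len(clean), config), config.batch_size):
            xs, fts = [], []
            for i in batch:
                li = _pre_view(clean[i], rng, config)
                if degrade_inputs:
                    spec = sample_degradation(config.degrade, li.diameter, rng)
                    x = apply_degradation(li, spec, rng)
                else:
                    x = li.image
                inp, _, ft = augment_pair(li, x, rng, config)
                xs.append(inp)
                fts.append(ft)
            x_in = np.stack(xs)[:, None].astype(np.float32)
            opt.zero_grad()
            out = net(x_in)
            loss = seg_output_loss(out, fts, flow_scale=config.weights.flow_scale)
            loss.backward()
            opt.step(lr)
            losses.append(loss.item())
        log.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))})
    return net, log


def train_restoration(
    dataset: list[LabeledImage],
    seg_net: UNet,
    config: TrainConfig,
) -> tuple[UNet, list[dict]]:
    """Fit a restoration network against the weighted three-term objective.

    ``seg_net`` must be pretrained and frozen; its parameters are guaranteed
    untouched.  Degradations are resampled every epoch.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    if not getattr(seg_net, "frozen", False):
        raise ValueError("seg_net must be frozen (seg_net.freeze()) before restoration training")
    net_cfg = config.net or NetConfig(out_mode="restore", seed=config.seed + 1)
    if net_cfg.out_mode != "restore":
        raise ValueError("restoration training needs a 'restore'-mode net config")
    restorer = build_net(net_cfg)
    opt = _make_optimizer(restorer, config)
    rng = np.random.default_rng(config.seed)
    clean = [_prepare_clean(li, config) for li in dataset]
    log: list[dict] = []
    for epoch in range(config.epochs):
        lr = lr_schedule(epoch, config)
        breakdown_sums: dict[str, float] = {}
        n_batches = 0
        for batch in _epoch_batches(_sample_indices(rng, len(clean), config), config.batch_size):
            xs, ts, fts = [], [], []
            for i in batch:
                li = _pre_view(clean[i], rng, config)
                spec = sample_degradation(config.degrade, li.diameter, rng)
                degraded = apply_degradation(li, spec, rng)
                inp, tgt, ft = augment_pair(li, degraded, rng, config)
                xs.append(inp)
                ts.append(tgt)
                fts.append(ft)
            x_in = np.stack(xs)[:, None].astype(np.float32)
            t_in = np.stack(ts)[:, None].astype(np.float32)
            opt.zero_grad()
            restored = restorer(x_in)
            loss, terms = total_loss(restored, t_in, fts, seg_net, config.weights)
            loss.backward()
            opt.step(lr)
            for k, v in terms.items():
                breakdown_sums[k] = breakdown_sums.get(k, 0.0) + v
            n_batches += 1
        entry = {"epoch": epoch, "lr": lr}
        entry.update({k: v / n_batches for k, v in breakdown_sums.items()})
        log.append(entry)
    return restorer, log


def write_log(log: list[dict], path) -> None:
    """Write a per-epoch training log as JSON lines."""
    with open(path, "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
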