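"""Heatmap-regression keypoint detector.

A U-Net-style encoder–decoder maps an RGB fundus image to three response
planes (crossover, bifurcation, combined) of the same spatial size, trained
with mean squared error against Gaussian target heatmaps.  The final layer
is linear: predictions may transiently leave [0, 1] and are clipped only at
keypoint extraction.

Training uses single-image batches with random affine and HSV augmentation,
Adam, and a reduce-on-plateau learning-rate schedule driven by validation
loss: the rate starts at ``lr_init`` and is multiplied by ``lr_factor``
whenever validation loss fails to improve for ``lr_patience`` training
steps; training stops when the next reduction would fall below ``lr_floor``
(or when an optional step cap is reached).  The parameters with the best
validation loss are returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from .geometry import AffineRanges, sample_affine
from .heatmaps import (
    DEFAULT_THRESHOLD,
    DEFAULT_WINDOW,
    HeatmapStack,
    extract_keypoints,
)
from .keypoints import KeypointSet
from .multiview import PhotometricAugment, photometric_augment
from .nn import Adam, Conv2d, MaxPool2, ReLU, Upsample2, zero_grads


# ---------------------------------------------------------------------------
# network


class UNet:
    """Encoder–decoder FCN; input (1, 3, H, W) -> output (1, 3, H, W).

    ``levels`` resolution levels with channel widths ``width * 2**l``,
    2x max-pool downsampling and nearest-neighbour upsampling with skip
    concatenation.  H and W must be multiples of ``2**(levels-1)``.
    """

    def __init__(self, in_ch=3, out_ch=3, levels=4, width=32, rng=None):
        rng = rng or np.random.default_rng(0)
        self.levels = levels
        self.width = width
        ch = [width * 2**l for l in range(levels)]
        self.enc = []
        c_prev = in_ch
        for c in ch:
            self.enc.append(
                [Conv2d(c_prev, c, 3, pad=1, rng=rng), ReLU(), Conv2d(c, c, 3, pad=1, rng=rng), ReLU()]
            )
            c_prev = c
        self.pools = [MaxPool2() for _ in range(levels - 1)]
        self.ups = [Upsample2() for _ in range(levels - 1)]
        self.dec = []
        for l in range(levels - 2, -1, -1):
            cin = ch[l] + ch[l + 1]
            self.dec.append(
                [Conv2d(cin, ch[l], 3, pad=1, rng=rng), ReLU(), Conv2d(ch[l], ch[l], 3, pad=1, rng=rng), ReLU()]
            )
        self.final = Conv2d(ch[0], out_ch, 1, rng=rng)

    def _blocks(self):
        for blk in self.enc + self.dec:
            yield from blk
        yield self.final

    def params(self):
        return [p for l in self._blocks() for p in l.params()]

    def grads(self):
        return [g for l in self._blocks() for g in l.grads()]

    def forward(self, x, train=True):
        skips = []
        for l in range(self.levels):
            for layer in self.enc[l]:
                x = layer.forward(x, train=train)
            if l < self.levels - 1:
                skips.append(x)
                x = self.pools[l].forward(x, train=train)
        self._skip_ch = []
        for i, l in enumerate(range(self.levels - 2, -1, -1)):
            x = self.ups[i].forward(x, train=train)
            skip = skips[l]
            self._skip_ch.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            for layer in self.dec[i]:
                x = layer.forward(x, train=train)
        return self.final.forward(x, train=train)

    def backward(self, gy):
        gy = self.final.backward(gy)
        gskip_at_level = [None] * (self.levels - 1)
        for i in range(len(self.dec) - 1, -1, -1):
            g = gy
            for layer in reversed(self.dec[i]):
                g = layer.backward(g)
            c = self._skip_ch[i]
            gskip_at_level[self.levels - 2 - i] = g[:, :c]
            gy = self.ups[i].backward(g[:, c:])
        for l in range(self.levels - 1, -1, -1):
            if l < self.levels - 1:
                gy = self.pools[l].backward(gy)
                gy = gy + gskip_at_level[l]
            for layer in reversed(self.enc[l]):
                gy = layer.backward(gy)
        return gy

    def zero_grads(self):
        for g in self.grads():
            g[...] = 0.0


@dataclass
class DetectorModel:
    unet: UNet
    threshold: float = DEFAULT_THRESHOLD
    window: int = DEFAULT_WINDOW

    def predict(self, image: np.ndarray) -> HeatmapStack:
        """Regress the three-plane heatmap stack for an RGB [0,1] image."""
        x, crop = _pad_to_multiple(image, 2 ** (self.unet.levels - 1))
        x = x.transpose(2, 0, 1)[None].astype(np.float32)
        y = self.unet.forward(x, train=False)[0]
        y = y[:, crop[0] : crop[0] + image.shape[0], crop[1] : crop[1] + image.shape[1]]
        return HeatmapStack(y, sigma=0.0)


def _pad_to_multiple(image, m):
    h, w = image.shape[:2]
    ph = (-h) % m
    pw = (-w) % m
    if ph == 0 and pw == 0:
        return image, (0, 0)
    padded = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect")
    return padded, (0, 0)


def detect(
    model: DetectorModel,
    image: np.ndarray,
    threshold: float | None = None,
    window: int | None = None,
) -> KeypointSet:
    """Predict heatmaps and extract discrete, classified keypoints."""
    stack = model.predict(image)
    return extract_keypoints(
        stack,
        threshold if threshold is not None else model.threshold,
        window if window is not None else model.window,
    )


# ---------------------------------------------------------------------------
# learning-rate schedule


class PlateauSchedule:
    """Reduce-on-plateau schedule with patience counted in training steps."""

    def __init__(self, lr_init=1e-4, factor=0.1, patience=2500, floor=1e-7):
        self.lr = lr_init
        self.factor = factor
        self.patience = patience
        self.floor = floor
        self.best = np.inf
        self.since = 0
        self.stopped = False

    def update(self, val_loss: float | None = None):
        """Advance one training step, optionally with a fresh validation loss."""
        if self.stopped:
            return
        self.since += 1
        if val_loss is not None and val_loss < self.best:
            self.best = val_loss
            self.since = 0
        if self.since >= self.patience:
            new_lr = self.lr * self.factor
            if new_lr < self.floor * (1.0 - 1e-12):
                self.stopped = True
            else:
                self.lr = new_lr
            self.since = 0


# ---------------------------------------------------------------------------
# training


@dataclass
class DetectorTrainConfig:
    lr_init: float = 1e-4
    lr_factor: float = 0.1
    lr_patience: int = 2500
    lr_floor: float = 1e-7
    rotation: float = 90.0
    scale: tuple[float, float] = (0.9, 1.1)
    shear: float = 20.0
    hsv_jitter: bool = True
    val_fraction: float = 0.25
    max_steps: int | None = 2000
    crop: int | None = 128  # random training crop (px); None = full image
    val_every: int = 25
    levels: int = 4
    width: int = 32

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.lr_floor >= self.lr_init:
            raise ValueError("lr_floor must be below lr_init")


def _augment_scene(image, planes, cfg, rng):
    h, w = image.shape[:2]
    ranges = AffineRanges(
        rotation=cfg.rotation,
        translation=0.0,
        scale=cfg.scale,
        shear=cfg.shear,
    )
    a = sample_affine(ranges, rng, image_size=(h, w)).matrix(center=(w / 2, h / 2))
    tform = ProjectiveTransform(matrix=np.linalg.inv(a))
    img = warp(image.astype(np.float64), tform, output_shape=(h, w))
    tgt = np.stack(
        [warp(p.astype(np.float64), tform, output_shape=(h, w)) for p in planes]
    )
    if cfg.hsv_jitter:
        img = photometric_augment(img, rng, PhotometricAugment(noise_prob=0.0))
    if cfg.crop and cfg.crop < min(h, w):
        c = cfg.crop
        y0 = rng.integers(0, h - c + 1)
        x0 = rng.integers(0, w - c + 1)
        img = img[y0 : y0 + c, x0 : x0 + c]
        tgt = tgt[:, y0 : y0 + c, x0 : x0 + c]
    return np.asarray(img, dtype=np.float32), tgt.astype(np.float32)


def _mse_forward_backward(unet, img, tgt):
    x = img.transpose(2, 0, 1)[None]
    pred = unet.forward(x)
    diff = pred[0] - tgt
    loss = float((diff**2).mean())
    gy = (2.0 / diff.size) * diff[None].astype(np.float32)
    unet.backward(gy)
    return loss


def _val_loss(unet, val_scenes, levels):
    total = 0.0
    for img, stack in val_scenes:
        x, _ = _pad_to_multiple(img, 2 ** (levels - 1))
        pred = unet.forward(x.transpose(2, 0, 1)[None].astype(np.float32), train=False)
        tgt = stack.planes
        p = pred[0][:, : tgt.shape[1], : tgt.shape[2]]
        total += float(((p - tgt) ** 2).mean())
    return total / len(val_scenes)


def train_detector(
    train_scenes: list[tuple[np.ndarray, HeatmapStack]],
    cfg: DetectorTrainConfig | None = None,
    seed: int = 0,
) -> DetectorModel:
    """Train the keypoint detector on (image, target heatmap stack) pairs.

    A fraction ``val_fraction`` of the scenes is held out for validation;
    the returned model carries the parameters with the best validation
    loss.  Deterministic for fixed (scenes, cfg, seed).
    """
    cfg = cfg or DetectorTrainConfig()
    if len(train_scenes) < 2:
        raise ValueError("need at least 2 scenes (1 train + 1 validation)")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(train_scenes))
    n_val = max(1, int(round(cfg.val_fraction * len(train_scenes))))
    val = [train_scenes[i] for i in idx[:n_val]]
    train = [train_scenes[i] for i in idx[n_val:]]
    if not train:
        raise ValueError("validation split consumed every scene")

    unet = UNet(levels=cfg.levels, width=cfg.width, rng=rng)
    opt = Adam(unet.params(), unet.grads(), lr=cfg.lr_init)
    sched = PlateauSchedule(cfg.lr_init, cfg.lr_factor, cfg.lr_patience, cfg.lr_floor)

    best_val = np.inf
    best_params = [p.copy() for p in unet.params()]
    step = 0
    while not sched.stopped and (cfg.max_steps is None or step < cfg.max_steps):
        img, stack = train[rng.integers(len(train))]
        aug_img, aug_tgt = _augment_scene(img, stack.planes, cfg, rng)
        unet.zero_grads()
        _mse_forward_backward(unet, aug_img, aug_tgt)
        opt.lr = sched.lr
        opt.step()
        step += 1
        vl = None
        if step % cfg.val_every == 0:
            vl = _val_loss(unet, val, cfg.levels)
            if vl < best_val:
                best_val = vl
                best_params = [p.copy() for p in unet.params()]
        sched.update(vl)

    for p, bp in zip(unet.params(), best_params):
        p[...] = bp
    return DetectorModel(unet=unet)


# ---------------------------------------------------------------------------
# checkpoint io


def save_detector(model: DetectorModel, path):
    arrays = {f"p{i}": p for i, p in enumerate(model.unet.params())}
    meta = {
        "format": "conked-detector-v1",
        "levels": model.unet.levels,
        "width": model.unet.width,
        "threshold": model.threshold,
        "window": model.window,
    }
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_detector(path) -> DetectorModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    if meta.get("format") != "conked-detector-v1":
        raise ValueError("not a detector checkpoint")
    unet = UNet(levels=meta["levels"], width=meta["width"])
    for i, p in enumerate(unet.params()):
        p[...] = data[f"p{i}"]
    return DetectorModel(unet=unet, threshold=meta["threshold"], window=meta["window"])
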