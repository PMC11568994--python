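"""Dense per-pixel descriptor network and the ConKeD training loop.

The network is a fully convolutional, dilation-based feature extractor in
the style of the modified L2-Net used for dense description: no spatial
downsampling, so the descriptor block has one descriptor per input pixel,
with a final L2 normalisation making every descriptor unit-norm (cosine
similarity = dot product).

All convolutions are *valid*; dense inference zero-pads the input once by
the receptive-field radius, so evaluating the network on a
receptive-field-sized patch centred at a keypoint gives exactly the same
descriptor as dense inference at that pixel.  Training exploits this: per
step, one base image is expanded into a 1+N multiviewed batch, descriptors
are computed on patches at the (warped) keypoint locations, and one of the
contrastive objectives (SupCon, MP-InfoNCE, or the triplet baseline) drives
an Adam step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import AffineRanges
from .keypoints import KeypointSet
from .losses import (
    MultiviewDescriptorTensor,
    TripletConfig,
    mp_infonce_loss_grad,
    supcon_loss_grad,
    triplet_loss,
)
from .multiview import DegenerateBatchError, build_multiview_batch
from .nn import Adam, BatchNorm2d, Conv2d, ReLU, Sequential

logger = logging.getLogger(__name__)

DEFAULT_DIM = 128


#: default dilation plan of the 3x3 conv stack; receptive field 1 + 2*sum
DEFAULT_DILATIONS = (1, 1, 2, 2, 3)


def _make_net(width: int, dim: int, rng, dilations=DEFAULT_DILATIONS) -> Sequential:
    # valid dilated convolutions, no downsampling: channel plan
    # w, w, 2w, 2w, ... followed by a 1x1 projection to dim
    chans = [width, width] + [2 * width] * (len(dilations) - 2)
    layers = []
    c_in = 3
    for c_out, d in zip(chans, dilations):
        layers += [
            Conv2d(c_in, c_out, 3, pad=0, dilation=d, rng=rng),
            BatchNorm2d(c_out),
            ReLU(),
        ]
        c_in = c_out
    layers.append(Conv2d(c_in, dim, 1, pad=0, rng=rng))
    net = Sequential(*layers)
    # non-zero final bias: pixels whose activations are all zero (dead ReLU
    # paths on dark regions) still normalise to a well-defined unit vector
    net.layers[-1].b[:] = 0.01
    return net


@dataclass
class DescriptorModel:
    net: Sequential
    width: int
    dim: int
    dilations: tuple = DEFAULT_DILATIONS
    loss_history: list = field(default_factory=list)

    @property
    def pad(self) -> int:
        """Zero padding applied once to the input = receptive-field radius."""
        return sum(self.dilations)

    @property
    def patch(self) -> int:
        return 2 * self.pad + 1


def make_descriptor_model(
    width: int = 16,
    dim: int = DEFAULT_DIM,
    seed: int = 0,
    dilations=DEFAULT_DILATIONS,
):
    rng = np.random.default_rng(seed)
    return DescriptorModel(
        net=_make_net(width, dim, rng, dilations),
        width=width,
        dim=dim,
        dilations=tuple(dilations),
    )


@dataclass
class DescriptorField:
    """Dense H×W×D block of unit-norm descriptors (one per pixel)."""

    data: np.ndarray

    @property
    def image_size(self):
        return self.data.shape[:2]


@dataclass
class DescriptorSet:
    """Descriptors sampled at keypoints; rows align with ``kps``."""

    vectors: np.ndarray  # (K, D)
    kps: KeypointSet


def _normalize_rows(y: np.ndarray):
    norms = np.linalg.norm(y, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-12)
    return y / norms, norms


def describe(model: DescriptorModel, image: np.ndarray) -> DescriptorField:
    """Dense descriptor field for an RGB [0, 1] image, unit-norm per pixel."""
    img = np.asarray(image, dtype=np.float32)
    x = np.pad(img, ((model.pad, model.pad), (model.pad, model.pad), (0, 0)))
    x = x.transpose(2, 0, 1)[None]
    y = model.net.forward(x, train=False)[0]  # (D, H, W)
    d, h, w = y.shape
    z, _ = _normalize_rows(y.reshape(d, h * w).T)
    return DescriptorField(z.reshape(h, w, d).astype(np.float32))


def nearest_pixel(xy: np.ndarray) -> np.ndarray:
    """Round-half-up per axis; (10.6, 3.2) -> column 11, row 3."""
    return np.floor(np.asarray(xy, dtype=np.float64) + 0.5).astype(np.int64)


def sample_descriptors(f: DescriptorField, kps: KeypointSet) -> DescriptorSet:
    """Select the descriptor at each keypoint's nearest integer pixel."""
    h, w = f.image_size
    if len(kps) == 0:
        return DescriptorSet(np.zeros((0, f.data.shape[2])), kps)
    px = nearest_pixel(kps.xy)
    if (
        (px[:, 0] < 0).any()
        or (px[:, 0] >= w).any()
        or (px[:, 1] < 0).any()
        or (px[:, 1] >= h).any()
    ):
        raise ValueError("keypoint outside the descriptor field")
    return DescriptorSet(f.data[px[:, 1], px[:, 0]].astype(np.float64), kps)


# ---------------------------------------------------------------------------
# training


@dataclass
class DescriptorTrainConfig:
    """ConKeD descriptor training settings.

    ``steps`` counts optimizer steps; each step consumes one multiviewed
    batch built from one base image (a single-image "epoch").  The triplet
    baseline conventionally runs with lr=1e-5 and several times more steps.
    """

    lr: float = 1e-4
    steps: int = 1500
    n_views: int = 9
    tau: float = 0.1
    loss: str = "mp_infonce"  # one of {"supcon", "mp_infonce", "triplet"}
    triplet_margin: float = 0.05
    width: int = 16
    dim: int = DEFAULT_DIM
    dilations: tuple = DEFAULT_DILATIONS
    ranges: AffineRanges = field(default_factory=AffineRanges)

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.loss not in ("supcon", "mp_infonce", "triplet"):
            raise ValueError(f"unknown loss {self.loss!r}")


class NoTrainableDataError(RuntimeError):
    pass


def _extract_patches(batch, model):
    """Patches at every per-view keypoint; returns (M, 3, P, P) float32 and
    the integer per-view pixel coordinates."""
    pad, p = model.pad, model.patch
    views = batch.views
    nv, h, w = views.shape[:3]
    px = nearest_pixel(batch.coords.reshape(-1, 2)).reshape(nv, -1, 2)
    patches = np.empty((nv * batch.k, 3, p, p), dtype=np.float32)
    m = 0
    for v in range(nv):
        vp = np.pad(views[v], ((pad, pad), (pad, pad), (0, 0)))
        for x, y in px[v]:
            patches[m] = vp[y : y + p, x : x + p].transpose(2, 0, 1)
            m += 1
    return patches


def _triplet_grad(z, nv, k, margin, rng):
    """Mean triplet hinge over all anchors with random positive view and
    random in-batch negative; returns (loss, dL/dz)."""
    m = nv * k
    gz = np.zeros_like(z)
    total = 0.0
    cnt = 0
    for i in range(nv):
        for kk in range(k):
            a = i * k + kk
            j = int(rng.integers(nv - 1))
            j = j + (j >= i)
            pidx = j * k + kk
            l = int(rng.integers(nv))
            c = int(rng.integers(k - 1))
            c = c + (c >= kk)
            nidx = l * k + c
            s_ap = z[a] @ z[pidx]
            s_an = z[a] @ z[nidx]
            val = triplet_loss(s_ap, s_an, TripletConfig(margin))
            total += val
            cnt += 1
            if val > 0:
                gz[a] += z[nidx] - z[pidx]
                gz[pidx] -= z[a]
                gz[nidx] += z[a]
    return total / cnt, gz / cnt


def train_descriptor(
    images: list[np.ndarray],
    detector=None,
    cfg: DescriptorTrainConfig | None = None,
    seed: int = 0,
    keypoints: list[KeypointSet] | None = None,
) -> DescriptorModel:
    """Train the dense descriptor with a contrastive objective.

    Keypoints are obtained by running ``detector`` on each original image
    once (or taken from ``keypoints`` when given); images yielding fewer
    than 2 keypoints are skipped with a warning.  Deterministic for fixed
    (images, cfg, seed).
    """
    from .detector import detect  # local import to avoid a cycle

    cfg = cfg or DescriptorTrainConfig()
    rng = np.random.default_rng(seed)
    if keypoints is None:
        if detector is None:
            raise ValueError("either a detector or explicit keypoints are required")
        keypoints = [detect(detector, img) for img in images]
    usable = [(img, kp) for img, kp in zip(images, keypoints) if len(kp) >= 2]
    for img, kp in zip(images, keypoints):
        if len(kp) < 2:
            logger.warning("skipping an image with %d detected keypoints", len(kp))
    if not usable:
        raise NoTrainableDataError("no image yielded >= 2 keypoints")

    model = make_descriptor_model(
        cfg.width, cfg.dim, seed=int(rng.integers(2**31)), dilations=cfg.dilations
    )
    opt = Adam(model.net.params(), model.net.grads(), lr=cfg.lr)

    for _ in range(cfg.steps):
        img, kps = usable[rng.integers(len(usable))]
        for _attempt in range(10):
            try:
                batch = build_multiview_batch(img, kps, cfg.n_views, rng, cfg.ranges)
            except DegenerateBatchError:
                continue
            if batch.k >= 2:
                break
        else:
            continue
        nv, k = batch.n + 1, batch.k
        patches = _extract_patches(batch, model)
        raw = model.net.forward(patches)[:, :, 0, 0].astype(np.float64)  # (M, D)
        z, norms = _normalize_rows(raw)
        if cfg.loss == "triplet":
            loss, gz_flat = _triplet_grad(z, nv, k, cfg.triplet_margin, rng)
        else:
            tensor = MultiviewDescriptorTensor(z.reshape(nv, k, -1), cfg.tau)
            fn = supcon_loss_grad if cfg.loss == "supcon" else mp_infonce_loss_grad
            loss, gz = fn(tensor)
            gz_flat = gz.reshape(nv * k, -1)
        # back through the row-wise L2 normalisation
        graw = (gz_flat - z * (z * gz_flat).sum(axis=1, keepdims=True)) / norms
        opt.zero_grad()
        model.net.backward(graw[:, :, None, None].astype(np.float32))
        opt.step()
        model.loss_history.append(loss)
    return model


# ---------------------------------------------------------------------------
# checkpoint io


def save_descriptor(model: DescriptorModel, path):
    arrays = {f"p{i}": p for i, p in enumerate(model.net.params())}
    arrays.update({f"b{i}": b for i, b in enumerate(model.net.buffers())})
    meta = {
        "format": "conked-descriptor-v1",
        "width": model.width,
        "dim": model.dim,
        "dilations": list(model.dilations),
    }
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_descriptor(path) -> DescriptorModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    if meta.get("format") != "conked-descriptor-v1":
        raise ValueError("not a descriptor checkpoint")
    model = make_descriptor_model(
        meta["width"], meta["dim"], dilations=tuple(meta["dilations"])
    )
    for i, p in enumerate(model.net.params()):
        p[...] = data[f"p{i}"]
    for i, b in enumerate(model.net.buffers()):
        b[...] = data[f"b{i}"]
    return model
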