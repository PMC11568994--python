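"""Multiviewed batches for descriptor training.

One base image plus N random augmentations ("views") form a batch of size
1 + N.  Keypoints are detected once, on the base image only; every view
receives the geometrically warped copies of those coordinates, so each of
the K keypoint identities is present in all N + 1 views.  That gives, per
anchor, exactly N positives (the same identity in the other views) and
(K - 1)(N + 1) negatives, for K(1 + N) samples in total.

Keypoints whose warped location leaves any view (or comes within a small
border margin, so nearest-pixel descriptor sampling stays valid) are
dropped from *all* views — K is constant across views, which the loss
index structure relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from .geometry import AffineRanges, apply_homography, sample_affine
from .keypoints import KeypointSet

DEFAULT_N_VIEWS = 9
#: border margin (px) inside which keypoints are discarded
BORDER_MARGIN = 3.0


class DegenerateBatchError(RuntimeError):
    """Raised when every keypoint fell outside some view; caller resamples."""


def _rgb2hsv(rgb: np.ndarray) -> np.ndarray:
    """Vectorised float32 RGB -> HSV on [0, 1] arrays.

    Equivalent to the standard hexcone conversion; kept local because view
    augmentation converts every view every step and needs a float32 path.
    """
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mx = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    d = mx - mn
    safe = np.where(d == 0, 1.0, d)
    h = np.where(
        mx == r,
        (g - b) / safe,
        np.where(mx == g, 2.0 + (b - r) / safe, 4.0 + (r - g) / safe),
    )
    h = np.where(d == 0, 0.0, h / 6.0) % 1.0
    s = np.where(mx == 0, 0.0, d / np.where(mx == 0, 1.0, mx))
    return np.stack([h, s, mx], axis=-1)


def _hsv2rgb(hsv: np.ndarray) -> np.ndarray:
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    i = np.floor(h * 6.0)
    f = h * 6.0 - i
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    i = i.astype(np.int64) % 6
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.stack([r, g, b], axis=-1)


@dataclass
class PhotometricAugment:
    """Photometric view augmentation: HSV jitter always, Gaussian noise
    (mean 0, std ``noise_sigma``) with probability ``noise_prob``."""

    hue: float = 0.02
    saturation: float = 0.15
    value: float = 0.15
    noise_sigma: float = 0.05
    noise_prob: float = 0.25


def photometric_augment(
    image: np.ndarray, rng: np.random.Generator, cfg: PhotometricAugment | None = None
) -> np.ndarray:
    """Apply HSV jitter and (probabilistically) Gaussian noise; clipped to [0, 1].

    Coordinates are never altered.  The rng is consumed in a fixed order so
    results are deterministic for a fixed stream state.
    """
    cfg = cfg or PhotometricAugment()
    out = np.asarray(image, dtype=np.float32)
    if cfg.hue or cfg.saturation or cfg.value:
        hsv = _rgb2hsv(out)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-cfg.hue, cfg.hue)) % 1.0
        hsv[..., 1] = np.clip(
            hsv[..., 1] * (1.0 + rng.uniform(-cfg.saturation, cfg.saturation)), 0, 1
        )
        hsv[..., 2] = np.clip(
            hsv[..., 2] * (1.0 + rng.uniform(-cfg.value, cfg.value)), 0, 1
        )
        out = _hsv2rgb(hsv)
    if rng.uniform() < cfg.noise_prob and cfg.noise_sigma > 0:
        out = out + cfg.noise_sigma * rng.standard_normal(out.shape, dtype=np.float32)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


@dataclass
class MultiviewBatch:
    views: np.ndarray  # (N+1, H, W, 3); index 0 = original
    warps: np.ndarray  # (N+1, 3, 3); index 0 = identity
    coords: np.ndarray  # (N+1, K, 2) per-view keypoint coordinates
    classes: np.ndarray  # (K,)

    @property
    def n(self) -> int:
        return self.views.shape[0] - 1

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def total_samples(self) -> int:
        return self.k * (1 + self.n)

    @property
    def positives_per_anchor(self) -> int:
        return self.n

    @property
    def negatives_per_anchor(self) -> int:
        return (self.k - 1) * (self.n + 1)


def build_multiview_batch(
    image: np.ndarray,
    kps: KeypointSet,
    n_views: int,
    rng: np.random.Generator,
    ranges: AffineRanges | None = None,
    photometric: PhotometricAugment | None = None,
    margin: float = BORDER_MARGIN,
) -> MultiviewBatch:
    """Build the 1+N multiviewed batch from one base image and its keypoints."""
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if len(kps) == 0:
        raise ValueError("keypoint set must be non-empty")
    ranges = ranges or AffineRanges()
    h, w = image.shape[:2]
    center = (w / 2.0, h / 2.0)

    warps = [np.eye(3)]
    views = [np.asarray(image, dtype=np.float32)]
    for _ in range(n_views):
        params = sample_affine(ranges, rng, image_size=(h, w))
        a = params.matrix(center=center)
        tform = ProjectiveTransform(matrix=np.linalg.inv(a))
        view = warp(np.asarray(image, dtype=np.float32), tform, output_shape=(h, w))
        view = photometric_augment(view, rng, photometric)
        warps.append(a)
        views.append(view)
    warps = np.stack(warps)

    coords = np.stack([apply_homography(a, kps.xy) for a in warps])  # (N+1, K, 2)
    inb = (
        (coords[..., 0] >= margin)
        & (coords[..., 0] <= w - 1 - margin)
        & (coords[..., 1] >= margin)
        & (coords[..., 1] <= h - 1 - margin)
    ).all(axis=0)
    if not inb.any():
        raise DegenerateBatchError("all keypoints left the view bounds")
    return MultiviewBatch(
        views=np.stack(views),
        warps=warps,
        coords=coords[:, inb],
        classes=kps.classes[inb].copy(),
    )
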