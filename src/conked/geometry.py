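"""Planar transforms: parameterised affines, homographies and sampling.

Conventions
-----------
Points are (x, y) with x = column, y = row, 0-based.  A transform is a 3x3
matrix acting on homogeneous column vectors (x, y, 1)^T.  Affine parameters
compose about a given centre as  T(c) @ Shear @ Scale @ Rot @ T(translation)
@ T(-c)  so that rotation/scale/shear pivot on the image centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AffineRanges:
    """Symmetric sampling ranges for random affine augmentation.

    rotation in degrees (+/-), translation as a fraction of each axis length
    (+/-), scale as a (lo, hi) multiplicative interval, shear in degrees
    (+/-).  Defaults are the descriptor-training augmentation regime.
    """

    rotation: float = 60.0
    translation: float = 0.25
    scale: tuple[float, float] = (0.75, 1.25)
    shear: float = 30.0


#: augmentation regime used when training the keypoint detector
DETECTOR_RANGES = AffineRanges(rotation=90.0, translation=0.0, scale=(0.9, 1.1), shear=20.0)


@dataclass
class AffineParams:
    rotation: float  # degrees
    translation: tuple[float, float]  # px
    scale: tuple[float, float]
    shear: float  # degrees

    def matrix(self, center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
        """3x3 matrix realising the parameters about ``center`` (x, y)."""
        th = np.deg2rad(self.rotation)
        sh = np.deg2rad(self.shear)
        rot = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        sc = np.diag([self.scale[0], self.scale[1], 1.0])
        shear = np.array([[1.0, np.tan(sh), 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        t = np.eye(3)
        t[:2, 2] = self.translation
        cx, cy = center
        to_c = np.eye(3)
        to_c[:2, 2] = (cx, cy)
        from_c = np.eye(3)
        from_c[:2, 2] = (-cx, -cy)
        m = to_c @ shear @ sc @ rot @ t @ from_c
        return m


def sample_affine(
    ranges: AffineRanges, rng: np.random.Generator, image_size: tuple[int, int] | None = None
) -> AffineParams:
    """Draw affine parameters uniformly and independently from ``ranges``.

    Translation is drawn per axis as a fraction of that axis length when
    ``image_size`` (H, W) is given, otherwise in pixels of the fraction
    itself (i.e. zero when the range is zero).
    """
    rot = rng.uniform(-ranges.rotation, ranges.rotation)
    if image_size is not None:
        h, w = image_size
        tx = rng.uniform(-ranges.translation * w, ranges.translation * w)
        ty = rng.uniform(-ranges.translation * h, ranges.translation * h)
    else:
        tx = rng.uniform(-ranges.translation, ranges.translation)
        ty = rng.uniform(-ranges.translation, ranges.translation)
    sx = rng.uniform(*ranges.scale)
    sy = rng.uniform(*ranges.scale)
    shear = rng.uniform(-ranges.shear, ranges.shear)
    return AffineParams(rot, (tx, ty), (sx, sy), shear)


def apply_homography(h: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Map (M, 2) points through a 3x3 homography (exact, float64)."""
    pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
    ph = np.column_stack([pts, np.ones(len(pts))])
    out = ph @ np.asarray(h, dtype=np.float64).T
    w = out[:, 2:3]
    with np.errstate(divide="ignore", invalid="ignore"):
        return out[:, :2] / w


def normalize_homography(h: np.ndarray) -> np.ndarray:
    """Scale so h[2, 2] == 1 when possible."""
    h = np.asarray(h, dtype=np.float64)
    if h[2, 2] != 0:
        return h / h[2, 2]
    return h
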