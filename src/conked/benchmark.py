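"""Desk-scale benchmark protocol: fixed study conditions for CPU runs.

This module pins the synthetic study conditions used by the package's
self-evaluation: ten 256x256 training scenes, separate held-out scenes,
a detector training of at most 2,000 steps, a 1,500-step descriptor
training with the 1+9 multiviewed batch and MP-InfoNCE, and three
evaluation protocols:

* detection recall against generator ground truth (5 px tolerance);
* mutual-match precision on held-out pairs whose relative rotation lies
  in 20-60 degrees — large enough that matching requires the learned
  viewpoint invariance rather than raw patch correlation — scored as the
  fraction of mutual matches within 3 px of the true warp;
* end-to-end registration (control-point error, registration score).

Problem sizes are chosen so a full run fits interactive CPU budgets;
everything is deterministic given the protocol seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detector import DetectorTrainConfig, detect, train_detector
from .descriptor import (
    DescriptorTrainConfig,
    describe,
    make_descriptor_model,
    sample_descriptors,
    train_descriptor,
)
from .evaluation import control_point_error
from .geometry import AffineRanges
from .heatmaps import binary_to_heatmap
from .multiview import DEFAULT_N_VIEWS
from .registration import (
    RegistrationConfig,
    match_precision,
    mutual_match,
    register_pair,
)
from .synthetic import generate_pair, generate_scene

SCENE_SIZE = 256
N_TREES = 3
N_BRANCH_EVENTS = 5
N_TRAIN_SCENES = 10
N_HELDOUT_SCENES = 4
HEATMAP_SIGMA = 3.0

DETECTOR_STEPS = 2000
DESCRIPTOR_STEPS = 1500
DESCRIPTOR_LR = 1e-3
DESCRIPTOR_WIDTH = 16
DESCRIPTOR_DIM = 128

#: evaluation-pair transform regime: rotations up to the descriptor
#: augmentation limit, mild translation/scale/shear
EVAL_RANGES = AffineRanges(rotation=60.0, translation=0.06, scale=(0.9, 1.1), shear=10.0)
EVAL_MIN_ROT = 20.0
EVAL_MAX_ROT = 60.0
PRECISION_TOL = 3.0


def make_scenes(seed: int, n: int):
    """n deterministic scenes derived from a protocol seed."""
    return [
        generate_scene(seed + i, SCENE_SIZE, N_TREES, N_BRANCH_EVENTS)
        for i in range(n)
    ]


def training_scenes(seed: int = 100):
    return make_scenes(seed, N_TRAIN_SCENES)


def heldout_scenes(seed: int = 200):
    return make_scenes(seed, N_HELDOUT_SCENES)


def train_benchmark_detector(scenes, seed: int = 1, max_steps: int = DETECTOR_STEPS):
    cfg = DetectorTrainConfig(
        levels=3, width=16, crop=128, max_steps=max_steps, val_every=50
    )
    data = [(s.image, binary_to_heatmap(s.keypoints, HEATMAP_SIGMA)) for s in scenes]
    return train_detector(data, cfg, seed=seed)


def train_benchmark_descriptor(
    images,
    detector=None,
    keypoints=None,
    seed: int = 2,
    loss: str = "mp_infonce",
    n_views: int = DEFAULT_N_VIEWS,
    steps: int = DESCRIPTOR_STEPS,
):
    cfg = DescriptorTrainConfig(
        steps=steps,
        n_views=n_views,
        loss=loss,
        width=DESCRIPTOR_WIDTH,
        dim=DESCRIPTOR_DIM,
        lr=DESCRIPTOR_LR,
    )
    return train_descriptor(images, detector, cfg, seed=seed, keypoints=keypoints)


def untrained_descriptor(seed: int = 9):
    return make_descriptor_model(DESCRIPTOR_WIDTH, DESCRIPTOR_DIM, seed=seed)


def detection_recall(detector, scenes, tol: float = 5.0):
    """Per-scene fraction of ground-truth keypoints detected within tol px."""
    out = []
    for s in scenes:
        det = detect(detector, s.image)
        if len(det) == 0:
            out.append(0.0)
            continue
        d = np.linalg.norm(s.keypoints.xy[:, None] - det.xy[None], axis=2)
        out.append(float((d.min(axis=1) < tol).mean()))
    return out


def _rotation_of(h):
    a = h[:2, :2]
    return abs(np.degrees(np.arctan2(a[1, 0], a[0, 0])))


def rotation_eval_pairs(scenes, seed: int = 7000, per_scene: int = 3):
    """Held-out pairs whose relative rotation is in the 20-60 degree band."""
    pairs = []
    for s in scenes:
        count = 0
        for j in range(80):
            if count >= per_scene:
                break
            p = generate_pair(s, seed + 13 * j + s.seed, transform_ranges=EVAL_RANGES)
            if EVAL_MIN_ROT <= _rotation_of(p.h_true) <= EVAL_MAX_ROT:
                pairs.append(p)
                count += 1
    return pairs


def category_eval_pairs(scenes, seed: int = 50, categories: str = "SA"):
    # distinct seed per (scene, slot) so every pair gets its own transform
    # and corruption draw
    return [
        generate_pair(s, seed + 97 * i + j, category_tag=c)
        for i, s in enumerate(scenes)
        for j, c in enumerate(categories)
    ]


@dataclass
class DetectionCache:
    """Keypoints detected once per pair, shared across descriptor models."""

    pairs: list
    detections: list

    @classmethod
    def build(cls, detector, pairs):
        return cls(
            pairs,
            [(detect(detector, p.fixed), detect(detector, p.moving)) for p in pairs],
        )


def mutual_match_precision(descriptor, cache: DetectionCache, tol=PRECISION_TOL):
    """Per-pair precision of mutual matches against the known true warp."""
    out = []
    for p, (kf, km) in zip(cache.pairs, cache.detections):
        if len(kf) == 0 or len(km) == 0:
            out.append(0.0)
            continue
        df = sample_descriptors(describe(descriptor, p.fixed), kf)
        dm = sample_descriptors(describe(descriptor, p.moving), km)
        out.append(match_precision(mutual_match(df, dm), p.h_true, tol))
    return out


def registration_errors(detector, descriptor, pairs):
    """Per-pair mean control-point error of the full inference path."""
    errs = []
    for p in pairs:
        res = register_pair(
            p.fixed, p.moving, detector, descriptor, RegistrationConfig(lenient=True)
        )
        errs.append(
            control_point_error(res.homography, p.cp_fixed, p.cp_moving)
            if res.ok
            else np.inf
        )
    return errs
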