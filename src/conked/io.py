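"""Plain-text and image persistence for pipeline artifacts.

Keypoints: CSV with header ``x,y,class`` (class in {crossover,
bifurcation}).  Control points: CSV ``x_fixed,y_fixed,x_moving,y_moving``.
Homographies: 3x3 row-major whitespace-separated text.  Images: 8-bit PNG;
heatmap planes: per-plane 16-bit grayscale PNG.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from imageio import v3 as iio

from .heatmaps import HeatmapStack
from .keypoints import CLASS_NAMES, KeypointSet

_PLANE_NAMES = ("crossover", "bifurcation", "combined")


def save_keypoints_csv(kps: KeypointSet, path):
    df = pd.DataFrame(
        {"x": kps.xy[:, 0], "y": kps.xy[:, 1], "class": kps.class_names()}
    )
    df.to_csv(path, index=False)


def load_keypoints_csv(path, image_size) -> KeypointSet:
    df = pd.read_csv(path)
    classes = np.array([CLASS_NAMES.index(c) for c in df["class"]], dtype=np.int8)
    return KeypointSet(df[["x", "y"]].to_numpy(dtype=np.float64), classes, image_size)


def save_control_points_csv(cp_fixed, cp_moving, path):
    df = pd.DataFrame(
        {
            "x_fixed": cp_fixed[:, 0],
            "y_fixed": cp_fixed[:, 1],
            "x_moving": cp_moving[:, 0],
            "y_moving": cp_moving[:, 1],
        }
    )
    df.to_csv(path, index=False)


def load_control_points_csv(path):
    df = pd.read_csv(path)
    return (
        df[["x_fixed", "y_fixed"]].to_numpy(dtype=np.float64),
        df[["x_moving", "y_moving"]].to_numpy(dtype=np.float64),
    )


def save_homography_txt(h, path):
    np.savetxt(path, np.asarray(h, dtype=np.float64))


def load_homography_txt(path):
    h = np.loadtxt(path)
    if h.shape != (3, 3):
        raise ValueError("homography file must contain a 3x3 matrix")
    return h


def save_image_png(image, path):
    """Save a float [0, 1] RGB image as 8-bit PNG."""
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    iio.imwrite(path, (arr * 255.0 + 0.5).astype(np.uint8))


def load_image_png(path):
    arr = iio.imread(path)
    return arr.astype(np.float32) / 255.0


def save_heatmaps_png(stack: HeatmapStack, prefix):
    """Persist the three planes as 16-bit grayscale PNGs for inspection."""
    for plane, name in zip(stack.planes, _PLANE_NAMES):
        arr = (np.clip(plane, 0.0, 1.0) * 65535.0 + 0.5).astype(np.uint16)
        iio.imwrite(f"{prefix}_{name}.png", arr)
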