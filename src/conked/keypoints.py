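"""Labelled keypoint containers shared by every stage of the pipeline.

Keypoints are vessel-tree landmarks: *crossovers* (two distinct vessels
crossing) and *bifurcations* (one vessel splitting in two).  Coordinates are
0-based ``(x = column, y = row)`` with pixel centres at integer coordinates;
this convention is used unchanged by the synthetic generator, the detector,
the descriptor sampler and the registration stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: class code -> name; codes are used internally, names in CSV files
CLASS_NAMES = ("crossover", "bifurcation")
CROSSOVER, BIFURCATION = 0, 1


@dataclass
class KeypointSet:
    """A set of labelled keypoints for one image.

    Parameters
    ----------
    xy : (K, 2) float array of (x, y) pixel coordinates.
    classes : (K,) int array with values in {0 = crossover, 1 = bifurcation}.
    image_size : (H, W) of the image the coordinates live in.
    """

    xy: np.ndarray
    classes: np.ndarray
    image_size: tuple[int, int]

    def __post_init__(self):
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=np.float64))
        if self.xy.size == 0:
            self.xy = self.xy.reshape(0, 2)
        self.classes = np.asarray(self.classes, dtype=np.int8).reshape(-1)
        if self.xy.shape[0] != self.classes.shape[0]:
            raise ValueError("xy and classes length mismatch")
        h, w = self.image_size
        if len(self) and (
            (self.xy[:, 0] < 0).any()
            or (self.xy[:, 0] >= w).any()
            or (self.xy[:, 1] < 0).any()
            or (self.xy[:, 1] >= h).any()
        ):
            raise ValueError("keypoint outside the image bounds")

    def __len__(self) -> int:
        return self.xy.shape[0]

    def of_class(self, cls: int) -> np.ndarray:
        """Indices of keypoints with the given class code."""
        return np.flatnonzero(self.classes == cls)

    def select(self, idx) -> "KeypointSet":
        return KeypointSet(self.xy[idx], self.classes[idx], self.image_size)

    def class_names(self) -> list[str]:
        return [CLASS_NAMES[c] for c in self.classes]


def merge_close(xy: np.ndarray, classes: np.ndarray, min_sep: float):
    """Greedily merge points closer than ``min_sep`` pixels.

    Points are scanned in order; a point is dropped when it lies within
    ``min_sep`` of an already kept point (regardless of class).  Returns the
    filtered (xy, classes).
    """
    kept: list[int] = []
    for i in range(len(xy)):
        ok = True
        for j in kept:
            if np.hypot(*(xy[i] - xy[j])) < min_sep:
                ok = False
                break
        if ok:
            kept.append(i)
    idx = np.asarray(kept, dtype=int)
    if idx.size == 0:
        return xy[:0], classes[:0]
    return xy[idx], classes[idx]
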