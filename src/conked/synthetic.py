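"""Synthetic fundus-like scenes with exact vessel-keypoint ground truth.

The generator emulates the structure that drives keypoint-based retinal
registration: a bright circular fundus disc on a dark background, dark
branching vessel trees rendered as anti-aliased strokes of decreasing
width, and the two landmark classes used throughout the pipeline —
*bifurcations* (branch events within one tree) and *crossovers*
(intersections between different trees).  Because the vessel centrelines
are generated analytically, every keypoint location, the full centreline
graph, and the projective transform relating an image pair are known
exactly, which is what real datasets can only approximate with manual
labels.

Registration fixtures mimic the three evaluation regimes of fundus
benchmarks: high overlap (S), low overlap (P), and high overlap with
simulated pathology progression (A) where random vessel segments are
erased from one image of the pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, zoom
from shapely.geometry import LineString, Polygon, box
from skimage.color import hsv2rgb, rgb2hsv
from skimage.draw import disk as draw_disk
from skimage.transform import ProjectiveTransform, warp

from .geometry import AffineRanges, apply_homography, sample_affine
from .keypoints import BIFURCATION, CROSSOVER, KeypointSet, merge_close

#: minimum separation between ground-truth keypoints (px); matches the
#: detector's local-maxima window so the ground truth stays recoverable
MIN_KEYPOINT_SEPARATION = 6.0


@dataclass
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    keypoints: KeypointSet
    vessel_mask: np.ndarray  # (H, W) bool
    seed: int
    centrelines: list = field(default_factory=list)  # per-stroke (M, 2) x,y arrays
    tree_ids: list = field(default_factory=list)  # tree index per stroke

    @property
    def image_size(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class PhotometricParams:
    """Photometric corruption applied to the moving image of a pair."""

    hue: float = 0.02
    saturation: float = 0.12
    value: float = 0.12
    blur_sigma: float = 0.8  # upper bound, drawn uniformly
    halo_strength: float = 0.25

    @classmethod
    def none(cls) -> "PhotometricParams":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class RegistrationPairFixture:
    fixed: np.ndarray
    moving: np.ndarray
    h_true: np.ndarray  # 3x3, maps fixed -> moving coordinates
    cp_fixed: np.ndarray  # (10, 2)
    cp_moving: np.ndarray  # (10, 2)
    overlap_fraction: float
    category_tag: str
    scene: SyntheticScene | None = None


# ---------------------------------------------------------------------------
# scene generation


def _unit(v):
    return v / np.hypot(*v)


def _rot(v, deg):
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _bezier(p0, d0, length, turn_deg, n):
    """Cubic Bezier from p0 along d0 turning by turn_deg; returns points
    and the end direction."""
    d1 = _rot(d0, turn_deg)
    mid = _unit(d0 + d1)
    p3 = p0 + mid * length
    p1 = p0 + d0 * (length / 3.0)
    p2 = p3 - d1 * (length / 3.0)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (
        (1 - t) ** 3 * p0
        + 3 * (1 - t) ** 2 * t * p1
        + 3 * (1 - t) * t**2 * p2
        + t**3 * p3
    )
    return pts, d1


class _Branch:
    __slots__ = ("tip", "direction", "width", "tree")

    def __init__(self, tip, direction, width, tree):
        self.tip = np.asarray(tip, dtype=float)
        self.direction = np.asarray(direction, dtype=float)
        self.width = float(width)
        self.tree = int(tree)


def _grow_segment(branch, rng, center, r_safe, length=None):
    """Extend a branch by one Bezier stroke, steering back inside the disc."""
    if length is None:
        length = rng.uniform(24.0, 42.0)
    d = branch.direction
    ahead = branch.tip + d * length
    if np.hypot(*(ahead - center)) > r_safe:
        to_c = _unit(center - branch.tip)
        d = _unit(0.35 * d + 0.65 * to_c)
    turn = rng.uniform(-28.0, 28.0)
    n = max(6, int(length / 1.5))
    pts, d1 = _bezier(branch.tip, d, length, turn, n)
    # widths taper linearly along the stroke
    widths = np.linspace(branch.width, branch.width * 0.94, len(pts))
    branch.tip = pts[-1]
    branch.direction = d1
    branch.width = widths[-1]
    return pts, widths


def generate_scene(
    seed: int,
    size: int | tuple[int, int] = 256,
    n_trees: int = 2,
    n_branch_events: int = 5,
) -> SyntheticScene:
    """Generate one fundus-like scene with exact keypoint ground truth.

    ``n_branch_events`` branch events are performed per tree, each
    contributing one bifurcation; intersections between strokes of
    different trees contribute crossovers.  Keypoints closer than 6 px are
    merged.  Deterministic in all arguments.
    """
    if isinstance(size, int):
        size = (size, size)
    h, w = size
    if h < 128 or w < 128:
        raise ValueError("size must be at least 128x128 to place the fundus disc")
    if n_trees < 0 or n_branch_events < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    center = np.array([w / 2.0, h / 2.0])
    radius = 0.46 * min(h, w)
    r_safe = radius - 8.0

    strokes: list[np.ndarray] = []
    stroke_widths: list[np.ndarray] = []
    tree_ids: list[int] = []
    bifurcations: list[np.ndarray] = []

    for tree in range(n_trees):
        ang = rng.uniform(0, 2 * np.pi)
        root = center + 0.88 * radius * np.array([np.cos(ang), np.sin(ang)])
        d0 = _unit(center - root)
        d0 = _rot(d0, rng.uniform(-25, 25))
        active = [_Branch(root, d0, rng.uniform(4.5, 6.0), tree)]
        for _ in range(n_branch_events):
            # pick an extendable branch; prefer ones far from the boundary
            order = rng.permutation(len(active))
            bi = next(
                (
                    i
                    for i in order
                    if np.hypot(*(active[i].tip - center)) < r_safe - 20.0
                ),
                order[0],
            )
            br = active[bi]
            pts, widths = _grow_segment(br, rng, center, r_safe)
            strokes.append(pts)
            stroke_widths.append(widths)
            tree_ids.append(tree)
            bifurcations.append(br.tip.copy())
            # split: the branch forks into two children
            a1 = rng.uniform(18.0, 42.0)
            a2 = -rng.uniform(18.0, 42.0)
            cw = max(2.0, br.width * 0.78)
            child = _Branch(br.tip, _rot(br.direction, a2), cw, tree)
            br.direction = _rot(br.direction, a1)
            br.width = cw
            active.append(child)
        # finish every active branch with one or two trailing strokes; the
        # first is unconditional so every recorded branch point really has
        # three incident strokes in the rendered image
        for br in active:
            for it in range(rng.integers(1, 3)):
                if it > 0 and np.hypot(*(br.tip - center)) > r_safe - 6.0:
                    break
                length = 18.0 if it == 0 else None
                pts, widths = _grow_segment(br, rng, center, r_safe, length=length)
                strokes.append(pts)
                stroke_widths.append(widths)
                tree_ids.append(tree)

    # crossovers: intersections between strokes of different trees
    crossovers: list[np.ndarray] = []
    lines = [LineString(s) for s in strokes]
    for i in range(len(strokes)):
        for j in range(i + 1, len(strokes)):
            if tree_ids[i] == tree_ids[j]:
                continue
            inter = lines[i].intersection(lines[j])
            if inter.is_empty:
                continue
            geoms = getattr(inter, "geoms", [inter])
            for g in geoms:
                if g.geom_type == "Point":
                    crossovers.append(np.array([g.x, g.y]))

    # assemble keypoints: bifurcations first, then crossovers, merged at 6 px
    pts_list = bifurcations + crossovers
    classes = np.array(
        [BIFURCATION] * len(bifurcations) + [CROSSOVER] * len(crossovers),
        dtype=np.int8,
    )
    if pts_list:
        xy = np.vstack(pts_list)
        inside = np.hypot(*(xy - center).T) < radius - 4.0
        xy, classes = xy[inside], classes[inside]
        xy, classes = merge_close(xy, classes, MIN_KEYPOINT_SEPARATION)
    else:
        xy = np.zeros((0, 2))
        classes = classes[:0]

    image, vessel_mask = _render(
        (h, w), center, radius, strokes, stroke_widths, rng
    )
    return SyntheticScene(
        image=image,
        keypoints=KeypointSet(xy, classes, (h, w)),
        vessel_mask=vessel_mask,
        seed=seed,
        centrelines=strokes,
        tree_ids=tree_ids,
    )


def _render(shape, center, radius, strokes, stroke_widths, rng):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(xx - center[0], yy - center[1]) / radius
    disc = np.clip(1.0 - rr**6, 0.0, 1.0)  # soft-edged fundus disc
    # low-frequency texture on the disc
    coarse = rng.normal(0.0, 1.0, (12, 12))
    tex = zoom(coarse, (h / 12.0, w / 12.0), order=3)[:h, :w]
    tex = 0.05 * tex / max(1e-9, np.abs(tex).max())
    # uneven illumination, as fundus photography produces (halos, vignetting)
    cx = rng.uniform(0.3 * w, 0.7 * w)
    cy = rng.uniform(0.3 * h, 0.7 * h)
    sig = rng.uniform(0.4, 0.7) * min(h, w)
    strength = rng.uniform(0.0, 0.25)
    illum = 1.0 - strength * np.exp(
        -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig**2)
    )

    # vessel occupancy, anti-aliased by a slight blur of per-sample disks
    vessel = np.zeros((h, w), dtype=np.float32)
    for pts, widths in zip(strokes, stroke_widths):
        for (x, y), wd in zip(pts, widths):
            r = max(1.0, wd / 2.0)
            rr_, cc_ = draw_disk((y, x), r, shape=(h, w))
            vessel[rr_, cc_] = 1.0
    vessel_mask = vessel > 0.5
    vessel = gaussian_filter(vessel, 0.7)

    base_rgb = np.array([0.86, 0.46, 0.18])  # fundus orange
    vessel_rgb = np.array([0.32, 0.10, 0.06])  # dark vessel red
    img = np.empty((h, w, 3), dtype=np.float32)
    for ch in range(3):
        bg = base_rgb[ch] * (0.75 + 0.25 * disc) * (1.0 + tex)
        img[..., ch] = (bg * (1 - vessel) + vessel_rgb[ch] * vessel) * illum
        img[..., ch] *= disc > 0.02
    img += 0.015  # lift pure black slightly, like camera offset
    return np.clip(img, 0.0, 1.0).astype(np.float32), vessel_mask


# ---------------------------------------------------------------------------
# registration pairs


#: affine regimes for the three fixture categories; category P uses large
#: translations to force low overlap
CATEGORY_RANGES = {
    "S": AffineRanges(rotation=10.0, translation=0.05, scale=(0.95, 1.05), shear=3.0),
    "A": AffineRanges(rotation=10.0, translation=0.05, scale=(0.95, 1.05), shear=3.0),
    "P": AffineRanges(rotation=12.0, translation=0.30, scale=(0.95, 1.05), shear=4.0),
}

N_CONTROL_POINTS = 10


def _perspective_matrix(params, center, rng, perspective=1.5e-4):
    m = params.matrix(center=center)
    p = np.eye(3)
    if perspective > 0:
        p[2, 0] = rng.uniform(-perspective, perspective)
        p[2, 1] = rng.uniform(-perspective, perspective)
    return m @ p


def _photometric(img, p: PhotometricParams, rng):
    out = img.astype(np.float64)
    if p.hue or p.saturation or p.value:
        hsv = rgb2hsv(out)
        hsv[..., 0] = (hsv[..., 0] + rng.uniform(-p.hue, p.hue)) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] * (1 + rng.uniform(-p.saturation, p.saturation)), 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] * (1 + rng.uniform(-p.value, p.value)), 0, 1)
        out = hsv2rgb(hsv)
    if p.halo_strength:
        h, w = out.shape[:2]
        cx = rng.uniform(0.25 * w, 0.75 * w)
        cy = rng.uniform(0.25 * h, 0.75 * h)
        sig = 0.5 * min(h, w)
        yy, xx = np.mgrid[0:h, 0:w]
        halo = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sig**2))
        out *= (1.0 - p.halo_strength * halo)[..., None]
    if p.blur_sigma:
        sig = rng.uniform(0.0, p.blur_sigma)
        if sig > 0.05:
            out = gaussian_filter(out, (sig, sig, 0))
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def _erase_segments(scene: SyntheticScene, rng, n_erase=3):
    """Paint background over a few vessel strokes (pathology progression)."""
    img = scene.image.copy()
    h, w = img.shape[:2]
    n = min(n_erase, len(scene.centrelines))
    if n == 0:
        return img
    idx = rng.choice(len(scene.centrelines), size=n, replace=False)
    bg = np.array([0.80, 0.42, 0.17], dtype=np.float32)
    mask = np.zeros((h, w), dtype=np.float32)
    for i in idx:
        pts = scene.centrelines[i]
        sl = slice(len(pts) // 4, 3 * len(pts) // 4)  # erase the middle part
        for x, y in pts[sl]:
            rr_, cc_ = draw_disk((y, x), 4.0, shape=(h, w))
            img[rr_, cc_] = bg
            mask[rr_, cc_] = 1.0
    # feather only the repainted regions; the rest of the image is untouched
    feather = np.clip(gaussian_filter(mask, 2.0) * 1.5, 0.0, 1.0)[..., None]
    blurred = gaussian_filter(img, (1.5, 1.5, 0))
    return img * (1 - feather) + blurred * feather


def generate_pair(
    scene: SyntheticScene,
    seed: int,
    transform_ranges: AffineRanges | None = None,
    photometric: PhotometricParams | None = None,
    category_tag: str = "S",
    max_retries: int = 20,
    transform: np.ndarray | None = None,
    perspective: float = 1.5e-4,
) -> RegistrationPairFixture:
    """Create a registration pair with a known projective transform.

    The moving image is the scene warped by ``h_true`` (fixed -> moving
    coordinates) and then photometrically corrupted.  Ten control points
    are sampled on vessel centrelines inside the overlap; their moving
    counterparts are the exact images under ``h_true``.  Category "A"
    additionally erases random vessel segments from the moving image.

    An explicit 3x3 ``transform`` bypasses sampling and is used as
    ``h_true`` verbatim; ``perspective`` bounds the random projective
    terms (0 gives a pure affine).
    """
    if category_tag not in CATEGORY_RANGES:
        raise ValueError(f"unknown category {category_tag!r}")
    ranges = transform_ranges or CATEGORY_RANGES[category_tag]
    photometric = PhotometricParams() if photometric is None else photometric
    h, w = scene.image_size
    center = (w / 2.0, h / 2.0)
    frame = box(0, 0, w - 1, h - 1)

    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        if transform is not None:
            h_true = np.asarray(transform, dtype=np.float64)
        else:
            params = sample_affine(ranges, rng, image_size=(h, w))
            h_true = _perspective_matrix(params, center, rng, perspective)
        # candidate control points: centreline samples inside the disc whose
        # images under h_true stay well inside the moving frame
        cands = (
            np.vstack(scene.centrelines) if scene.centrelines else np.zeros((0, 2))
        )
        if len(cands) == 0:
            raise RuntimeError("scene has no centrelines to place control points on")
        mapped = apply_homography(h_true, cands)
        margin = 6.0
        ok = (
            (cands[:, 0] > margin)
            & (cands[:, 0] < w - margin)
            & (cands[:, 1] > margin)
            & (cands[:, 1] < h - margin)
            & (mapped[:, 0] > margin)
            & (mapped[:, 0] < w - margin)
            & (mapped[:, 1] > margin)
            & (mapped[:, 1] < h - margin)
        )
        idx = np.flatnonzero(ok)
        if len(idx) < N_CONTROL_POINTS:
            continue
        # spread the control points out by greedy farthest-point selection
        chosen = [idx[rng.integers(len(idx))]]
        for _ in range(N_CONTROL_POINTS - 1):
            d = np.min(
                np.linalg.norm(
                    cands[idx, None, :] - cands[None, chosen, :], axis=-1
                ),
                axis=1,
            )
            chosen.append(idx[int(np.argmax(d))])
        cp_fixed = cands[chosen]
        cp_moving = apply_homography(h_true, cp_fixed)

        source = scene.image
        if category_tag == "A":
            source = _erase_segments(scene, rng)
        tform = ProjectiveTransform(matrix=np.linalg.inv(h_true))
        moving = warp(
            source.astype(np.float64), tform, output_shape=(h, w), cval=0.015
        )
        moving = _photometric(moving, photometric, rng)

        corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
        quad = Polygon(apply_homography(h_true, corners))
        overlap = quad.intersection(frame).area / frame.area

        return RegistrationPairFixture(
            fixed=scene.image.copy(),
            moving=moving,
            h_true=h_true,
            cp_fixed=cp_fixed,
            cp_moving=cp_moving,
            overlap_fraction=float(overlap),
            category_tag=category_tag,
            scene=scene,
        )
    raise RuntimeError(
        f"could not place {N_CONTROL_POINTS} control points in the overlap "
        f"after {max_retries} attempts"
    )
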