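"""Descriptor matching and robust projective transform estimation.

Matching is bidirectional and class-restricted: crossovers are only
matched with crossovers and bifurcations with bifurcations, and a pair
(a, b) is kept only when b is a's most similar descriptor within the class
*and* a is b's.  Restricting to classes cuts the O(n^2) comparison count
and exploits the detector's classification.

The transform is a homography estimated by RANSAC over 4-point minimal
samples solved with a Hartley-normalised direct linear transform (DLT);
the best consensus set is refit by least squares on all inliers.  An
exhaustive mode evaluates every C(M, 4) minimal sample, which is what
budget-controlled evaluation (VTKRS) requires.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .geometry import apply_homography, normalize_homography
from .keypoints import CLASS_NAMES, KeypointSet


class InsufficientMatchesError(RuntimeError):
    pass


@dataclass
class MatchSet:
    """Per-class bidirectional correspondences between two keypoint sets."""

    idx_fixed: np.ndarray  # (M,) indices into kps_fixed
    idx_moving: np.ndarray  # (M,) indices into kps_moving
    classes: np.ndarray  # (M,) class codes (shared by both endpoints)
    similarities: np.ndarray  # (M,) cosine similarities
    kps_fixed: KeypointSet
    kps_moving: KeypointSet

    def __len__(self):
        return len(self.idx_fixed)

    @property
    def xy_fixed(self) -> np.ndarray:
        return self.kps_fixed.xy[self.idx_fixed]

    @property
    def xy_moving(self) -> np.ndarray:
        return self.kps_moving.xy[self.idx_moving]

    def select(self, idx) -> "MatchSet":
        return MatchSet(
            self.idx_fixed[idx],
            self.idx_moving[idx],
            self.classes[idx],
            self.similarities[idx],
            self.kps_fixed,
            self.kps_moving,
        )


def mutual_match(desc_fixed, desc_moving) -> MatchSet:
    """Bidirectional nearest-neighbour matching within each keypoint class.

    Ties in similarity are broken towards the lowest index (np.argmax),
    which makes the matching deterministic.
    """
    kf, km = desc_fixed.kps, desc_moving.kps
    out_f, out_m, out_c, out_s = [], [], [], []
    for cls in range(len(CLASS_NAMES)):
        fi = kf.of_class(cls)
        mi = km.of_class(cls)
        if len(fi) == 0 or len(mi) == 0:
            continue
        sims = desc_fixed.vectors[fi] @ desc_moving.vectors[mi].T
        best_m = np.argmax(sims, axis=1)
        best_f = np.argmax(sims, axis=0)
        for a in range(len(fi)):
            b = best_m[a]
            if best_f[b] == a:
                out_f.append(fi[a])
                out_m.append(mi[b])
                out_c.append(cls)
                out_s.append(sims[a, b])
    return MatchSet(
        np.asarray(out_f, dtype=np.int64),
        np.asarray(out_m, dtype=np.int64),
        np.asarray(out_c, dtype=np.int8),
        np.asarray(out_s, dtype=np.float64),
        kf,
        km,
    )


def rescale_matches(m: MatchSet, from_size, to_size) -> MatchSet:
    """Rescale both keypoint sets from one resolution to another.

    x scales by W_to/W_from and y by H_to/H_from; indices and similarities
    are untouched.
    """
    (hf, wf), (ht, wt) = from_size, to_size
    if min(hf, wf, ht, wt) <= 0:
        raise ValueError("sizes must be positive")
    sx, sy = wt / wf, ht / hf

    def scale(kps):
        xy = kps.xy * np.array([sx, sy])
        return KeypointSet(xy, kps.classes.copy(), (ht, wt))

    return MatchSet(
        m.idx_fixed.copy(),
        m.idx_moving.copy(),
        m.classes.copy(),
        m.similarities.copy(),
        scale(m.kps_fixed),
        scale(m.kps_moving),
    )


# ---------------------------------------------------------------------------
# homography estimation


def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity transform bringing points to centroid 0, mean norm sqrt(2).

    pts: (S, P, 2).  Returns (S, 3, 3).
    """
    centroid = pts.mean(axis=1)  # (S, 2)
    d = np.linalg.norm(pts - centroid[:, None], axis=2).mean(axis=1)  # (S,)
    scale = np.sqrt(2.0) / np.maximum(d, 1e-12)
    t = np.zeros((len(pts), 3, 3))
    t[:, 0, 0] = scale
    t[:, 1, 1] = scale
    t[:, 2, 2] = 1.0
    t[:, 0, 2] = -scale * centroid[:, 0]
    t[:, 1, 2] = -scale * centroid[:, 1]
    return t


def dlt_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Normalised DLT for batches of correspondence sets.

    src, dst: (S, P, 2) with P >= 4 (or (P, 2) for a single set).  Returns
    (S, 3, 3) (or (3, 3)) homographies mapping src -> dst, h33-normalised.
    """
    single = src.ndim == 2
    if single:
        src, dst = src[None], dst[None]
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    s, p, _ = src.shape
    ts = _hartley_normalization(src)
    td = _hartley_normalization(dst)
    sn = np.einsum("sij,spj->spi", ts[:, :2, :2], src) + ts[:, None, :2, 2]
    dn = np.einsum("sij,spj->spi", td[:, :2, :2], dst) + td[:, None, :2, 2]
    a = np.zeros((s, 2 * p, 9))
    x, y = sn[..., 0], sn[..., 1]
    u, v = dn[..., 0], dn[..., 1]
    a[:, 0::2, 0] = -x
    a[:, 0::2, 1] = -y
    a[:, 0::2, 2] = -1.0
    a[:, 0::2, 6] = u * x
    a[:, 0::2, 7] = u * y
    a[:, 0::2, 8] = u
    a[:, 1::2, 3] = -x
    a[:, 1::2, 4] = -y
    a[:, 1::2, 5] = -1.0
    a[:, 1::2, 6] = v * x
    a[:, 1::2, 7] = v * y
    a[:, 1::2, 8] = v
    _, _, vt = np.linalg.svd(a)
    hn = vt[:, -1, :].reshape(s, 3, 3)
    h = np.linalg.inv(td) @ hn @ ts
    w = h[:, 2, 2]
    ok = np.abs(w) > 1e-15
    h[ok] /= w[ok, None, None]
    return h[0] if single else h


def _degenerate_quads(pts: np.ndarray) -> np.ndarray:
    """Boolean mask of 4-point sets containing 3 (near-)collinear points."""
    s = len(pts)
    bad = np.zeros(s, dtype=bool)
    for tri in combinations(range(4), 3):
        p0, p1, p2 = (pts[:, i] for i in tri)
        cross = (p1[:, 0] - p0[:, 0]) * (p2[:, 1] - p0[:, 1]) - (
            p1[:, 1] - p0[:, 1]
        ) * (p2[:, 0] - p0[:, 0])
        span = np.linalg.norm(p1 - p0, axis=1) * np.linalg.norm(p2 - p0, axis=1)
        bad |= np.abs(cross) < 1e-8 * np.maximum(span, 1e-12)
    return bad


@dataclass
class RansacConfig:
    inlier_threshold: float = 5.0  # px, one-way reprojection error
    iterations: int = 10000
    confidence: float = 0.999
    exhaustive: bool = False


def _reproj_errors(h_batch: np.ndarray, src: np.ndarray, dst: np.ndarray):
    """One-way reprojection errors; h_batch (S,3,3), src/dst (M,2) -> (S,M)."""
    ph = np.column_stack([src, np.ones(len(src))])  # (M, 3)
    mapped = np.einsum("sij,mj->smi", h_batch, ph)
    w = mapped[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        xy = mapped[..., :2] / w[..., None]
    err = np.linalg.norm(xy - dst[None], axis=2)
    err[~np.isfinite(err)] = np.inf
    return err


def estimate_homography(
    m: MatchSet | tuple[np.ndarray, np.ndarray],
    cfg: RansacConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """RANSAC homography from matched points.

    ``m`` is a MatchSet or a (src, dst) pair of (M, 2) arrays.  Returns
    (3x3 homography mapping fixed -> moving, boolean inlier flags).
    """
    cfg = cfg or RansacConfig()
    rng = rng or np.random.default_rng(0)
    if isinstance(m, MatchSet):
        src, dst = m.xy_fixed, m.xy_moving
    else:
        src, dst = (np.asarray(a, dtype=np.float64) for a in m)
    n = len(src)
    if n < 4:
        raise InsufficientMatchesError(f"homography needs >= 4 matches, got {n}")

    if cfg.exhaustive:
        samples = np.array(list(combinations(range(n), 4)))
    else:
        n_iter = cfg.iterations
        samples = np.empty((0, 4), dtype=np.int64)

    best_count = -1
    best_h = None
    best_err = np.inf
    processed = 0
    chunk = 2048
    needed = len(samples) if cfg.exhaustive else cfg.iterations

    def eval_chunk(idx_chunk):
        nonlocal best_count, best_h, best_err
        s4, d4 = src[idx_chunk], dst[idx_chunk]
        ok = ~(_degenerate_quads(s4) | _degenerate_quads(d4))
        if not ok.any():
            return
        hs = dlt_homography(s4[ok], d4[ok])
        errs = _reproj_errors(hs, src, dst)
        inl = errs < cfg.inlier_threshold
        counts = inl.sum(axis=1)
        mean_err = np.where(inl, errs, 0.0).sum(axis=1) / np.maximum(counts, 1)
        for t in range(len(hs)):
            if counts[t] > best_count or (
                counts[t] == best_count and mean_err[t] < best_err
            ):
                best_count = int(counts[t])
                best_h = hs[t]
                best_err = float(mean_err[t])

    while processed < needed:
        take = min(chunk, needed - processed)
        if cfg.exhaustive:
            idx_chunk = samples[processed : processed + take]
        else:
            idx_chunk = np.stack(
                [rng.choice(n, size=4, replace=False) for _ in range(take)]
            )
        eval_chunk(idx_chunk)
        processed += take
        if not cfg.exhaustive and best_count >= 4:
            w = best_count / n
            with np.errstate(divide="ignore"):
                denom = np.log(max(1e-12, 1.0 - w**4))
            if denom < 0:
                n_star = np.log(1.0 - cfg.confidence) / denom
                if processed >= n_star:
                    break

    if best_h is None:
        raise InsufficientMatchesError("no non-degenerate minimal sample found")

    inliers = _reproj_errors(best_h[None], src, dst)[0] < cfg.inlier_threshold
    if inliers.sum() >= 4:
        refit = dlt_homography(src[inliers], dst[inliers])
        inliers_refit = _reproj_errors(refit[None], src, dst)[0] < cfg.inlier_threshold
        if inliers_refit.sum() >= inliers.sum():
            best_h, inliers = refit, inliers_refit
    return normalize_homography(best_h), inliers


# ---------------------------------------------------------------------------
# end-to-end pair registration


@dataclass
class RegistrationConfig:
    threshold: float | None = None  # detector extraction threshold override
    window: int | None = None
    ransac: RansacConfig = field(default_factory=RansacConfig)
    lenient: bool = False
    eval_size: tuple[int, int] | None = None  # rescale matches to this (H, W)
    seed: int = 0


@dataclass
class RegistrationResult:
    homography: np.ndarray | None
    matches: MatchSet | None
    inliers: np.ndarray | None
    log: dict
    failure: str | None = None

    @property
    def ok(self) -> bool:
        return self.homography is not None


def register_pair(
    fixed: np.ndarray,
    moving: np.ndarray,
    detector,
    descriptor,
    cfg: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Full inference path: detect, describe, match, estimate homography.

    Returns the fixed -> moving homography along with the matches, inlier
    flags and per-stage counts/timings.  With ``cfg.lenient`` a structured
    failure record is returned instead of raising on insufficient matches.
    """
    from .descriptor import describe, sample_descriptors
    from .detector import detect

    cfg = cfg or RegistrationConfig()
    log: dict = {}
    t0 = time.perf_counter()
    kf = detect(detector, fixed, cfg.threshold, cfg.window)
    km = detect(detector, moving, cfg.threshold, cfg.window)
    log["t_detect"] = time.perf_counter() - t0
    log["n_keypoints_fixed"] = len(kf)
    log["n_keypoints_moving"] = len(km)
    log["n_comparisons"] = comparison_count(len(kf), len(km))

    def fail(msg):
        if cfg.lenient:
            return RegistrationResult(None, None, None, log, failure=msg)
        raise InsufficientMatchesError(msg)

    if len(kf) == 0 or len(km) == 0:
        return fail("no keypoints detected in one of the images")

    t0 = time.perf_counter()
    df = sample_descriptors(describe(descriptor, fixed), kf)
    dm = sample_descriptors(describe(descriptor, moving), km)
    log["t_describe"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    matches = mutual_match(df, dm)
    log["t_match"] = time.perf_counter() - t0
    log["n_matches"] = len(matches)
    if cfg.eval_size is not None:
        matches = rescale_matches(matches, fixed.shape[:2], cfg.eval_size)
    if len(matches) < 4:
        return fail(f"only {len(matches)} mutual matches")

    t0 = time.perf_counter()
    try:
        h, inl = estimate_homography(
            matches, cfg.ransac, np.random.default_rng(cfg.seed)
        )
    except InsufficientMatchesError as e:
        return fail(str(e))
    log["t_ransac"] = time.perf_counter() - t0
    log["n_inliers"] = int(inl.sum())
    return RegistrationResult(h, matches, inl, log)


def comparison_count(k_fixed: int, k_moving: int) -> int:
    """Number of descriptor comparisons in brute-force matching (O(n^2))."""
    if k_fixed < 0 or k_moving < 0:
        raise ValueError("counts must be non-negative")
    return k_fixed * k_moving


def match_precision(matches: MatchSet, h_true: np.ndarray, tol: float = 3.0) -> float:
    """Fraction of matches consistent with a known fixed -> moving warp."""
    if len(matches) == 0:
        return 0.0
    mapped = apply_homography(h_true, matches.xy_fixed)
    err = np.linalg.norm(mapped - matches.xy_moving, axis=1)
    return float((err < tol).mean())
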