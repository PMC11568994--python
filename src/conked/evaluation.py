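"""Registration-quality metrics: score curves, category summaries, VTKRS.

The *registration score* sweeps an error threshold t = 1..25 px over the
per-pair mean control-point error; the success ratio at t is the fraction
of pairs whose error is <= t, and the curve's AUC is the mean of the 25
ratios.  Failed registrations carry error +inf so they penalise every
threshold.  Scores aggregate per category (S: high overlap, P: low
overlap, A: high overlap with pathology progression) as an unweighted
average and a pair-count-weighted average.

*VTKRS* (Variable Top Keypoint Registration Score) recomputes the score
while RANSAC sees only the top-n best-matched keypoints per class, n =
3..25, with an exhaustive RANSAC budget (all C(M, 4) minimal samples), and
summarises the resulting score-vs-n curve by its mean.  It measures how
much registration quality depends on sheer keypoint count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import apply_homography
from .keypoints import CLASS_NAMES
from .registration import (
    InsufficientMatchesError,
    MatchSet,
    RansacConfig,
    estimate_homography,
)

logger = logging.getLogger(__name__)

THRESHOLDS = np.arange(1, 26)  # px, inclusive grid used by the score curve
VTKRS_N_RANGE = range(3, 26)  # top-n per class


@dataclass
class ScoreCurve:
    thresholds: np.ndarray
    success_ratio: np.ndarray
    auc: float


@dataclass
class CategorySummary:
    auc: dict  # category -> AUC
    avg: float
    w_avg: float


def control_point_error(h: np.ndarray, cp_fixed, cp_moving) -> float:
    """Mean Euclidean distance between mapped fixed and true moving points.

    Returns +inf when the transform sends any control point to infinity
    (failed registration sentinel).
    """
    cp_fixed = np.atleast_2d(cp_fixed)
    cp_moving = np.atleast_2d(cp_moving)
    if len(cp_fixed) == 0:
        raise ValueError("need at least one control-point pair")
    mapped = apply_homography(h, cp_fixed)
    if not np.isfinite(mapped).all():
        return np.inf
    return float(np.linalg.norm(mapped - cp_moving, axis=1).mean())


def registration_score(errors) -> ScoreCurve:
    """Success-ratio curve over thresholds 1..25 px and its AUC.

    ``errors``: per-pair mean control-point errors; failures enter as +inf.
    A pair succeeds at threshold t when its error is <= t.
    """
    errors = np.asarray(list(errors), dtype=np.float64)
    if errors.size == 0:
        raise ValueError("need at least one pair")
    ratios = (errors[None, :] <= THRESHOLDS[:, None]).mean(axis=1)
    return ScoreCurve(THRESHOLDS.copy(), ratios, float(ratios.mean()))


def aggregate_by_category(
    per_pair_errors: dict, categories: dict, weights: dict | None = None
) -> CategorySummary:
    """Per-category registration-score AUCs plus (weighted) averages.

    ``weights`` defaults to the per-category pair counts.  Categories with
    no pairs are excluded from the averages with a warning.
    """
    cats = sorted(set(categories.values()))
    aucs = {}
    counts = {}
    for c in cats:
        errs = [e for k, e in per_pair_errors.items() if categories[k] == c]
        if not errs:
            logger.warning("category %s has no pairs; excluded from averages", c)
            continue
        aucs[c] = registration_score(errs).auc
        counts[c] = len(errs)
    if not aucs:
        raise ValueError("no category had any pairs")
    w = weights or counts
    avg = float(np.mean(list(aucs.values())))
    w_avg = float(
        sum(w[c] * aucs[c] for c in aucs) / sum(w[c] for c in aucs)
    )
    return CategorySummary(auc=aucs, avg=avg, w_avg=w_avg)


# ---------------------------------------------------------------------------
# VTKRS


def top_n_matches(matches: MatchSet, n: int) -> MatchSet:
    """Keep the n best matches per class, ranked by descriptor similarity.

    When a class has fewer than n matches, all of them are kept ("no more
    points are added to that specific class").
    """
    keep = []
    for cls in range(len(CLASS_NAMES)):
        idx = np.flatnonzero(matches.classes == cls)
        order = idx[np.argsort(-matches.similarities[idx], kind="stable")]
        keep.extend(order[:n].tolist())
    return matches.select(np.asarray(sorted(keep), dtype=np.int64))


def vtkrs_curve(
    pair_data: list[tuple[MatchSet, np.ndarray, np.ndarray]],
    n_range=VTKRS_N_RANGE,
    inlier_threshold: float = 5.0,
) -> ScoreCurve:
    """VTKRS from per-pair matches and control points.

    ``pair_data``: one (matches, cp_fixed, cp_moving) triple per image
    pair, with matches computed once.  For each n in ``n_range`` the top-n
    matches per class feed an exhaustive RANSAC; the registration-score
    AUC at each n forms a curve whose mean is the VTKRS AUC.  Pairs with
    fewer than 4 kept matches at some n count as failed at that n.
    """
    cfg = RansacConfig(inlier_threshold=inlier_threshold, exhaustive=True)
    ns = np.asarray(list(n_range))
    aucs = []
    for n in ns:
        errors = []
        for matches, cp_fixed, cp_moving in pair_data:
            sub = top_n_matches(matches, int(n))
            if len(sub) < 4:
                errors.append(np.inf)
                continue
            try:
                h, _ = estimate_homography(sub, cfg)
                errors.append(control_point_error(h, cp_fixed, cp_moving))
            except InsufficientMatchesError:
                errors.append(np.inf)
        aucs.append(registration_score(errors).auc)
    aucs = np.asarray(aucs)
    return ScoreCurve(ns, aucs, float(aucs.mean()))


def vtkrs(
    pair_fixtures,
    detector,
    descriptor,
    n_range=VTKRS_N_RANGE,
    inlier_threshold: float = 5.0,
) -> ScoreCurve:
    """Convenience wrapper: run the models on fixtures, then ``vtkrs_curve``.

    ``pair_fixtures`` are RegistrationPairFixture objects; matching is done
    once per pair.
    """
    from .descriptor import describe, sample_descriptors
    from .detector import detect
    from .registration import mutual_match

    pair_data = []
    for fx in pair_fixtures:
        kf = detect(detector, fx.fixed)
        km = detect(detector, fx.moving)
        if len(kf) == 0 or len(km) == 0:
            pair_data.append(
                (
                    MatchSet(
                        np.zeros(0, np.int64),
                        np.zeros(0, np.int64),
                        np.zeros(0, np.int8),
                        np.zeros(0),
                        kf,
                        km,
                    ),
                    fx.cp_fixed,
                    fx.cp_moving,
                )
            )
            continue
        df = sample_descriptors(describe(descriptor, fx.fixed), kf)
        dm = sample_descriptors(describe(descriptor, fx.moving), km)
        pair_data.append((mutual_match(df, dm), fx.cp_fixed, fx.cp_moving))
    return vtkrs_curve(pair_data, n_range, inlier_threshold)
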