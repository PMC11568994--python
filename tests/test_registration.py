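"""Mutual matching, coordinate rescaling and RANSAC homography estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conked.descriptor import DescriptorSet
from conked.geometry import apply_homography
from conked.keypoints import KeypointSet
from conked.registration import (
    InsufficientMatchesError,
    RansacConfig,
    comparison_count,
    dlt_homography,
    estimate_homography,
    mutual_match,
    rescale_matches,
)


def _descset(vectors, classes, size=(100, 100)):
    vectors = np.asarray(vectors, dtype=np.float64)
    vectors = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    k = len(vectors)
    xy = np.column_stack([np.arange(k) * 5.0 + 5, np.arange(k) * 3.0 + 5])
    return DescriptorSet(vectors, KeypointSet(xy, classes, size))


def brute_force_mutual(sims):
    """Exhaustive double-argmax enumeration for a single-class instance."""
    out = []
    for a in range(sims.shape[0]):
        b = int(np.argmax(sims[a]))
        if int(np.argmax(sims[:, b])) == a:
            out.append((a, b))
    return out


class TestMutualMatch:
    def test_identical_sets_match_identically(self, rng):
        v = rng.normal(size=(6, 16))
        classes = [0, 0, 0, 1, 1, 1]
        m = mutual_match(_descset(v, classes), _descset(v, classes))
        assert len(m) == 6
        assert np.array_equal(m.idx_fixed, m.idx_moving)
        assert np.allclose(m.similarities, 1.0)

    def test_hand_worked_similarity_matrix(self):
        # single-class 3x3 similarity matrix with diagonal dominance;
        # realise it exactly with A = sims, B = I so A @ B.T == sims
        sims = np.array([[0.9, 0.1, 0.0], [0.2, 0.8, 0.1], [0.1, 0.0, 0.7]])
        assert brute_force_mutual(sims) == [(0, 0), (1, 1), (2, 2)]
        xy = np.column_stack([np.arange(3) * 5.0 + 5] * 2)
        da = DescriptorSet(sims, KeypointSet(xy, [0, 0, 0], (50, 50)))
        db = DescriptorSet(np.eye(3), KeypointSet(xy, [0, 0, 0], (50, 50)))
        m = mutual_match(da, db)
        assert set(zip(m.idx_fixed.tolist(), m.idx_moving.tolist())) == {
            (0, 0),
            (1, 1),
            (2, 2),
        }
        assert np.allclose(sorted(m.similarities), [0.7, 0.8, 0.9])

    def test_asymmetric_best_is_excluded(self):
        # A0's best is B0, but B0's best is A1 -> (A0, B0) must be excluded
        a = np.array([[1.0, 0.2], [1.0, 0.9]])
        b = np.array([[1.0, 0.6]])
        m = mutual_match(_descset(a, [0, 0]), _descset(b, [0]))
        assert len(m) == 1
        assert (m.idx_fixed[0], m.idx_moving[0]) == (1, 0)

    def test_classes_never_mix(self, rng):
        va = rng.normal(size=(4, 8))
        m = mutual_match(_descset(va, [0, 0, 1, 1]), _descset(va, [1, 1, 0, 0]))
        assert all(
            [0, 0, 1, 1][f] == [1, 1, 0, 0][g]
            for f, g in zip(m.idx_fixed, m.idx_moving)
        )

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        kf = int(rng.integers(2, 30))
        km = int(rng.integers(2, 30))
        a = rng.normal(size=(kf, 8))
        b = rng.normal(size=(km, 8))
        da = _descset(a, [0] * kf, size=(200, 200))
        db = _descset(b, [0] * km, size=(200, 200))
        sims = da.vectors @ db.vectors.T
        expected = set(brute_force_mutual(sims))
        m = mutual_match(da, db)
        assert set(zip(m.idx_fixed.tolist(), m.idx_moving.tolist())) == expected

    def test_symmetry_under_role_swap(self, rng):
        a = rng.normal(size=(7, 8))
        b = rng.normal(size=(9, 8))
        da = _descset(a, [0, 0, 0, 1, 1, 1, 1])
        db = _descset(b, [0, 0, 1, 1, 1, 0, 0, 1, 0])
        m1 = mutual_match(da, db)
        m2 = mutual_match(db, da)
        s1 = set(zip(m1.idx_fixed.tolist(), m1.idx_moving.tolist()))
        s2 = set(zip(m2.idx_moving.tolist(), m2.idx_fixed.tolist()))
        assert s1 == s2


class TestRescale:
    def test_identity_for_equal_sizes(self, rng):
        da = _descset(rng.normal(size=(4, 8)), [0, 0, 1, 1])
        m = mutual_match(da, da)
        r = rescale_matches(m, (100, 100), (100, 100))
        assert np.allclose(r.kps_fixed.xy, m.kps_fixed.xy)

    def test_drive_to_fire_scaling(self, rng):
        # detection at 584x565 rescaled to the 2912x2912 test resolution
        da = _descset(rng.normal(size=(4, 8)), [0, 0, 1, 1], size=(584, 565))
        m = mutual_match(da, da)
        r = rescale_matches(m, (584, 565), (2912, 2912))
        x, y = m.kps_fixed.xy[2]
        assert r.kps_fixed.xy[2, 0] == pytest.approx(x * 2912 / 565)
        assert r.kps_fixed.xy[2, 1] == pytest.approx(y * 2912 / 584)

    def test_round_trip(self, rng):
        da = _descset(rng.normal(size=(4, 8)), [0, 0, 1, 1], size=(584, 565))
        m = mutual_match(da, da)
        r = rescale_matches(
            rescale_matches(m, (584, 565), (2912, 2912)), (2912, 2912), (584, 565)
        )
        assert np.abs(r.kps_fixed.xy - m.kps_fixed.xy).max() < 1e-9


def random_homography(rng, scale=1.0):
    h = np.eye(3)
    h[:2, :2] += rng.uniform(-0.15, 0.15, (2, 2)) * scale
    h[:2, 2] = rng.uniform(-20, 20, 2) * scale
    h[2, :2] = rng.uniform(-1e-4, 1e-4, 2) * scale
    return h


class TestHomographyEstimation:
    def test_exact_correspondences_recover_matrix(self, rng):
        h = random_homography(rng)
        src = rng.uniform(0, 250, (8, 2))
        dst = apply_homography(h, src)
        est, inl = estimate_homography((src, dst), RansacConfig(exhaustive=True))
        assert np.abs(est - h / h[2, 2]).max() < 1e-6
        assert inl.all()

    def test_gross_outliers_are_rejected(self, rng):
        h = random_homography(rng)
        src = rng.uniform(0, 250, (20, 2))
        dst = apply_homography(h, src)
        bad = rng.choice(20, 8, replace=False)
        dst[bad] += rng.uniform(50, 150, (8, 2)) * rng.choice([-1, 1], (8, 2))
        est, inl = estimate_homography(
            (src, dst), RansacConfig(inlier_threshold=5.0), rng
        )
        clean = np.ones(20, bool)
        clean[bad] = False
        assert np.array_equal(inl, clean)
        assert np.abs(est - h / h[2, 2]).max() < 1e-3

    def test_minimal_problem_interpolates(self, rng):
        h = random_homography(rng)
        src = np.array([[10.0, 10.0], [200.0, 15.0], [190.0, 210.0], [20.0, 205.0]])
        dst = apply_homography(h, src)
        est, inl = estimate_homography((src, dst), RansacConfig(exhaustive=True))
        assert np.abs(apply_homography(est, src) - dst).max() < 1e-6
        assert inl.all()

    def test_fewer_than_four_matches_raises(self, rng):
        src = rng.uniform(0, 100, (3, 2))
        with pytest.raises(InsufficientMatchesError):
            estimate_homography((src, src), RansacConfig())

    def test_exhaustive_and_randomized_agree_on_clean_data(self, rng):
        h = random_homography(rng)
        src = rng.uniform(0, 250, (12, 2))
        dst = apply_homography(h, src)
        _, inl_a = estimate_homography((src, dst), RansacConfig(exhaustive=True))
        _, inl_b = estimate_homography((src, dst), RansacConfig(), rng)
        assert np.array_equal(inl_a, inl_b)
        assert inl_a.all()

    def test_recovery_over_many_random_pairs(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(50):
            h = random_homography(rng)
            src = rng.uniform(0, 250, (10, 2))
            dst = apply_homography(h, src)
            est, _ = estimate_homography((src, dst), RansacConfig(exhaustive=True))
            worst = max(worst, float(np.abs(est - h / h[2, 2]).max()))
        assert worst < 1e-5

    def test_dlt_batched_matches_single(self, rng):
        h = random_homography(rng)
        src = rng.uniform(0, 100, (3, 4, 2))
        dst = np.stack([apply_homography(h, s) for s in src])
        batch = dlt_homography(src, dst)
        for i in range(3):
            single = dlt_homography(src[i], dst[i])
            assert np.abs(batch[i] - single).max() < 1e-9


class TestComparisonCount:
    @pytest.mark.parametrize(
        "kf,km,expected",
        [(115, 115, 13_225), (740, 740, 547_600), (5000, 5000, 25_000_000), (0, 7, 0)],
    )
    def test_counts(self, kf, km, expected):
        assert comparison_count(kf, km) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            comparison_count(-1, 3)


class TestRegisterPair:
    def test_blank_images_give_structured_failure(self, rng):
        from conked.descriptor import make_descriptor_model
        from conked.detector import DetectorModel, UNet
        from conked.registration import RegistrationConfig, register_pair

        detector = DetectorModel(unet=UNet(levels=2, width=4, rng=rng))
        descriptor = make_descriptor_model(width=4, dim=8, seed=0)
        blank = np.zeros((64, 64, 3), dtype=np.float32)
        res = register_pair(
            blank, blank, detector, descriptor, RegistrationConfig(lenient=True)
        )
        assert not res.ok
        assert res.failure is not None
        assert "n_keypoints_fixed" in res.log

    def test_strict_mode_raises(self, rng):
        from conked.descriptor import make_descriptor_model
        from conked.detector import DetectorModel, UNet
        from conked.registration import (
            InsufficientMatchesError,
            RegistrationConfig,
            register_pair,
        )

        detector = DetectorModel(unet=UNet(levels=2, width=4, rng=rng))
        descriptor = make_descriptor_model(width=4, dim=8, seed=0)
        blank = np.zeros((64, 64, 3), dtype=np.float32)
        with pytest.raises(InsufficientMatchesError):
            register_pair(blank, blank, detector, descriptor, RegistrationConfig())
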