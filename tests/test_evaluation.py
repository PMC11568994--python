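"""Registration score, category aggregation and VTKRS."""

import numpy as np
import pytest

from conked.descriptor import DescriptorSet
from conked.evaluation import (
    aggregate_by_category,
    control_point_error,
    registration_score,
    top_n_matches,
    vtkrs_curve,
)
from conked.geometry import apply_homography
from conked.keypoints import KeypointSet
from conked.registration import MatchSet, mutual_match


class TestControlPointError:
    def test_identity_on_coincident_points(self):
        cp = np.array([[1.0, 2.0], [5.0, 5.0]])
        assert control_point_error(np.eye(3), cp, cp) == 0.0

    def test_three_four_five_offset(self):
        cp = np.array([[10.0, 10.0], [40.0, 7.0]])
        assert control_point_error(np.eye(3), cp, cp + [3.0, 4.0]) == pytest.approx(5.0)

    def test_matches_per_point_loop_oracle(self, rng):
        h = np.eye(3)
        h[:2, :2] += rng.uniform(-0.1, 0.1, (2, 2))
        h[:2, 2] = rng.uniform(-5, 5, 2)
        h[2, :2] = rng.uniform(-1e-4, 1e-4, 2)
        cpf = rng.uniform(0, 100, (10, 2))
        cpm = rng.uniform(0, 100, (10, 2))
        manual = np.mean(
            [
                float(np.hypot(*(apply_homography(h, p[None])[0] - q)))
                for p, q in zip(cpf, cpm)
            ]
        )
        assert control_point_error(h, cpf, cpm) == pytest.approx(manual, abs=1e-12)

    def test_point_at_infinity_is_failure(self):
        h = np.eye(3)
        h[2] = [1.0, 0.0, -10.0]  # w = 0 on the line x = 10
        assert control_point_error(h, [[10.0, 5.0]], [[0.0, 0.0]]) == np.inf


class TestRegistrationScore:
    def test_all_zero_errors(self):
        assert registration_score([0.0, 0.0]).auc == 1.0

    def test_all_errors_beyond_grid(self):
        assert registration_score([26.0, 100.0, np.inf]).auc == 0.0

    def test_single_pair_worked_example(self):
        # one pair with error 13: ratio 0 for t < 13, 1 for t >= 13
        curve = registration_score([13.0])
        assert curve.success_ratio[:12].max() == 0.0
        assert curve.success_ratio[12:].min() == 1.0
        assert curve.auc == pytest.approx(13.0 / 25.0)

    def test_boundary_counts_as_success(self):
        curve = registration_score([25.0])
        assert curve.success_ratio[-1] == 1.0

    def test_monotone_in_threshold_and_in_errors(self, rng):
        errs = rng.uniform(0, 40, 30)
        curve = registration_score(errs)
        assert (np.diff(curve.success_ratio) >= 0).all()
        better = errs.copy()
        better[0] = max(0.0, better[0] - 10)
        curve2 = registration_score(better)
        assert (curve2.success_ratio >= curve.success_ratio).all()
        assert curve2.auc >= curve.auc


class TestAggregation:
    def test_equal_category_aucs(self):
        errors = {f"p{i}": 0.0 for i in range(6)}
        cats = {f"p{i}": "APS"[i % 3] for i in range(6)}
        s = aggregate_by_category(errors, cats)
        assert s.avg == pytest.approx(1.0)
        assert s.w_avg == pytest.approx(1.0)

    def test_weighted_average_with_benchmark_pair_counts(self):
        # categories A/P/S with AUCs 0.6/0.4/0.9 and pair counts 14/49/71
        aucs = {"A": 0.6, "P": 0.4, "S": 0.9}
        weights = {"A": 14, "P": 49, "S": 71}
        expected = (14 * 0.6 + 49 * 0.4 + 71 * 0.9) / 134
        assert expected == pytest.approx(0.6858, abs=5e-4)
        # the weighted mean produced by the aggregator must follow the same
        # arithmetic for whatever per-category AUCs the data realise
        rng = np.random.default_rng(0)
        errors, cats = {}, {}
        i = 0
        for c, n in weights.items():
            for _ in range(n):
                errors[i] = float(rng.uniform(0, 35))
                cats[i] = c
                i += 1
        s = aggregate_by_category(errors, cats, weights=weights)
        manual_w = sum(weights[c] * s.auc[c] for c in s.auc) / sum(weights.values())
        assert s.w_avg == pytest.approx(manual_w, abs=1e-12)
        assert s.avg == pytest.approx(np.mean(list(s.auc.values())), abs=1e-12)

    def test_unweighted_average(self):
        aucs = (0.6, 0.4, 0.9)
        assert np.mean(aucs) == pytest.approx(0.63333, abs=1e-4)

    def test_empty_category_excluded_with_warning(self, caplog):
        errors = {0: 1.0, 1: 2.0}
        cats = {0: "S", 1: "S"}
        s = aggregate_by_category(errors, cats, weights={"S": 2})
        assert list(s.auc) == ["S"]


def _perfect_pair(rng, n_cross=6, n_bif=6, size=(256, 256)):
    """A synthetic matched pair: perfect descriptors under a known warp."""
    h = np.eye(3)
    h[:2, :2] += rng.uniform(-0.05, 0.05, (2, 2))
    h[:2, 2] = rng.uniform(-8, 8, 2)
    k = n_cross + n_bif
    xy = rng.uniform(30, 220, (k, 2))
    classes = np.array([0] * n_cross + [1] * n_bif, dtype=np.int8)
    kf = KeypointSet(xy, classes, size)
    km = KeypointSet(apply_homography(h, xy), classes, size)
    # orthonormal descriptors: similarity 1 for true pairs, 0 otherwise
    vec = np.eye(k)
    df = DescriptorSet(vec, kf)
    dm = DescriptorSet(vec, km)
    m = mutual_match(df, dm)
    cp = rng.uniform(40, 200, (10, 2))
    return m, cp, apply_homography(h, cp), h


class TestVtkrs:
    def test_top_n_caps_at_available_matches(self, rng):
        m, *_ = _perfect_pair(rng, n_cross=2, n_bif=8)
        sub = top_n_matches(m, 5)
        assert (sub.classes == 0).sum() == 2  # crossover class capped at 2
        assert (sub.classes == 1).sum() == 5

    def test_perfect_descriptors_make_curve_flat(self):
        rng = np.random.default_rng(1)
        pairs = [_perfect_pair(rng)[:3] for _ in range(3)]
        curve = vtkrs_curve(pairs, n_range=range(3, 8))
        assert np.allclose(curve.success_ratio, curve.success_ratio[0])

    def test_vtkrs_with_all_matches_equals_unlimited_score(self):
        rng = np.random.default_rng(2)
        pairs = []
        errors = []
        from conked.evaluation import control_point_error as cpe
        from conked.registration import RansacConfig, estimate_homography

        for _ in range(3):
            m, cpf, cpm, h = _perfect_pair(rng)
            pairs.append((m, cpf, cpm))
            hh, _ = estimate_homography(m, RansacConfig(exhaustive=True))
            errors.append(cpe(hh, cpf, cpm))
        n_total = max(len(p[0]) for p in pairs)
        curve = vtkrs_curve(pairs, n_range=[n_total])
        assert curve.auc == pytest.approx(registration_score(errors).auc, abs=1e-12)

    def test_insufficient_matches_count_as_failures(self, rng):
        m, cpf, cpm, _ = _perfect_pair(rng, n_cross=1, n_bif=2)  # 3 matches max
        curve = vtkrs_curve([(m, cpf, cpm)], n_range=range(3, 5))
        assert curve.auc == 0.0
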