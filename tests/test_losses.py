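"""Contrastive loss correctness: brute-force oracles, closed forms,
invariances, and analytic gradients."""

from math import comb, exp, log

import numpy as np
import pytest

from conked.losses import (
    MultiviewDescriptorTensor,
    TripletConfig,
    mp_infonce_loss,
    mp_infonce_loss_grad,
    mp_infonce_terms,
    similarity,
    supcon_loss,
    supcon_loss_grad,
    supcon_terms,
    triplet_loss,
)


def rand_tensor(rng, n, k, d=8, tau=0.1):
    z = rng.normal(size=(n + 1, k, d))
    z /= np.linalg.norm(z, axis=-1, keepdims=True)
    return MultiviewDescriptorTensor(z, tau)


def supcon_oracle(t):
    """Literal nested-loop transcription of the SupCon definition."""
    z, tau = t.z, t.tau
    nv, k, _ = z.shape
    total = 0.0
    for i in range(nv):
        for j in range(nv):
            if j == i:
                continue
            for kk in range(k):
                num = exp(z[i, kk] @ z[j, kk] / tau)
                den = sum(
                    exp(z[i, kk] @ z[i, c] / tau) for c in range(k) if c != kk
                )
                den += sum(
                    exp(z[i, kk] @ z[l, c] / tau)
                    for l in range(nv)
                    if l != i
                    for c in range(k)
                )
                total += -log(num / den)
    return total / (nv - 1)


def nce_oracle(t):
    """Literal nested-loop transcription of the MP-InfoNCE definition."""
    z, tau = t.z, t.tau
    nv, k, _ = z.shape
    total = 0.0
    for i in range(nv):
        for j in range(i + 1, nv):
            for kk in range(k):
                num = exp(z[i, kk] @ z[j, kk] / tau)
                den = sum(
                    exp(z[i, kk] @ z[i, c] / tau) for c in range(k) if c != kk
                )
                den += sum(exp(z[i, kk] @ z[j, c] / tau) for c in range(k))
                total += -log(num / den)
    return total / (comb(nv, 2) * k)


class TestSimilarity:
    def test_identical_and_orthogonal(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([0.0, 1.0, 0.0])
        assert similarity(a, a) == pytest.approx(1.0)
        assert similarity(a, b) == pytest.approx(0.0)

    def test_matches_scalar_loop(self, rng):
        a = rng.normal(size=16)
        a /= np.linalg.norm(a)
        b = rng.normal(size=16)
        b /= np.linalg.norm(b)
        manual = sum(float(x) * float(y) for x, y in zip(a, b))
        assert similarity(a, b) == pytest.approx(manual, abs=1e-12)

    def test_rejects_non_unit(self):
        with pytest.raises(ValueError):
            similarity(np.array([2.0, 0.0]), np.array([1.0, 0.0]))


class TestClosedForms:
    def test_supcon_identical_descriptors(self):
        # N=1, K=2, all descriptors equal: every term is log 3, 4 terms, 1/N=1
        z = np.tile(np.eye(8)[0], (2, 2, 1))
        t = MultiviewDescriptorTensor(z)
        assert supcon_loss(t) == pytest.approx(4 * np.log(3), abs=1e-9)

    @pytest.mark.parametrize("n", [1, 3, 9])
    def test_mp_infonce_identical_descriptors(self, n):
        # K=2: each term is log(2K-1)=log 3; normalisation cancels the count
        z = np.tile(np.eye(8)[0], (n + 1, 2, 1))
        t = MultiviewDescriptorTensor(z)
        assert mp_infonce_loss(t) == pytest.approx(np.log(3), abs=1e-9)

    def test_supcon_high_temperature_limit(self, rng):
        # tau -> inf: all exponents -> 1, loss -> (N+1) K log(K-1+NK)
        t = rand_tensor(rng, n=2, k=3, tau=1e9)
        expected = 3 * 3 * np.log(3 - 1 + 2 * 3)
        assert supcon_loss(t) == pytest.approx(expected, rel=1e-6)


class TestOracleEquivalence:
    @pytest.mark.parametrize("n,k", [(1, 2), (2, 3), (3, 4), (9, 5), (3, 8)])
    def test_supcon_matches_loop(self, rng, n, k):
        for _ in range(5):
            t = rand_tensor(rng, n, k)
            assert supcon_loss(t) == pytest.approx(supcon_oracle(t), rel=1e-10)

    @pytest.mark.parametrize("n,k", [(1, 2), (2, 3), (3, 4), (9, 5), (2, 8)])
    def test_mp_infonce_matches_loop(self, rng, n, k):
        for _ in range(5):
            t = rand_tensor(rng, n, k)
            assert mp_infonce_loss(t) == pytest.approx(nce_oracle(t), rel=1e-10)


class TestInvariances:
    def test_keypoint_permutation(self, rng):
        t = rand_tensor(rng, 3, 5)
        perm = rng.permutation(5)
        tp = MultiviewDescriptorTensor(t.z[:, perm], t.tau)
        assert supcon_loss(tp) == pytest.approx(supcon_loss(t), rel=1e-12)
        assert mp_infonce_loss(tp) == pytest.approx(mp_infonce_loss(t), rel=1e-12)

    def test_view_permutation_supcon(self, rng):
        # SupCon sums over ordered view pairs, so any relabeling of views
        # leaves it unchanged.  MP-InfoNCE assigns the anchor role to the
        # lower view index of each pair, so it is only invariant to keypoint
        # relabeling, not to view relabeling.
        t = rand_tensor(rng, 3, 4)
        perm = rng.permutation(4)
        tp = MultiviewDescriptorTensor(t.z[perm], t.tau)
        assert supcon_loss(tp) == pytest.approx(supcon_loss(t), rel=1e-12)

    def test_moving_positives_closer_decreases_loss(self, rng):
        t = rand_tensor(rng, 2, 4)
        # pull every view's descriptors toward the view-0 anchors
        z2 = t.z.copy()
        z2[1:] = 0.5 * z2[1:] + 0.5 * z2[0]
        z2 /= np.linalg.norm(z2, axis=-1, keepdims=True)
        t2 = MultiviewDescriptorTensor(z2, t.tau)
        assert supcon_loss(t2) < supcon_loss(t)
        assert mp_infonce_loss(t2) < mp_infonce_loss(t)

    def test_sharp_temperature_is_finite(self, rng):
        t = rand_tensor(rng, 2, 3, tau=0.01)
        assert np.isfinite(supcon_loss(t))
        assert np.isfinite(mp_infonce_loss(t))

    def test_n1_term_identity(self, rng):
        for _ in range(10):
            t = rand_tensor(rng, 1, 5)
            st = supcon_terms(t)
            nt = mp_infonce_terms(t)
            assert np.abs(st[0, 1] - nt[0, 1]).max() < 1e-10


class TestGradients:
    @pytest.mark.parametrize("fn", [supcon_loss_grad, mp_infonce_loss_grad])
    def test_analytic_matches_numeric(self, rng, fn):
        t = rand_tensor(rng, 2, 3, d=6)
        _, g = fn(t)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 3), (2, 1, 5)]:
            zp = t.z.copy()
            zp[idx] += eps
            zm = t.z.copy()
            zm[idx] -= eps
            # bypass the unit-norm validation for the perturbed copies
            tp = MultiviewDescriptorTensor.__new__(MultiviewDescriptorTensor)
            tp.z, tp.tau = zp, t.tau
            tm = MultiviewDescriptorTensor.__new__(MultiviewDescriptorTensor)
            tm.z, tm.tau = zm, t.tau
            num = (fn(tp)[0] - fn(tm)[0]) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestTriplet:
    @pytest.mark.parametrize(
        "s_ap,s_an,expected",
        [(1.0, 0.0, 0.0), (0.5, 0.5, 0.05), (0.2, 0.9, 0.75)],
    )
    def test_hinge_values(self, s_ap, s_an, expected):
        assert triplet_loss(s_ap, s_an) == pytest.approx(expected)

    def test_margin_must_be_positive(self):
        with pytest.raises(ValueError):
            TripletConfig(margin=0.0)


class TestValidation:
    def test_k1_rejected(self, rng):
        t = rand_tensor(rng, 2, 2)
        t1 = MultiviewDescriptorTensor(t.z[:, :1], t.tau)
        with pytest.raises(ValueError):
            supcon_loss(t1)
        with pytest.raises(ValueError):
            mp_infonce_loss(t1)

    def test_non_unit_tensor_rejected(self):
        with pytest.raises(ValueError):
            MultiviewDescriptorTensor(np.ones((2, 2, 4)))
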