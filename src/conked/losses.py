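"""Multi-positive multi-negative contrastive objectives over descriptors.

A multiviewed batch yields descriptors ``z[i, k]`` for view ``i`` in
``1..N+1`` (view 0 is the original image) and keypoint identity ``k`` in
``1..K``.  All descriptors are L2-normalised, so the cosine similarity of
two descriptors is their dot product.  For an anchor ``z[i, k]`` the
positives are the same keypoint in the other N views and the negatives are
every other keypoint in every view, including the anchor's own view — all
of them hard negatives, since every keypoint is a vessel crossover or
bifurcation.

Two losses are provided:

* **SupCon** — sums, for every ordered view pair (i, j), i != j, and every
  keypoint, the log-ratio of the positive similarity against a denominator
  spanning *all* other samples in the batch (same-view keypoints c != k and
  every keypoint of every other view), scaled by 1/N.
* **MP-InfoNCE** — a multi-positive extension of InfoNCE: for every
  unordered view pair (i, j), j > i, the denominator only spans the anchor
  view (c != k) and the partner view (all c); the sum is normalised by
  C(N+1, 2) * K.

For N = 1 the individual log-ratio terms of the two losses coincide; the
aggregate scalars differ only by their normalisation conventions, which are
kept exactly as defined above.

Both losses are computed with max-subtraction inside each log-sum-exp, so
temperatures as sharp as 0.01 do not overflow.  ``*_grad`` variants return
the analytic gradient with respect to the raw (already normalised)
descriptors, which is all the descriptor training loop needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

DEFAULT_TAU = 0.1


@dataclass
class MultiviewDescriptorTensor:
    """Unit-norm descriptors for an (N+1)-view batch.

    z : (N+1, K, D) array; tau : softmax temperature.
    """

    z: np.ndarray
    tau: float = DEFAULT_TAU

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        if self.z.ndim != 3:
            raise ValueError("z must be (n_views, K, D)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        norms = np.linalg.norm(self.z, axis=-1)
        if len(norms) and np.abs(norms - 1.0).max() > 1e-3:
            raise ValueError("descriptors must be unit-norm")

    @property
    def n_views(self) -> int:
        return self.z.shape[0]

    @property
    def n(self) -> int:
        return self.z.shape[0] - 1

    @property
    def k(self) -> int:
        return self.z.shape[1]


@dataclass
class TripletConfig:
    margin: float = 0.05

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be positive")


def similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two unit descriptors (their dot product)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    for v in (a, b):
        if abs(np.linalg.norm(v) - 1.0) > 1e-3:
            raise ValueError("similarity expects unit-norm descriptors")
    return float(a @ b)


def _check(t: MultiviewDescriptorTensor):
    if t.k < 2:
        raise ValueError("loss needs K >= 2 keypoints")
    if t.n < 1:
        raise ValueError("loss needs at least one augmented view")


def _flat_sim(t: MultiviewDescriptorTensor):
    """Similarity matrix over flattened samples; row m = i*K + k."""
    m = t.n_views * t.k
    z = t.z.reshape(m, -1)
    s = (z @ z.T) / t.tau
    views = np.repeat(np.arange(t.n_views), t.k)
    keys = np.tile(np.arange(t.k), t.n_views)
    return z, s, views, keys


def _masked_lse(s: np.ndarray, mask: np.ndarray):
    """Row-wise log-sum-exp over masked entries, max-stabilised.

    Returns (lse, softmax) where softmax is zero outside the mask.
    """
    neg = np.where(mask, s, -np.inf)
    mx = neg.max(axis=1, keepdims=True)
    e = np.exp(neg - mx)
    tot = e.sum(axis=1, keepdims=True)
    lse = (mx + np.log(tot)).ravel()
    return lse, e / tot


# ---------------------------------------------------------------------------
# SupCon


def supcon_loss(t: MultiviewDescriptorTensor) -> float:
    return _supcon(t, with_grad=False)[0]


def supcon_loss_grad(t: MultiviewDescriptorTensor):
    """Return (loss, dL/dz) with dL/dz shaped like t.z."""
    return _supcon(t, with_grad=True)


def _supcon(t: MultiviewDescriptorTensor, with_grad: bool):
    _check(t)
    z, s, views, keys = _flat_sim(t)
    m = len(z)
    denom_mask = ~np.eye(m, dtype=bool)  # every sample except the anchor
    pos = (keys[:, None] == keys[None, :]) & (views[:, None] != views[None, :])
    lse, soft = _masked_lse(s, denom_mask)
    loss = float(lse.sum() - (s[pos].sum()) / t.n)
    if not with_grad:
        return loss, None
    a = soft - pos / t.n  # dL/dS
    gz = ((a + a.T) @ z) / t.tau
    return loss, gz.reshape(t.z.shape)


def supcon_terms(t: MultiviewDescriptorTensor) -> np.ndarray:
    """Individual log-ratio terms, shape (N+1, N+1, K); entry (i, j, k) is
    the term for anchor view i, positive view j != k-diagonal; the (i, i, :)
    slice is zero.  The loss equals terms.sum() / N."""
    _check(t)
    _, s, views, keys = _flat_sim(t)
    m = s.shape[0]
    lse, _ = _masked_lse(s, ~np.eye(m, dtype=bool))
    nv, k = t.n_views, t.k
    out = np.zeros((nv, nv, k))
    for i in range(nv):
        for j in range(nv):
            if i == j:
                continue
            rows = i * k + np.arange(k)
            cols = j * k + np.arange(k)
            out[i, j] = -s[rows, cols] + lse[rows]
    return out


# ---------------------------------------------------------------------------
# MP-InfoNCE


def mp_infonce_loss(t: MultiviewDescriptorTensor) -> float:
    return _mp_infonce(t, with_grad=False)[0]


def mp_infonce_loss_grad(t: MultiviewDescriptorTensor):
    return _mp_infonce(t, with_grad=True)


def _mp_infonce(t: MultiviewDescriptorTensor, with_grad: bool):
    _check(t)
    z, s, _, _ = _flat_sim(t)
    nv, k = t.n_views, t.k
    norm = 1.0 / (comb(nv, 2) * k)
    total = 0.0
    a = np.zeros_like(s) if with_grad else None
    eye = np.eye(k, dtype=bool)
    for i in range(nv):
        ri = i * k
        for j in range(i + 1, nv):
            rj = j * k
            s_ii = s[ri : ri + k, ri : ri + k]
            s_ij = s[ri : ri + k, rj : rj + k]
            cat = np.concatenate([s_ii, s_ij], axis=1)  # (K, 2K)
            mask = np.concatenate([~eye, np.ones((k, k), dtype=bool)], axis=1)
            lse, soft = _masked_lse(cat, mask)
            total += float(lse.sum() - np.trace(s_ij))
            if with_grad:
                a[ri : ri + k, ri : ri + k] += norm * soft[:, :k]
                a[ri : ri + k, rj : rj + k] += norm * soft[:, k:]
                a[ri : ri + k, rj : rj + k][eye] -= norm
    loss = norm * total
    if not with_grad:
        return loss, None
    gz = ((a + a.T) @ z) / t.tau
    return loss, gz.reshape(t.z.shape)


def mp_infonce_terms(t: MultiviewDescriptorTensor) -> np.ndarray:
    """Log-ratio terms, shape (N+1, N+1, K); entry (i, j, k) for j > i is
    the anchor-i / partner-j term; other entries are zero.  The loss equals
    terms.sum() / (C(N+1, 2) * K)."""
    _check(t)
    _, s, _, _ = _flat_sim(t)
    nv, k = t.n_views, t.k
    eye = np.eye(k, dtype=bool)
    out = np.zeros((nv, nv, k))
    for i in range(nv):
        ri = i * k
        for j in range(i + 1, nv):
            rj = j * k
            s_ii = s[ri : ri + k, ri : ri + k]
            s_ij = s[ri : ri + k, rj : rj + k]
            cat = np.concatenate([s_ii, s_ij], axis=1)
            mask = np.concatenate([~eye, np.ones((k, k), dtype=bool)], axis=1)
            lse, _ = _masked_lse(cat, mask)
            out[i, j] = -np.diag(s_ij) + lse
    return out


# ---------------------------------------------------------------------------
# triplet baseline


def triplet_loss(s_ap, s_an, cfg: TripletConfig | None = None):
    """Hinge on cosine distances: max(0, margin - s_ap + s_an)."""
    cfg = cfg or TripletConfig()
    s_ap = np.asarray(s_ap, dtype=np.float64)
    s_an = np.asarray(s_an, dtype=np.float64)
    out = np.maximum(0.0, cfg.margin - s_ap + s_an)
    return float(out) if out.ndim == 0 else out
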