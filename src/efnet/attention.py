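"""3D multi-head self-attention with decomposed relative positional encoding.

Attention over all T*H*W positions of a spatiotemporal feature map.  The
position term r is the broadcast sum of three learned tables — temporal
(Rt: T x D x 1 x 1), height (Rh: 1 x D x H x 1) and width (Rw: 1 x D x 1 x W) —
applied to both queries and keys, so attention logits for head i are

    (Qi Ki^T + Qi r^T + r Ki^T) / sqrt(d),    d = D / n_heads.

Q, K, V come from 1x1x1 convolutions (channel-wise linear maps with bias);
head outputs are concatenated back to D channels with no output projection.

``mhsa3d_reference`` recomputes the same quantity with explicit per-position
scalar loops and shares no code with the vectorized path; it is the oracle
the fast implementation is tested against.
"""

from __future__ import annotations

import math

import numpy as np

from .nn import Module, Parameter

#: refuse attention over more flattened positions than this unless overridden
MAX_POSITIONS = 50_000


class RelPosEncoding(Module):
    """Learned decomposed position tables; r = Rt + Rh + Rw, shape T x D x H x W."""

    def __init__(self, channels: int, t: int, h: int, w: int, init_std: float = 0.02, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.rt = Parameter(rng.normal(0.0, init_std, (t, channels, 1, 1)))
        self.rh = Parameter(rng.normal(0.0, init_std, (1, channels, h, 1)))
        self.rw = Parameter(rng.normal(0.0, init_std, (1, channels, 1, w)))
        self.shape = (t, h, w)
        self.channels = channels

    def flat(self) -> np.ndarray:
        """Broadcast sum flattened to (N, D), N = T*H*W in C order over (T, H, W)."""
        r = self.rt.data + self.rh.data + self.rw.data  # T,D,H,W
        t, h, w = self.shape
        return r.transpose(0, 2, 3, 1).reshape(t * h * w, self.channels)

    def accumulate_flat_grad(self, dr_flat: np.ndarray) -> None:
        t, h, w = self.shape
        dr = dr_flat.reshape(t, h, w, self.channels).transpose(0, 3, 1, 2)
        self.rt.grad += dr.sum(axis=(2, 3), keepdims=True)
        self.rh.grad += dr.sum(axis=(0, 3), keepdims=True)
        self.rw.grad += dr.sum(axis=(0, 2), keepdims=True)


class MHSA3d(Module):
    """Multi-head self-attention over a (B, D, T, H, W) feature map."""

    def __init__(
        self,
        channels: int,
        t: int,
        h: int,
        w: int,
        n_heads: int = 4,
        rpe_init_std: float = 0.02,
        rng=None,
        allow_large: bool = False,
    ):
        super().__init__()
        if channels % n_heads:
            raise ValueError(f"channels {channels} not divisible by n_heads {n_heads}")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.n_heads = n_heads
        self.head_dim = channels // n_heads
        self.grid = (t, h, w)
        self.allow_large = allow_large
        scale = math.sqrt(1.0 / channels)
        self.wq = Parameter(rng.normal(0.0, scale, (channels, channels)))
        self.bq = Parameter(np.zeros(channels))
        self.wk = Parameter(rng.normal(0.0, scale, (channels, channels)))
        self.bk = Parameter(np.zeros(channels))
        self.wv = Parameter(rng.normal(0.0, scale, (channels, channels)))
        self.bv = Parameter(np.zeros(channels))
        self.rpe = RelPosEncoding(channels, t, h, w, init_std=rpe_init_std, rng=rng)
        self._cache = None

    def _check(self, x):
        b, d, t, h, w = x.shape
        if d != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {d}")
        if (t, h, w) != self.grid:
            raise ValueError(f"feature grid {(t, h, w)} != positional grid {self.grid}")
        n = t * h * w
        if n > MAX_POSITIONS and not self.allow_large:
            raise ValueError(
                f"attention over {n} positions exceeds the {MAX_POSITIONS} guard; "
                "set allow_large=True to override"
            )
        return b, n

    def _heads(self, m: np.ndarray, b: int, n: int) -> np.ndarray:
        # (B,N,D) -> (B,heads,N,d)
        return m.reshape(b, n, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: np.ndarray, return_attention: bool = False):
        b, n = self._check(x)
        d = self.head_dim
        xm = x.transpose(0, 2, 3, 4, 1).reshape(b, n, self.channels)
        q = xm @ self.wq.data.T + self.bq.data
        k = xm @ self.wk.data.T + self.bk.data
        v = xm @ self.wv.data.T + self.bv.data
        r = self.rpe.flat().astype(x.dtype)  # (N, D)

        qh = self._heads(q, b, n)
        kh = self._heads(k, b, n)
        vh = self._heads(v, b, n)
        rh = r.reshape(n, self.n_heads, d).transpose(1, 0, 2)  # heads,N,d

        inv = 1.0 / math.sqrt(d)
        out = np.empty_like(qh)
        attn_all = np.empty((b, self.n_heads, n, n), dtype=x.dtype) if (
            return_attention or self.training
        ) else None
        for i in range(self.n_heads):  # per-head loop caps the N x N memory
            logits = (
                qh[:, i] @ kh[:, i].transpose(0, 2, 1)
                + qh[:, i] @ rh[i].T
                + rh[i] @ kh[:, i].transpose(0, 2, 1)
            ) * inv
            logits -= logits.max(axis=-1, keepdims=True)
            np.exp(logits, out=logits)
            logits /= logits.sum(axis=-1, keepdims=True)
            out[:, i] = logits @ vh[:, i]
            if attn_all is not None:
                attn_all[:, i] = logits

        y = out.transpose(0, 2, 1, 3).reshape(b, n, self.channels)
        t, h, w = self.grid
        y5 = np.ascontiguousarray(
            y.reshape(b, t, h, w, self.channels).transpose(0, 4, 1, 2, 3)
        )
        if self.training:
            self._cache = (xm, qh, kh, vh, rh, attn_all, x.dtype)
        if return_attention:
            return y5, attn_all
        return y5

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called on MHSA3d without a cached forward")
        xm, qh, kh, vh, rh, attn, dtype = self._cache
        b, n = xm.shape[:2]
        d = self.head_dim
        inv = 1.0 / math.sqrt(d)
        t, h, w = self.grid

        dym = dy.transpose(0, 2, 3, 4, 1).reshape(b, n, self.channels)
        dyh = self._heads(dym, b, n)

        dq = np.empty_like(qh)
        dk = np.empty_like(kh)
        dv = np.empty_like(vh)
        dr_h = np.zeros_like(rh)
        for i in range(self.n_heads):
            a = attn[:, i]
            dv[:, i] = a.transpose(0, 2, 1) @ dyh[:, i]
            da = dyh[:, i] @ vh[:, i].transpose(0, 2, 1)
            dlogits = a * (da - (da * a).sum(axis=-1, keepdims=True))
            dlogits *= inv
            dq[:, i] = dlogits @ (kh[:, i] + rh[i])
            dk[:, i] = dlogits.transpose(0, 2, 1) @ (qh[:, i] + rh[i])
            # r enters once as key position, once as query position
            dr_h[i] = (
                np.einsum("bnm,bnd->md", dlogits, qh[:, i], optimize=True)
                + np.einsum("bnm,bmd->nd", dlogits, kh[:, i], optimize=True)
            )

        def merge(heads):  # (B,heads,N,d) -> (B,N,D)
            return heads.transpose(0, 2, 1, 3).reshape(b, n, self.channels)

        dqm, dkm, dvm = merge(dq), merge(dk), merge(dv)
        self.wq.grad += np.einsum("bnd,bnc->dc", dqm, xm, optimize=True)
        self.bq.grad += dqm.sum(axis=(0, 1))
        self.wk.grad += np.einsum("bnd,bnc->dc", dkm, xm, optimize=True)
        self.bk.grad += dkm.sum(axis=(0, 1))
        self.wv.grad += np.einsum("bnd,bnc->dc", dvm, xm, optimize=True)
        self.bv.grad += dvm.sum(axis=(0, 1))

        dr_flat = dr_h.transpose(1, 0, 2).reshape(n, self.channels)
        self.rpe.accumulate_flat_grad(dr_flat)

        dxm = dqm @ self.wq.data + dkm @ self.wk.data + dvm @ self.wv.data
        dx = dxm.reshape(b, t, h, w, self.channels).transpose(0, 4, 1, 2, 3)
        self._cache = None
        return np.ascontiguousarray(dx).astype(dtype)


def mhsa3d(
    x: np.ndarray,
    weights: dict[str, np.ndarray],
    rpe: dict[str, np.ndarray],
    n_heads: int,
) -> np.ndarray:
    """Functional front end: arrays in, attention output out.

    ``weights`` holds wq/wk/wv (D x D) and bq/bk/bv (D); ``rpe`` holds
    rt (T x D x 1 x 1), rh (1 x D x H x 1), rw (1 x D x 1 x W).
    """
    _, d, t, h, w = x.shape
    layer = MHSA3d.__new__(MHSA3d)
    Module.__init__(layer)
    if d % n_heads:
        raise ValueError(f"channels {d} not divisible by n_heads {n_heads}")
    layer.channels = d
    layer.n_heads = n_heads
    layer.head_dim = d // n_heads
    layer.grid = (t, h, w)
    layer.allow_large = False
    layer._cache = None
    for name in ("wq", "bq", "wk", "bk", "wv", "bv"):
        setattr(layer, name, Parameter(np.asarray(weights[name])))
    layer.rpe = RelPosEncoding.__new__(RelPosEncoding)
    Module.__init__(layer.rpe)
    layer.rpe.rt = Parameter(np.asarray(rpe["rt"]))
    layer.rpe.rh = Parameter(np.asarray(rpe["rh"]))
    layer.rpe.rw = Parameter(np.asarray(rpe["rw"]))
    layer.rpe.shape = (t, h, w)
    layer.rpe.channels = d
    layer.eval()
    return layer.forward(x)


def mhsa3d_reference(
    x: np.ndarray,
    weights: dict[str, np.ndarray],
    rpe: dict[str, np.ndarray],
    n_heads: int,
) -> np.ndarray:
    """Loop-based oracle for tiny inputs (N <= 512); shares no code with mhsa3d.

    Every query/key pair is handled one at a time with scalar accumulation:
    logit(n, m) = (q_n.k_m + q_n.r_m + r_n.k_m) / sqrt(d), softmax over m,
    output(n) = sum_m softmax(n, m) * v_m, heads concatenated.
    """
    x = np.asarray(x, dtype=np.float64)
    b, dch, t, h, w = x.shape
    n = t * h * w
    if n > 512:
        raise ValueError(f"reference oracle is for tiny inputs only (N={n} > 512)")
    if dch % n_heads:
        raise ValueError(f"channels {dch} not divisible by n_heads {n_heads}")
    d = dch // n_heads

    # per-position channel vectors, C-order over (t, h, w)
    positions = []
    for ti in range(t):
        for hi in range(h):
            for wi in range(w):
                positions.append(x[:, :, ti, hi, wi])  # (B, D) each

    wq, bq = np.asarray(weights["wq"], float), np.asarray(weights["bq"], float)
    wk, bk = np.asarray(weights["wk"], float), np.asarray(weights["bk"], float)
    wv, bv = np.asarray(weights["wv"], float), np.asarray(weights["bv"], float)
    rt = np.asarray(rpe["rt"], float)
    rhh = np.asarray(rpe["rh"], float)
    rw = np.asarray(rpe["rw"], float)

    r_vecs = []
    for ti in range(t):
        for hi in range(h):
            for wi in range(w):
                r_vecs.append(rt[ti, :, 0, 0] + rhh[0, :, hi, 0] + rw[0, :, 0, wi])

    out = np.zeros((b, dch, t, h, w))
    for bi in range(b):
        qs = [wq @ positions[m][bi] + bq for m in range(n)]
        ks = [wk @ positions[m][bi] + bk for m in range(n)]
        vs = [wv @ positions[m][bi] + bv for m in range(n)]
        for head in range(n_heads):
            sl = slice(head * d, (head + 1) * d)
            for qi in range(n):
                logits = []
                for ki in range(n):
                    dot = 0.0
                    for c in range(d):
                        qc = qs[qi][sl][c]
                        kc = ks[ki][sl][c]
                        rq = r_vecs[qi][sl][c]
                        rk = r_vecs[ki][sl][c]
                        dot += qc * kc + qc * rk + rq * kc
                    logits.append(dot / math.sqrt(d))
                peak = max(logits)
                weights_row = [math.exp(l - peak) for l in logits]
                total = sum(weights_row)
                acc = np.zeros(d)
                for ki in range(n):
                    acc += (weights_row[ki] / total) * vs[ki][sl]
                ti, rem = divmod(qi, h * w)
                hi, wi = divmod(rem, w)
                out[bi, sl, ti, hi, wi] = acc
    return out
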