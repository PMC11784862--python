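"""Small NumPy neural-network layer framework with explicit backprop.

Provides exactly what the 3D residual-transformer regressor needs:
3D convolution (im2col), batch normalization, ReLU, linear, global average
pooling, a sequential container and Adam.  Every layer implements
``forward(x)`` (caching what backward needs) and ``backward(dy)`` which
accumulates parameter gradients and returns the input gradient.  Gradients
are verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: parameter bookkeeping plus train/eval mode."""

    def __init__(self):
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def submodules(self):
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield attr
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = ""):
        for name, attr in vars(self).items():
            if isinstance(attr, Parameter):
                yield (f"{prefix}{name}", attr)
        for name, attr in vars(self).items():
            if isinstance(attr, Module):
                yield from attr.named_parameters(f"{prefix}{name}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.submodules():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"{name}: shape {state[name].shape} != {p.data.shape}")
            p.data[...] = state[name]


def count_parameters(model: Module) -> int:
    """Total number of trainable scalars in the model."""
    return sum(p.size for p in model.parameters())


# ---------------------------------------------------------------------------
# convolution


def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, int):
        return (v, v, v)
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected int or length-3 tuple, got {v!r}")
    return t


def _im2col(xp: np.ndarray, kernel, stride) -> np.ndarray:
    """Extract strided patches from padded input (B,C,T,H,W) -> (B, P, C*kt*kh*kw)."""
    kt, kh, kw = kernel
    st, sh, sw = stride
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kt, kh, kw), axis=(2, 3, 4))
    windows = windows[:, :, ::st, ::sh, ::sw]  # B,C,To,Ho,Wo,kt,kh,kw
    b, c, to, ho, wo = windows.shape[:5]
    cols = windows.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(b, to * ho * wo, c * kt * kh * kw)
    return np.ascontiguousarray(cols), (to, ho, wo)


def conv3d_forward(x, weight, bias, stride, padding):
    """Plain strided cross-correlation; returns (y, cols) with cols for backward."""
    st = _triple(stride)
    pd = _triple(padding)
    xp = np.pad(x, ((0, 0), (0, 0), (pd[0], pd[0]), (pd[1], pd[1]), (pd[2], pd[2])))
    cols, (to, ho, wo) = _im2col(xp, weight.shape[2:], st)
    wmat = weight.reshape(weight.shape[0], -1)
    y = cols @ wmat.T  # B,P,cout
    if bias is not None:
        y = y + bias
    b = x.shape[0]
    y = y.reshape(b, to, ho, wo, weight.shape[0]).transpose(0, 4, 1, 2, 3)
    return np.ascontiguousarray(y), cols


def conv3d_input_grad(dy, weight, x_shape, stride, padding):
    """Gradient w.r.t. the conv input: dcols = dy @ W folded back (col2im).

    The fold is one strided in-place add per kernel offset, so nothing larger
    than the im2col matrix itself is ever materialized.
    """
    st, sh, sw = _triple(stride)
    pt, ph, pw = _triple(padding)
    cout, cin, kt, kh, kw = weight.shape
    b = dy.shape[0]
    to, ho, wo = dy.shape[2:]
    ti, hi, wi = x_shape[2:]

    dy_mat = dy.transpose(0, 2, 3, 4, 1).reshape(b, -1, cout)
    dcols = dy_mat @ weight.reshape(cout, -1)  # B,P,C*kt*kh*kw
    dcols = dcols.reshape(b, to, ho, wo, cin, kt, kh, kw)

    dxp = np.zeros((b, cin, ti + 2 * pt, hi + 2 * ph, wi + 2 * pw), dtype=dy.dtype)
    for a in range(kt):
        for c in range(kh):
            for e in range(kw):
                dxp[
                    :, :,
                    a : a + to * st : st,
                    c : c + ho * sh : sh,
                    e : e + wo * sw : sw,
                ] += dcols[:, :, :, :, :, a, c, e].transpose(0, 4, 1, 2, 3)
    return dxp[:, :, pt : pt + ti, ph : ph + hi, pw : pw + wi]


class Conv3d(Module):
    """3D convolution; bias-free by default (the BN that follows supplies the shift)."""

    def __init__(self, cin, cout, kernel, stride=1, padding=0, bias=False, rng=None):
        super().__init__()
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)
        self.padding = _triple(padding)
        fan_in = cin * int(np.prod(self.kernel))
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU networks
        self.weight = Parameter(rng.normal(0.0, scale, (cout, cin, *self.kernel)))
        self.bias = Parameter(np.zeros(cout)) if bias else None
        self._cache = None

    def named_parameters(self, prefix: str = ""):
        yield (f"{prefix}weight", self.weight)
        if self.bias is not None:
            yield (f"{prefix}bias", self.bias)

    def forward(self, x):
        bias = self.bias.data if self.bias is not None else None
        y, cols = conv3d_forward(x, self.weight.data, bias, self.stride, self.padding)
        # caching the im2col matrix is only needed for backward; skip in eval
        self._cache = (x.shape, cols) if self.training else None
        return y

    def backward(self, dy):
        if self._cache is None:
            raise RuntimeError("backward called on a Conv3d that ran in eval mode")
        x_shape, cols = self._cache
        b, cout = dy.shape[:2]
        dy_mat = dy.transpose(0, 2, 3, 4, 1).reshape(b, -1, cout)
        dw = np.einsum("bpo,bpc->oc", dy_mat, cols, optimize=True)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dy_mat.sum(axis=(0, 1))
        self._cache = None
        return conv3d_input_grad(dy, self.weight.data, x_shape, self.stride, self.padding)


class BatchNorm3d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def _shape(self, v):
        return v.reshape(1, -1, 1, 1, 1)

    def forward(self, x):
        if self.training:
            axes = (0, 2, 3, 4)
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // x.shape[1]
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * n / max(n - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(mean)) * self._shape(inv_std)
        self._cache = (xhat, inv_std)
        return self._shape(self.gamma.data) * xhat + self._shape(self.beta.data)

    def backward(self, dy):
        xhat, inv_std = self._cache
        axes = (0, 2, 3, 4)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self._shape(self.gamma.data)
        if not self.training:
            return dxhat * self._shape(inv_std)
        n = dy.size // dy.shape[1]
        term = (
            dxhat
            - self._shape(dxhat.sum(axis=axes)) / n
            - xhat * self._shape((dxhat * xhat).sum(axis=axes)) / n
        )
        self._cache = None
        return term * self._shape(inv_std)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Linear(Module):
    def __init__(self, cin, cout, rng=None, bias_init=0.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(rng.normal(0.0, np.sqrt(1.0 / cin), (cout, cin)))
        self.bias = Parameter(np.full(cout, bias_init, dtype=np.float32))

    def forward(self, x):
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy):
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data


class GlobalAvgPool3d(Module):
    """Average over (T, H, W): (B, C, T, H, W) -> (B, C)."""

    def forward(self, x):
        self._shape_in = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dy):
        b, c, t, h, w = self._shape_in
        return np.broadcast_to(dy[:, :, None, None, None], self._shape_in) / (t * h * w)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay added to the gradient."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
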