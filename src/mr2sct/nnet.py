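"""Minimal CPU neural-network engine used by the translation GAN.

Implements exactly the layer set the generator/discriminator need —
strided 2D convolutions, instance normalisation, nearest-neighbour
upsampling, a dense head, the usual activations — with hand-derived
backward passes and an Adam optimizer.  Everything runs in float32 on
numpy arrays laid out channels-last, ``(N, H, W, C)``: convolutions are
evaluated as one GEMM per kernel tap accumulated over taps, which keeps
the working set in cache-friendly contiguous runs and hands all heavy
lifting to BLAS.

Layers cache their forward inputs, so each ``forward`` must be paired
with its ``backward`` before the layer is reused.  Gradients accumulate
into ``Param.grad`` until ``zero_grad``; this makes multi-term losses
(adversarial + L1) a plain sequence of backward calls.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2D convolution (cross-correlation) with integer padding.

    Weights are stored ``(k, k, cin, cout)``; the forward pass is a sum of
    ``k*k`` GEMMs, one per kernel tap, over shifted views of the padded
    input.  Requires ``(H + 2*pad - k)`` divisible by ``stride``.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k, k, cin, cout)))
        self.b = Param(np.zeros(cout))
        self._xp = None

    def params(self):
        return [self.w, self.b]

    def _out_extent(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.k, self.stride, self.pad
        if (h + 2 * p - k) % s or (w + 2 * p - k) % s:
            raise ValueError(
                f"spatial extent {h}x{w} incompatible with k={k}, stride={s}, "
                f"pad={p}; pad input so (H+2*pad-k) % stride == 0"
            )
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def forward(self, x, train=True):
        k, s, p = self.k, self.stride, self.pad
        n, h, w, _ = x.shape
        ho, wo = self._out_extent(h, w)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        y = np.empty((n * ho * wo, self.cout), dtype=F32)
        y[:] = self.b.value
        taps = []
        for ki in range(k):
            for kj in range(k):
                a = xp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :]
                a = np.ascontiguousarray(a).reshape(-1, self.cin)
                y += a @ self.w.value[ki, kj]
                if train:
                    taps.append(a)
        if train:
            self._taps, self._xshape = taps, x.shape
        return y.reshape(n, ho, wo, self.cout)

    def backward(self, dy):
        k, s, p = self.k, self.stride, self.pad
        n, ho, wo, cout = dy.shape
        _, h, w, _ = self._xshape
        dyf = dy.reshape(-1, cout)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.cin), dtype=F32)
        for ki in range(k):
            for kj in range(k):
                a = self._taps[ki * k + kj]
                self.w.grad[ki, kj] += a.T @ dyf
                dxp[:, ki:ki + s * ho:s, kj:kj + s * wo:s, :] += (
                    dyf @ self.w.value[ki, kj].T
                ).reshape(n, ho, wo, self.cin)
        self.b.grad += dyf.sum(axis=0)
        self._taps = None
        if p:
            dxp = dxp[:, p:-p, p:-p, :]
        return np.ascontiguousarray(dxp)


class InstanceNorm(Layer):
    """Per-sample, per-channel normalisation with learned affine."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.eps = eps
        self.g = Param(np.ones(c))
        self.b = Param(np.zeros(c))

    def params(self):
        return [self.g, self.b]

    def forward(self, x, train=True):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._xhat, self._inv = xhat, inv
        return self.g.value * xhat + self.b.value

    def backward(self, dy):
        xhat, inv = self._xhat, self._inv
        m = dy.shape[1] * dy.shape[2]
        self.g.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.b.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.g.value
        dx = (inv / m) * (
            m * dxhat
            - dxhat.sum(axis=(1, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(1, 2), keepdims=True)
        )
        self._xhat = self._inv = None
        return dx.astype(F32, copy=False)


class ReLU(Layer):
    def forward(self, x, train=True):
        y = np.maximum(x, 0)
        if train:
            self._m = x > 0
        return y

    def backward(self, dy):
        dx = dy * self._m
        self._m = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x, train=True):
        if train:
            self._m = x > 0
        return np.where(x > 0, x, self.slope * x)

    def backward(self, dy):
        dx = np.where(self._m, dy, self.slope * dy)
        self._m = None
        return dx.astype(F32, copy=False)


class Tanh(Layer):
    def forward(self, x, train=True):
        y = np.tanh(x)
        if train:
            self._y = y
        return y

    def backward(self, dy):
        dx = dy * (1.0 - self._y * self._y)
        self._y = None
        return dx


class Sigmoid(Layer):
    def forward(self, x, train=True):
        y = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._y = y
        return y

    def backward(self, dy):
        dx = dy * self._y * (1.0 - self._y)
        self._y = None
        return dx


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling; backward sum-pools 2x2 blocks."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        if train:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dy):
        n, h, w, c = self._shape
        return np.broadcast_to(dy[:, None, None, :] / (h * w), self._shape).astype(F32)


class Linear(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.normal(0.0, np.sqrt(1.0 / cin), size=(cin, cout)))
        self.b = Param(np.zeros(cout))

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy):
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.value.T
        self._x = None
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for lay in self.layers for p in lay.params()]

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dy):
        for lay in reversed(self.layers):
            dy = lay.backward(dy)
        return dy


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad * p.grad
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def save_params(path, params: list[Param], meta: dict | None = None) -> None:
    """Serialize parameter values (and optional JSON-able metadata)."""
    import json

    arrays = {f"p{i}": p.value for i, p in enumerate(params)}
    if meta is not None:
        arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_params(path, params: list[Param]) -> dict:
    import json

    with np.load(path) as z:
        for i, p in enumerate(params):
            p.value = z[f"p{i}"].astype(F32)
        meta = {}
        if "_meta" in z:
            meta = json.loads(bytes(z["_meta"]).decode())
    return meta
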