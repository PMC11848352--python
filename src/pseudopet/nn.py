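"""Minimal numpy neural-network layers with hand-written backpropagation.

Everything the noise predictor needs: same-padded convolutions (2-D or 3-D
spatial, via im2col matmul), linear layers, SiLU activations, 2x average
pooling / nearest upsampling, and an Adam optimizer.  Layers cache their
forward inputs on the instance, so each layer object belongs to exactly one
position in the network graph (one forward, then one backward).

All parameters and activations are float32; gradients accumulate into
``Param.grad`` and are zeroed by the optimizer after each step.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv",
    "Linear",
    "SiLU",
    "AvgPool",
    "Upsample",
    "Adam",
]


class Param:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def _im2col(x: np.ndarray, k: int, ndim: int) -> np.ndarray:
    """(N, C, *S) -> (N, prod(S), C * k**ndim) patches with same padding."""
    n, c = x.shape[:2]
    spatial = x.shape[2:]
    p = k // 2
    xp = np.pad(x, [(0, 0), (0, 0)] + [(p, p)] * ndim)
    v = np.lib.stride_tricks.sliding_window_view(
        xp, (k,) * ndim, axis=tuple(range(2, 2 + ndim))
    )
    # v: (N, C, *S, *K) -> (N, *S, C, *K) -> flat patches, channel-major
    perm = (0,) + tuple(range(2, 2 + ndim)) + (1,) + tuple(range(2 + ndim, 2 + 2 * ndim))
    cols = v.transpose(perm).reshape(n, int(np.prod(spatial)), c * k**ndim)
    return np.ascontiguousarray(cols)


class Conv:
    """Stride-1, same-padded convolution over 2-D or 3-D spatial grids.

    The weight is stored as a matrix ``(c_out, c_in * k**ndim)`` whose flat
    axis is channel-major then kernel-offset (matching ``_im2col``).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        ndim: int = 2,
        k: int = 3,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ) -> None:
        self.c_in, self.c_out, self.ndim, self.k = c_in, c_out, ndim, k
        fan_in = c_in * k**ndim
        if zero_init:
            w = np.zeros((c_out, fan_in), dtype=np.float32)
        else:
            if rng is None:
                raise ValueError("rng required unless zero_init")
            w = rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
        self.W = Param(w)
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._cols: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        n = x.shape[0]
        spatial = x.shape[2:]
        cols = _im2col(x, self.k, self.ndim)
        self._cols = cols
        self._spatial = spatial
        y = cols @ self.W.value.T + self.b.value  # (N, P, c_out)
        return np.ascontiguousarray(np.moveaxis(y, -1, 1)).reshape(
            n, self.c_out, *spatial
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0]
        spatial = dy.shape[2:]
        dym = np.ascontiguousarray(
            dy.reshape(n, self.c_out, -1).transpose(0, 2, 1), dtype=np.float32
        )  # (N, P, c_out)
        self.W.grad += np.tensordot(dym, self._cols, axes=([0, 1], [0, 1]))
        self.b.grad += dym.sum(axis=(0, 1))
        self._cols = None  # free memory
        # grad wrt input: convolve dy with the flipped, channel-transposed kernel
        wk = self.W.value.reshape(self.c_out, self.c_in, *(self.k,) * self.ndim)
        wf = np.flip(wk, axis=tuple(range(2, 2 + self.ndim)))
        wf = wf.transpose(1, 0, *range(2, 2 + self.ndim))  # (c_in, c_out, *K)
        wfm = np.ascontiguousarray(wf.reshape(self.c_in, self.c_out * self.k**self.ndim))
        cols_dy = _im2col(np.ascontiguousarray(dy, dtype=np.float32), self.k, self.ndim)
        dx = cols_dy @ wfm.T  # (N, P, c_in)
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1)).reshape(
            n, self.c_in, *spatial
        )


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        self.W = Param(rng.standard_normal((d_out, d_in)) * np.sqrt(1.0 / d_in))
        self.b = Param(np.zeros(d_out, dtype=np.float32))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value


class SiLU:
    """x * sigmoid(x); smooth, non-monotone-free activation."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        # numerically stable sigmoid (avoids overflow for large |x|)
        self._s = np.where(
            x >= 0,
            1.0 / (1.0 + np.exp(-np.abs(x))),
            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))),
        ).astype(np.float32)
        return x * self._s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s, x = self._s, self._x
        return dy * (s * (1.0 + x * (1.0 - s)))


class AvgPool:
    """2x average pooling along every spatial axis (requires even sizes)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd = x.ndim - 2
        self._in_shape = x.shape
        shape = [x.shape[0], x.shape[1]]
        for s in x.shape[2:]:
            if s % 2:
                raise ValueError(f"spatial size {s} not divisible by 2")
            shape += [s // 2, 2]
        axes = tuple(3 + 2 * i for i in range(nd))
        return x.reshape(shape).mean(axis=axes)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd = dy.ndim - 2
        out = dy / (2.0**nd)
        for ax in range(2, 2 + nd):
            out = np.repeat(out, 2, axis=ax)
        return out.astype(np.float32, copy=False)


class Upsample:
    """Nearest-neighbour 2x upsampling along every spatial axis."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        nd = x.ndim - 2
        out = x
        for ax in range(2, 2 + nd):
            out = np.repeat(out, 2, axis=ax)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd = dy.ndim - 2
        shape = [dy.shape[0], dy.shape[1]]
        for s in dy.shape[2:]:
            shape += [s // 2, 2]
        axes = tuple(3 + 2 * i for i in range(nd))
        return dy.reshape(shape).sum(axis=axes)


class Adam:
    """Adaptive-moment estimation over a flat list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 2e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            p.grad[...] = 0.0
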