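"""Minimal numpy neural-network primitives with explicit backward passes.

Layout is channels-last ``(B, H, W, C)``.  Every layer caches what its
backward pass needs during ``forward`` and returns the input gradient from
``backward`` while accumulating parameter gradients in-place.  Convolutions
use im2col + matmul; the input gradient of a same-padded stride-1 convolution
is itself a same-padded convolution with the spatially flipped,
channel-transposed kernel.

Correctness of every backward pass is pinned by finite-difference checks in
the test suite.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2x2",
    "Dense",
    "MaxPool2x2",
    "ReLU",
    "Sigmoid",
    "Adam",
    "he_init",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad[...] = 0


def he_init(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


def _conv_same(x: np.ndarray, w: np.ndarray, b: Optional[np.ndarray]):
    """Same-padded stride-1 correlation.  Returns (y, cols_matrix)."""
    k = w.shape[0]
    cin, cout = w.shape[2], w.shape[3]
    bsz, h, wd = x.shape[0], x.shape[1], x.shape[2]
    pad = k // 2
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    # (B, H, W, Cin, k, k) -> (B, H, W, k, k, Cin)
    win = sliding_window_view(x, (k, k), axis=(1, 2))
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        bsz * h * wd, k * k * cin
    )
    y = cols @ w.reshape(k * k * cin, cout)
    if b is not None:
        y += b
    return y.reshape(bsz, h, wd, cout), cols


class Conv2d:
    """Same-padded stride-1 convolution (kernel 1x1 or 3x3)."""

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: int,
        rng: np.random.Generator,
        dtype=np.float32,
        name: str = "conv",
    ) -> None:
        fan_in = kernel * kernel * cin
        self.w = Param(he_init(rng, (kernel, kernel, cin, cout), fan_in, dtype), f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=dtype), f"{name}.b")
        self.kernel = kernel
        self._cols: Optional[np.ndarray] = None
        self._xshape = None

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, cols = _conv_same(x, self.w.value, self.b.value)
        self._cols = cols
        self._xshape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.kernel
        cin, cout = self.w.value.shape[2], self.w.value.shape[3]
        dy_mat = dy.reshape(-1, cout)
        self.w.grad += (self._cols.T @ dy_mat).reshape(self.w.value.shape)
        self.b.grad += dy_mat.sum(axis=0)
        # input gradient: convolve dy with the flipped, channel-transposed kernel
        w_flip = self.w.value[::-1, ::-1].transpose(0, 1, 3, 2)
        dx, _ = _conv_same(dy, np.ascontiguousarray(w_flip), None)
        self._cols = None
        return dx


class Dense:
    """Fully connected layer on (B, Cin) vectors — a 1x1 conv on channel states."""

    def __init__(
        self,
        cin: int,
        cout: int,
        rng: np.random.Generator,
        dtype=np.float32,
        name: str = "dense",
    ) -> None:
        self.w = Param(he_init(rng, (cin, cout), cin, dtype), f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=dtype), f"{name}.b")
        self._x: Optional[np.ndarray] = None

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        dx = dy @ self.w.value.T
        self._x = None
        return dx


class ConvTranspose2x2:
    """2x2 stride-2 transposed convolution: doubles H and W."""

    def __init__(
        self,
        cin: int,
        cout: int,
        rng: np.random.Generator,
        dtype=np.float32,
        name: str = "convT",
    ) -> None:
        self.w = Param(he_init(rng, (2, 2, cin, cout), cin, dtype), f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=dtype), f"{name}.b")
        self._x: Optional[np.ndarray] = None

    def params(self) -> List[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        bsz, h, w, cin = x.shape
        cout = self.w.value.shape[3]
        w_mat = self.w.value.transpose(2, 0, 1, 3).reshape(cin, 4 * cout)
        t = (x.reshape(-1, cin) @ w_mat).reshape(bsz, h, w, 2, 2, cout)
        y = t.transpose(0, 1, 3, 2, 4, 5).reshape(bsz, 2 * h, 2 * w, cout)
        return y + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        bsz, h, w, cin = x.shape
        cout = self.w.value.shape[3]
        t = dy.reshape(bsz, h, 2, w, 2, cout).transpose(0, 1, 3, 2, 4, 5)
        t_mat = np.ascontiguousarray(t).reshape(-1, 4 * cout)
        w_mat = self.w.value.transpose(2, 0, 1, 3).reshape(cin, 4 * cout)
        dx = (t_mat @ w_mat.T).reshape(x.shape)
        dw = x.reshape(-1, cin).T @ t_mat  # (cin, 4*cout)
        self.w.grad += dw.reshape(cin, 2, 2, cout).transpose(1, 2, 0, 3)
        self.b.grad += dy.reshape(-1, cout).sum(axis=0)
        self._x = None
        return dx


class MaxPool2x2:
    """2x2 max pooling, stride 2; gradient routed to the argmax of each window."""

    def __init__(self) -> None:
        self._idx: Optional[np.ndarray] = None
        self._xshape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        bsz, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        win = x.reshape(bsz, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        win = np.ascontiguousarray(win).reshape(bsz, h // 2, w // 2, c, 4)
        self._idx = win.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        bsz, h, w, c = self._xshape
        scat = np.zeros((bsz, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(scat, self._idx[..., None], dy[..., None], axis=-1)
        dx = scat.reshape(bsz, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        self._idx = None
        return np.ascontiguousarray(dx).reshape(bsz, h, w, c)


class ReLU:
    def __init__(self) -> None:
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, 0)
        self._mask = None
        return dx


class Sigmoid:
    def __init__(self) -> None:
        self._y: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._y * (1.0 - self._y)
        self._y = None
        return dx


class Adam:
    """Adam with bias correction; deterministic given the update sequence."""

    def __init__(
        self,
        params: List[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
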