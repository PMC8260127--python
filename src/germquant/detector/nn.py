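"""Minimal numpy neural-network layers with hand-written gradients.

The trainable parts of the detector are small (a 3x3 conv + 1x1 heads for
the proposal stage, two linear layers for the ROI head), so forward and
backward passes are written directly against numpy; parameters carry Adam
moment state.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A weight tensor with gradient and Adam moments."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float):
        self.params = params
        self.lr = lr
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad**2
            mhat = p.m / (1 - b1**self.t)
            vhat = p.v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + eps)


class Linear:
    """y = x @ W + b with cached input for the backward pass."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # Xavier/Glorot uniform initialization
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Param(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Conv3x3:
    """Same-padded 3x3 convolution on (H, W, Cin) maps via im2col.

    ``backward`` optionally propagates the input gradient (col2im); layers
    sitting directly on the frozen feature extractor skip it.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        n_in = 9 * c_in
        limit = np.sqrt(6.0 / (n_in + c_out))
        self.W = Param(rng.uniform(-limit, limit, size=(n_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.c_in = c_in
        self._cols: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    @staticmethod
    def im2col(x: np.ndarray) -> np.ndarray:
        h, w, c = x.shape
        padded = np.pad(x, ((1, 1), (1, 1), (0, 0)))
        cols = np.empty((h * w, 9 * c), dtype=x.dtype)
        k = 0
        for dy in range(3):
            for dx in range(3):
                cols[:, k * c : (k + 1) * c] = padded[dy : dy + h, dx : dx + w, :].reshape(
                    h * w, c
                )
                k += 1
        return cols

    def forward(self, x: np.ndarray) -> np.ndarray:
        h, w, _ = x.shape
        self._shape = (h, w)
        self._cols = self.im2col(x)
        return (self._cols @ self.W.value + self.b.value).reshape(h, w, -1)

    def backward(self, dy: np.ndarray, need_dx: bool = False) -> np.ndarray | None:
        h, w = self._shape
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += self._cols.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        if not need_dx:
            return None
        c = self.c_in
        dxp = np.zeros((h + 2, w + 2, c))
        dcols = dy2 @ self.W.value.T  # (h*w, 9c)
        k = 0
        for dyo in range(3):
            for dxo in range(3):
                dxp[dyo : dyo + h, dxo : dxo + w, :] += dcols[
                    :, k * c : (k + 1) * c
                ].reshape(h, w, c)
                k += 1
        return dxp[1 : h + 1, 1 : w + 1]


def relu(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = x > 0
    return x * mask, mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, targets: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over rows and its gradient w.r.t. the logits.

    ``targets`` are integer class indices. Returns (loss, dlogits) with the
    1/N normalization folded into the gradient. Empty input -> (0, zeros).
    """
    if logits.shape[0] == 0:
        return 0.0, np.zeros_like(logits)
    p = softmax(logits)
    n = logits.shape[0]
    ll = -np.log(np.clip(p[np.arange(n), targets], 1e-12, None))
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(ll.mean()), grad / n


def smooth_l1(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Smooth-L1 (Huber, threshold 1): 0.5 x^2 for |x|<1 else |x| - 0.5.

    Summed over the last axis, averaged over rows. Empty input -> (0, zeros).
    """
    if pred.shape[0] == 0:
        return 0.0, np.zeros_like(pred)
    d = pred - target
    a = np.abs(d)
    quad = a < 1.0
    loss = np.where(quad, 0.5 * d**2, a - 0.5).sum(axis=-1).mean()
    grad = np.where(quad, d, np.sign(d)) / pred.shape[0]
    return float(loss), grad
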