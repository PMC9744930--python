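"""Minimal convolutional-network primitives in numpy.

Implements exactly what the classifier contract needs — 3x3 same-padding
convolution (im2col), ReLU, 2x2 max pooling, global average pooling, a
linear head, softmax cross-entropy, and Adam — with hand-written backward
passes.  Layers cache what their backward pass needs; ``backward`` consumes
the gradient w.r.t. the layer output and returns the gradient w.r.t. the
input while accumulating parameter gradients in ``.grads``.

Shapes follow the (N, C, H, W) convention.
"""

from __future__ import annotations

import numpy as np


def _im2col3(x: np.ndarray) -> np.ndarray:
    """Unfold 3x3 neighborhoods (zero-padded) into (N, C*9, H*W) columns."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c, 9, h, w), dtype=x.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            cols[:, :, k] = xp[:, :, dy:dy + h, dx:dx + w]
            k += 1
    return cols.reshape(n, c * 9, h * w)


def _col2im3(cols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of `_im2col3`: scatter-add columns back onto the image grid."""
    n, c, h, w = shape
    cols = cols.reshape(n, c, 9, h, w)
    xp = np.zeros((n, c, h + 2, w + 2), dtype=cols.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            xp[:, :, dy:dy + h, dx:dx + w] += cols[:, :, k]
            k += 1
    return xp[:, :, 1:1 + h, 1:1 + w]


class Conv3x3:
    """3x3 convolution, stride 1, zero padding 1 (spatial size preserved)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        # kaiming-normal fan-in initialization for ReLU networks
        std = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, std, size=(c_out, c_in, 3, 3))
        self.b = np.zeros(c_out)
        self.grads: dict[str, np.ndarray] = {}
        self._cols: np.ndarray | None = None
        self._in_shape: tuple[int, int, int, int] | None = None

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col3(x)
        wmat = self.W.reshape(self.W.shape[0], -1)
        y = np.einsum("oc,ncp->nop", wmat, cols) + self.b[None, :, None]
        self._cols, self._in_shape = cols, x.shape
        return y.reshape(n, -1, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, co, h, w = dy.shape
        dyf = dy.reshape(n, co, h * w)
        wmat = self.W.reshape(co, -1)
        self.grads["W"] = np.einsum("nop,ncp->oc", dyf, self._cols).reshape(self.W.shape)
        self.grads["b"] = dyf.sum(axis=(0, 2))
        dcols = np.einsum("oc,nop->ncp", wmat, dyf)
        return _col2im3(dcols, self._in_shape)


class ReLU:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped."""

    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, :, : ho * 2, : wo * 2].reshape(n, c, ho, 2, wo, 2)
        patches = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        self._argmax = patches.argmax(axis=-1)
        self._in_shape = x.shape
        return patches.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, ho, wo = dy.shape
        onehot = np.zeros((n, c, ho, wo, 4), dtype=dy.dtype)
        np.put_along_axis(onehot, self._argmax[..., None], 1.0, axis=-1)
        patches = (onehot * dy[..., None]).reshape(n, c, ho, wo, 2, 2)
        dx = np.zeros(self._in_shape, dtype=dy.dtype)
        dx[:, :, : ho * 2, : wo * 2] = patches.transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho * 2, wo * 2)
        return dx


class GlobalAvgPool:
    params: dict = {}
    grads: dict = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(dy[:, :, None, None], self._in_shape) / (h * w)


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / d_in)
        self.W = rng.normal(0.0, std, size=(d_out, d_in))
        self.b = np.zeros(d_out)
        self.grads: dict[str, np.ndarray] = {}

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.W


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy loss and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    loss = float(-np.log(p[np.arange(n), labels] + 1e-12).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    def __init__(self, layers: list, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                mhat = m[k] / (1 - self.b1 ** self.t)
                vhat = v[k] / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
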