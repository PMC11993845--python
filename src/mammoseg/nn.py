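"""Minimal CNN building blocks with explicit backpropagation.

The segmentation network is trained on the CPU with hand-written
forward/backward passes over float32 NHWC tensors. Convolutions are
evaluated as nine shifted-slice GEMMs (equivalent to im2col without
materialising the full column matrix), 2x2 max pooling tracks argmax
indices for an exact gradient, and 2x2-stride-2 transposed convolutions
are four interleaved 1x1 GEMMs. The optimiser is Adam.

These primitives exist because no autodiff/NN backend is part of the
package's dependency set; they are deliberately restricted to what the
U-Net needs (3x3 same-padding conv, ReLU, 2x2 pool, 2x2 up-conv, 1x1
conv, channel concat).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv3x3",
    "Conv1x1",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "UpConv2",
    "SGD",
    "Adam",
    "bce_with_logits",
    "soft_dice_loss",
    "sigmoid",
]

_DTYPE = np.float32


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=_DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv3x3:
    """3x3 convolution, stride 1, zero same-padding.

    Evaluated as nine shifted-slice GEMMs over the padded input — the
    memory-lean equivalent of im2col (no 9x column matrix is ever
    materialised)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = Param(he_init(rng, (3, 3, c_in, c_out), 9 * c_in))
        self.b = Param(np.zeros(c_out))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._xp = xp
        c_out = self.W.value.shape[-1]
        out = np.empty((n, h, w, c_out), dtype=_DTYPE)
        out[...] = self.b.value
        flat = out.reshape(-1, c_out)
        for di in range(3):
            for dj in range(3):
                xs = np.ascontiguousarray(xp[:, di : di + h, dj : dj + w, :]).reshape(-1, c)
                flat += xs @ self.W.value[di, dj]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        assert xp is not None
        n, h, w, c_out = dout.shape
        c = xp.shape[-1]
        dflat = dout.reshape(-1, c_out)
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                xs = np.ascontiguousarray(xp[:, di : di + h, dj : dj + w, :]).reshape(-1, c)
                self.W.grad[di, dj] += xs.T @ dflat
                dxp[:, di : di + h, dj : dj + w, :] += (
                    dflat @ self.W.value[di, dj].T
                ).reshape(n, h, w, c)
        self.b.grad += dout.sum(axis=(0, 1, 2))
        self._xp = None
        return dxp[:, 1:-1, 1:-1, :]


class Conv1x1:
    """1x1 convolution (per-pixel linear map). ``zero_init`` starts the
    layer at an exact zero map — used for the output head so training
    begins from an unbiased probability of one half everywhere."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, zero_init: bool = False):
        w = np.zeros((c_in, c_out)) if zero_init else he_init(rng, (c_in, c_out), c_in)
        self.W = Param(w)
        self.b = Param(np.zeros(c_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, h, w, c = x.shape
        return (x.reshape(-1, c) @ self.W.value + self.b.value).reshape(
            n, h, w, -1
        )

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        n, h, w, c = x.shape
        c_out = dout.shape[-1]
        dflat = dout.reshape(-1, c_out)
        self.W.grad += x.reshape(-1, c).T @ dflat
        self.b.grad += dflat.sum(axis=0)
        self._x = None
        return (dflat @ self.W.value.T).reshape(n, h, w, c)


class BatchNorm:
    """Per-channel batch normalisation over (N, H, W).

    Batch statistics are used during training and tracked as running
    moments for inference. The learned scale starts at one and the shift
    at zero."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)
        self.training = True
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(_DTYPE)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if self.training:
            self._cache = (xhat, inv_std.astype(_DTYPE))
        return (self.gamma.value * xhat + self.beta.value).astype(_DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache  # type: ignore[misc]
        self._cache = None
        m = dout.shape[0] * dout.shape[1] * dout.shape[2]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dout.sum(axis=(0, 1, 2))
        dxhat = dout * self.gamma.value
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).mean(axis=(0, 1, 2))
        ) * inv_std
        return dx.astype(_DTYPE, copy=False)


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(_DTYPE, copy=False)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        mask = self._mask
        self._mask = None
        return np.where(mask, dout, 0.0).astype(_DTYPE, copy=False)


class MaxPool2:
    """2x2 max pooling, stride 2, exact argmax gradient."""

    def __init__(self):
        self._idx: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = (
            x.reshape(n, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // 2, w // 2, c, 4)
        )
        idx = xr.argmax(axis=-1)
        self._idx = idx
        self._shape = x.shape
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape  # type: ignore[misc]
        dxr = np.zeros((n, h // 2, w // 2, c, 4), dtype=_DTYPE)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        self._idx = None
        self._shape = None
        return (
            dxr.reshape(n, h // 2, w // 2, c, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class UpConv2:
    """2x2 transposed convolution, stride 2 (doubles spatial size)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = Param(he_init(rng, (2, 2, c_in, c_out), c_in))
        self.b = Param(np.zeros(c_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        n, h, w, c = x.shape
        c_out = self.W.value.shape[-1]
        out = np.empty((n, 2 * h, 2 * w, c_out), dtype=_DTYPE)
        flat = x.reshape(-1, c)
        for i in range(2):
            for j in range(2):
                out[:, i::2, j::2, :] = (flat @ self.W.value[i, j]).reshape(n, h, w, c_out)
        out += self.b.value
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        n, h, w, c = x.shape
        flat = x.reshape(-1, c)
        dx = np.zeros_like(x)
        for i in range(2):
            for j in range(2):
                ds = np.ascontiguousarray(dout[:, i::2, j::2, :]).reshape(-1, dout.shape[-1])
                self.W.grad[i, j] += flat.T @ ds
                dx += (ds @ self.W.value[i, j].T).reshape(n, h, w, c)
        self.b.grad += dout.sum(axis=(0, 1, 2))
        self._x = None
        return dx


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._v):
            v *= self.momentum
            v += p.grad
            p.value -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class Adam:
    """Adam optimiser over a fixed parameter list."""

    def __init__(
        self,
        params: list[Param],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy summed over the pixels of each image and
    averaged over the batch (the classic fully-convolutional segmentation
    convention, under which quoted learning rates refer to whole-image
    gradients); returns (loss, dL/dz) for z of shape (N, H, W)."""
    y = y.astype(_DTYPE, copy=False)
    n_batch = z.shape[0]
    per_pixel = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = per_pixel.sum() / n_batch
    grad = (sigmoid(z) - y) / n_batch
    return float(loss), grad.astype(_DTYPE, copy=False)


def soft_dice_loss(z: np.ndarray, y: np.ndarray, eps: float = 1.0) -> tuple[float, np.ndarray]:
    """One minus the soft Dice of sigmoid(z) against y over the whole
    batch; returns (loss, dL/dz)."""
    y = y.astype(_DTYPE, copy=False)
    p = sigmoid(z)
    inter = float((p * y).sum())
    denom = float(p.sum() + y.sum()) + eps
    dice = (2.0 * inter + eps) / denom
    # d(1-D)/dp = -(2 y denom - (2 inter + eps)) / denom^2
    dp = -(2.0 * y * denom - (2.0 * inter + eps)) / (denom * denom)
    dz = dp * p * (1.0 - p)
    return float(1.0 - dice), dz.astype(_DTYPE, copy=False)
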