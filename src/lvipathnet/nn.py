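"""Minimal CPU neural-network engine used by both pipeline stages.

Implements exactly the pieces the pipeline needs — 2D convolution (with
dilation, for the atrous context module), ReLU, 2x2 max-pooling, nearest
upsampling, dense layers, and the Adam optimizer — on numpy arrays in
NCHW layout with hand-written backward passes. Weight initialization is
He-normal from an explicit Generator, so training is bit-reproducible for
a fixed seed.

This is deliberately a desk-scale engine: models here have thousands of
parameters, not millions, and are meant to learn synthetic slides on one
CPU in seconds.
"""

from __future__ import annotations

import numpy as np

#: Compute dtype for the whole engine. float32 halves memory traffic and is
#: ample precision for desk-scale models; tests compare against float64
#: oracles at commensurate tolerances.
DTYPE = np.float32

__all__ = [
    "DTYPE",
    "Param",
    "Conv2d",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "GlobalAvgPool",
    "GlobalMaxPool",
    "Dense",
    "Adam",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z)
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """Same-padded k x k convolution with optional dilation, stride 1.

    Forward/backward are computed as a sum over the k*k shifted slices of
    the padded input — no im2col buffer, which keeps memory flat for the
    tile sizes used here.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (in_ch * k * k))
        self.W = Param(rng.normal(0.0, scale, size=(out_ch, in_ch, k, k)))
        self.b = Param(np.zeros(out_ch))
        self.k = k
        self.dilation = dilation
        self._x_padded: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        k, d = self.k, self.dilation
        pad = d * (k - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        self._x_padded = xp
        N, _, H, W = x.shape
        out = np.zeros((N, self.W.value.shape[0], H, W), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                sl = xp[:, :, i * d : i * d + H, j * d : j * d + W]
                out += np.einsum("oc,nchw->nohw", self.W.value[:, :, i, j], sl,
                                 optimize=True)
        return out + self.b.value[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.asarray(dout, dtype=DTYPE)
        k, d = self.k, self.dilation
        pad = d * (k - 1) // 2
        xp = self._x_padded
        N, _, Hp, Wp = xp.shape
        H, W = Hp - 2 * pad, Wp - 2 * pad
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                sl = xp[:, :, i * d : i * d + H, j * d : j * d + W]
                self.W.grad[:, :, i, j] += np.einsum("nohw,nchw->oc", dout, sl,
                                                     optimize=True)
                dxp[:, :, i * d : i * d + H, j * d : j * d + W] += np.einsum(
                    "oc,nohw->nchw", self.W.value[:, :, i, j], dout, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        if pad:
            return dxp[:, :, pad:-pad, pad:-pad]
        return dxp


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class MaxPool2:
    """2x2 max pooling, stride 2. Input H, W must be even; ties go to the
    first maximal element (row-major within the window)."""

    def __init__(self) -> None:
        self._argmax: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        win = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(N, C, H // 2, W // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        dflat = np.zeros((N, C, H // 2, W // 2, 4), dtype=DTYPE)
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        dwin = dflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dwin.reshape(N, C, H, W)


class Upsample2:
    """Nearest-neighbor 2x upsampling."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H2, W2 = dout.shape
        return dout.reshape(N, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool:
    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (H * W), self._shape).copy()


class GlobalMaxPool:
    """Per-channel spatial max — 'is the feature present anywhere' semantics.

    Gradient flows to the (first) maximal location per channel.
    """

    def __init__(self) -> None:
        self._shape: tuple[int, ...] | None = None
        self._argmax: np.ndarray | None = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        flat = x.reshape(N, C, H * W)
        self._argmax = flat.argmax(axis=2)
        self._shape = x.shape
        return np.take_along_axis(flat, self._argmax[..., None], axis=2)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        dflat = np.zeros((N, C, H * W), dtype=DTYPE)
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=2)
        return dflat.reshape(self._shape)


class Dense:
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / in_f), size=(in_f, out_f)))
        self.b = Param(np.zeros(out_f))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = np.asarray(x, dtype=DTYPE)
        return self._x @ self.W.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = np.asarray(dout, dtype=DTYPE)
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Adam:
    """Adam optimizer over a flat list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
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
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad**2
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
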