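"""A small self-contained convolutional-network engine on NumPy.

Provides exactly what the denoising U-Nets need: 2-D/3-D convolutions (im2col
+ BLAS matmul, zero padding, stride 1), ReLU, 2x average pooling, 2x nearest
upsampling, channel concatenation, He-normal initialisation, a voxel-wise MSE
loss and the Adam optimizer — each layer with an explicit hand-written
backward pass. Everything is float32 and deterministic given the
``numpy.random.Generator`` used for initialisation.

The :class:`UNet` assembles an encoder-decoder with skip connections: two
conv+ReLU per resolution level, average pooling between levels (smoothing
fits a denoising task better than max pooling), nearest-neighbour upsampling,
and a linear 1x1(x1) output convolution. Batch normalisation is deliberately
absent. An optional identity shortcut adds the (central) input channel to the
output, so the network refines the noisy image rather than rebuilding it.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np

__all__ = ["Conv", "ReLU", "AvgPool", "Upsample", "Sequential", "UNet", "Adam", "mse_loss"]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Conv:
    """k^nd convolution, zero 'same' padding, He-normal init, optional bias."""

    def __init__(self, cin: int, cout: int, k: int, ndim: int, rng: np.random.Generator):
        self.cin, self.cout, self.k, self.ndim = cin, cout, k, ndim
        fan_in = cin * k**ndim
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(cout, fan_in))
        self.W = Param(w.astype(np.float32))
        self.b = Param(np.zeros(cout, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def _offsets(self):
        return list(itertools.product(range(self.k), repeat=self.ndim))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        p = self.k // 2
        if p:
            pad = [(0, 0), (0, 0)] + [(p, p)] * self.ndim
            xp = np.pad(x, pad)
        else:
            xp = x
        npos = int(np.prod(spatial))
        offs = self._offsets()
        cols = np.empty((n, len(offs) * c, npos), dtype=np.float32)
        for i, off in enumerate(offs):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)
            )
            cols[:, i * c : (i + 1) * c] = xp[sl].reshape(n, c, npos)
        out = np.matmul(self.W.value, cols) + self.b.value[:, None]
        if train:
            self._cache = (cols, x.shape)
        return out.reshape(n, self.cout, *spatial)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c = xshape[:2]
        spatial = xshape[2:]
        npos = int(np.prod(spatial))
        dmat = dout.reshape(n, self.cout, npos)
        self.b.grad += dmat.sum(axis=(0, 2))
        self.W.grad += np.einsum("ncp,nkp->ck", dmat, cols, optimize=True)
        dcols = np.matmul(self.W.value.T, dmat)  # (n, k^nd*c, npos)
        p = self.k // 2
        padded = tuple(s + 2 * p for s in spatial)
        dxp = np.zeros((n, c) + padded, dtype=np.float32)
        for i, off in enumerate(self._offsets()):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)
            )
            dxp[sl] += dcols[:, i * c : (i + 1) * c].reshape(n, c, *spatial)
        if p:
            crop = (slice(None), slice(None)) + tuple(slice(p, p + s) for s in spatial)
            return dxp[crop]
        return dxp


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class AvgPool:
    """2x average pooling over every spatial axis."""

    def __init__(self, ndim: int):
        self.ndim = ndim

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        newshape = [n, c]
        for s in spatial:
            newshape += [s // 2, 2]
        axes = tuple(3 + 2 * i for i in range(self.ndim))
        return x.reshape(newshape).mean(axis=axes)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = dout / (2**self.ndim)
        for ax in range(2, 2 + self.ndim):
            g = np.repeat(g, 2, axis=ax)
        return g


class Upsample:
    """2x nearest-neighbour upsampling over every spatial axis."""

    def __init__(self, ndim: int):
        self.ndim = ndim

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for ax in range(2, 2 + self.ndim):
            x = np.repeat(x, 2, axis=ax)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c = dout.shape[:2]
        spatial = dout.shape[2:]
        newshape = [n, c]
        for s in spatial:
            newshape += [s // 2, 2]
        axes = tuple(3 + 2 * i for i in range(self.ndim))
        return dout.reshape(newshape).sum(axis=axes)


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


def _conv_block(cin: int, cout: int, ndim: int, rng) -> Sequential:
    return Sequential(
        Conv(cin, cout, 3, ndim, rng), ReLU(), Conv(cout, cout, 3, ndim, rng), ReLU()
    )


class UNet:
    """Encoder-decoder with skip connections for image denoising.

    ``depth`` resolution levels with ``base_channels * 2**level`` features;
    spatial input sizes must be divisible by ``2**(depth-1)``. With
    ``residual=True`` the input's central channel is added to the linear
    output.
    """

    def __init__(
        self,
        in_channels: int = 1,
        depth: int = 3,
        base_channels: int = 8,
        ndim: int = 2,
        residual: bool = True,
        seed: int | np.random.Generator = 0,
    ):
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.in_channels = in_channels
        self.depth = depth
        self.base_channels = base_channels
        self.ndim = ndim
        self.residual = residual
        chans = [base_channels * 2**l for l in range(depth)]
        self.enc = []
        cin = in_channels
        for l in range(depth):
            self.enc.append(_conv_block(cin, chans[l], ndim, rng))
            cin = chans[l]
        self.pool = AvgPool(ndim)
        self.up = Upsample(ndim)
        self.dec = []
        for l in reversed(range(depth - 1)):
            self.dec.append(_conv_block(chans[l] + chans[l + 1], chans[l], ndim, rng))
        self.out = Conv(chans[0], 1, 1, ndim, rng)
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        ps = []
        for b in self.enc:
            ps += b.params()
        for b in self.dec:
            ps += b.params()
        ps += self.out.params()
        return ps

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        div = 2 ** (self.depth - 1)
        if any(s % div for s in x.shape[2:]):
            raise ValueError(
                f"spatial shape {x.shape[2:]} not divisible by {div} (depth {self.depth})"
            )
        skips = []
        h = x
        for l in range(self.depth - 1):
            h = self.enc[l].forward(h, train)
            skips.append(h)
            h = self.pool.forward(h, train)
        h = self.enc[-1].forward(h, train)
        for i, l in enumerate(reversed(range(self.depth - 1))):
            h = self.up.forward(h, train)
            h = np.concatenate([skips[l], h], axis=1)
            h = self.dec[i].forward(h, train)
        y = self.out.forward(h, train)
        if self.residual:
            mid = self.in_channels // 2
            y = y + x[:, mid : mid + 1]
        if train:
            self._cache = x.shape
        return y

    def backward(self, dy: np.ndarray) -> None:
        chans = [self.base_channels * 2**l for l in range(self.depth)]
        dh = self.out.backward(dy)
        dskips = [None] * (self.depth - 1)
        # decoder blocks unwind in reverse: dec[i] ran at level l = depth-2-i
        for l in range(self.depth - 1):
            i = self.depth - 2 - l
            dh = self.dec[i].backward(dh)
            dskips[l] = dh[:, : chans[l]]
            dh = self.up.backward(dh[:, chans[l] :])
        dh = self.enc[-1].backward(dh)
        for l in reversed(range(self.depth - 1)):
            dh = self.pool.backward(dh)
            dh = dh + dskips[l]
            dh = self.enc[l].backward(dh)
        # input gradient unused (the residual shortcut would add dy at the
        # central channel); training only needs parameter gradients

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Voxel-wise MSE and its gradient with respect to the prediction."""
    diff = (pred - target).astype(np.float32)
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    return loss, (2.0 / diff.size) * diff


class Adam:
    """Adaptive-moment first-order optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-3):
        self.params = list(params)
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + eps)
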