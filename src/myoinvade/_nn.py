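"""Minimal numpy CNN kernel: layers with explicit backprop, U-Net builder.

This exists because the deployment environment provides no deep-learning
framework; the networks here are deliberately desk-scale (a few hundred
thousand parameters, 128x128 inputs) and every layer implements its own
backward pass. Arrays are NCHW float32. All randomness flows through a
caller-supplied ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "Conv1x1", "ReLU", "MaxPool2", "Upsample2", "Sigmoid",
           "ConvBlock", "UNet", "SGD"]


class Layer:
    """Base: forward caches what backward needs; params yields (w, grad)."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self):
        return []


class Conv2d(Layer):
    """3x3 same-padding stride-1 convolution (cross-correlation)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * 9
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, 3, 3)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._windows: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # N,C,H,W,3,3
        self._windows = win
        y = np.tensordot(win, self.w, axes=([1, 4, 5], [1, 2, 3]))
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2)) + self.b[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        win = self._windows
        self.gw += np.tensordot(gy, win, axes=([0, 2, 3], [0, 2, 3]))
        self.gb += gy.sum(axis=(0, 2, 3))
        gyp = np.pad(gy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        gwin = sliding_window_view(gyp, (3, 3), axis=(2, 3))  # N,Cout,H,W,3,3
        w_flip = self.w[:, :, ::-1, ::-1]
        gx = np.tensordot(gwin, w_flip, axes=([1, 4, 5], [0, 2, 3]))
        self._windows = None
        return np.ascontiguousarray(gx.transpose(0, 3, 1, 2))

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class Conv1x1(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / c_in),
                            size=(c_out, c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("nchw,oc->nohw", x, self.w) + self.b[None, :, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.gw += np.einsum("nohw,nchw->oc", gy, self._x)
        self.gb += gy.sum(axis=(0, 2, 3))
        gx = np.einsum("nohw,oc->nchw", gy, self.w)
        self._x = None
        return gx

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = np.where(self._mask, gy, 0.0)
        self._mask = None
        return gx


class MaxPool2(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        # ties share the gradient equally (rare with float activations)
        mask = xr == y[:, :, :, None, :, None]
        self._mask = mask / np.maximum(mask.sum(axis=(3, 5), keepdims=True), 1)
        self._shape = x.shape
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = self._mask * gy[:, :, :, None, :, None]
        self._mask = None
        return gx.reshape(self._shape)


class Upsample2(Layer):
    """Nearest-neighbor x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c, h, w = gy.shape
        return gy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sigmoid(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._y * (1.0 - self._y)
        self._y = None
        return gx


class ConvBlock(Layer):
    """n_convs x (Conv3x3 -> ReLU), optionally with a residual connection.

    The residual form (identity, or 1x1 projection on channel change) is
    what makes the ``resnet34-like`` encoder family a genuine residual
    network rather than a renamed VGG stack.
    """

    def __init__(self, c_in: int, c_out: int, n_convs: int,
                 rng: np.random.Generator, residual: bool = False):
        self.layers: list[Layer] = []
        c = c_in
        for _ in range(n_convs):
            self.layers.append(Conv2d(c, c_out, rng))
            self.layers.append(ReLU())
            c = c_out
        self.residual = residual
        self.proj = Conv1x1(c_in, c_out, rng) if residual and c_in != c_out else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x
        for layer in self.layers:
            y = layer.forward(y)
        if self.residual:
            self._x_in = x
            shortcut = self.proj.forward(x) if self.proj is not None else x
            y = y + shortcut
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        if self.residual:
            g_short = self.proj.backward(gy) if self.proj is not None else gy
        gx = gy
        for layer in reversed(self.layers):
            gx = layer.backward(gx)
        if self.residual:
            gx = gx + g_short
            self._x_in = None
        return gx

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        if self.proj is not None:
            out.extend(self.proj.params())
        return out


class UNet:
    """Symmetric encoder-decoder with skip connections.

    ``enc_channels`` gives the channel width at each encoder stage; the
    bottleneck doubles the deepest width; each decoder stage upsamples,
    concatenates the opposing encoder feature map, and convolves back down.
    The head is a 1x1 convolution with per-structure sigmoids.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 enc_channels: tuple[int, ...], n_convs: int,
                 rng: np.random.Generator, residual: bool = False):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.enc_channels = tuple(enc_channels)
        self.enc_blocks: list[ConvBlock] = []
        self.pools: list[MaxPool2] = []
        c = in_channels
        for ch in enc_channels:
            self.enc_blocks.append(ConvBlock(c, ch, n_convs, rng, residual))
            self.pools.append(MaxPool2())
            c = ch
        self.bottleneck = ConvBlock(c, 2 * c, n_convs, rng, residual)
        self.ups: list[Upsample2] = []
        self.dec_blocks: list[ConvBlock] = []
        c = 2 * enc_channels[-1]
        for ch in reversed(enc_channels):
            self.ups.append(Upsample2())
            self.dec_blocks.append(ConvBlock(c + ch, ch, n_convs, rng, residual))
            c = ch
        self.head = Conv1x1(c, out_channels, rng)
        self.out_act = Sigmoid()

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_channels = [s.shape[1] for s in skips]
        for up, dec, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            x = up.forward(x)
            x = np.concatenate([x, skip], axis=1)
            x = dec.forward(x)
        x = self.head.forward(x)
        return self.out_act.forward(x)

    def backward(self, gy: np.ndarray) -> None:
        g = self.out_act.backward(gy)
        g = self.head.backward(g)
        skip_grads = []
        for up, dec, ch in zip(reversed(self.ups), reversed(self.dec_blocks),
                               self._skip_channels):
            g = dec.backward(g)
            g, g_skip = g[:, :-ch], g[:, -ch:]
            skip_grads.append(g_skip)
            g = up.backward(g)
        g = self.bottleneck.backward(g)
        # skip_grads is ordered shallow -> deep; encoder backward runs deep first
        for block, pool, g_skip in zip(reversed(self.enc_blocks),
                                       reversed(self.pools),
                                       reversed(skip_grads)):
            g = pool.backward(g) + g_skip
            g = block.backward(g)

    def params(self):
        out = []
        for block in self.enc_blocks:
            out.extend(block.params())
        out.extend(self.bottleneck.params())
        for dec in self.dec_blocks:
            out.extend(dec.params())
        out.extend(self.head.params())
        return out

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return int(sum(w.size for w, _ in self.params()))

    def state(self) -> list[np.ndarray]:
        return [w.copy() for w, _ in self.params()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for (w, _), saved in zip(self.params(), state):
            w[...] = saved


class SGD:
    """Stochastic gradient descent with classical momentum.

    Gradients are rescaled when their global norm exceeds ``clip_norm``:
    the soft-Dice loss produces occasional large spikes that can slam a
    whole output channel into saturation (the empty-prediction attractor),
    and clipping removes that failure mode without touching the loss.
    """

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 clip_norm: float | None = 1.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.velocity = [np.zeros_like(w) for w, _ in self.params]

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g ** 2).sum()) for _, g in self.params))
            if total > self.clip_norm:
                scale = self.clip_norm / total
        for (w, g), v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * scale * g
            w += v
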