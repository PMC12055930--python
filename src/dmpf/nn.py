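"""A small 3-D encoder-decoder segmentation network in pure numpy.

The network follows the V-Net topology — per-level convolution blocks, 2x
max-pool downsampling, nearest-neighbour upsampling with additive skip
connections, and a 1x1x1 K-way voxel classifier head — with configurable
depth and channel widths.  Forward and backward passes are written
explicitly (im2col convolutions); an SGD-with-momentum optimizer with
polynomial learning-rate decay accompanies it.  Output spatial shape always
equals input shape; spatial dims must be divisible by ``2**(levels-1)``.

Weights are initialised with the Kaiming normal scheme.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Conv3d", "ReLU", "MaxPool2x", "Upsample2x", "VNetLite", "SGD"]


DTYPE = np.float32


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, D, H, W) -> (B*D*H*W, C*k^3) with zero same-padding."""
    b, c, d, h, w = x.shape
    pad = k // 2
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    return np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
                                ).reshape(b * d * h * w, c * k ** 3)


class Conv3d:
    """Same-padding 3-D convolution via im2col.

    The input gradient is computed as a convolution of the output gradient
    with the spatially flipped, transposed kernel, reusing the same im2col
    matmul path (valid for same zero-padding).
    """

    def __init__(self, c_in: int, c_out: int, ksize: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, ksize
        fan_in = c_in * ksize ** 3
        std = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=(c_out, fan_in)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        b, c, d, h, w = x.shape
        assert c == self.c_in, (c, self.c_in)
        col = _im2col(x, self.k)
        out = col @ self.W.T + self.b
        self._cache = (col, (b, c, d, h, w))
        return out.reshape(b, d, h, w, self.c_out).transpose(0, 4, 1, 2, 3)

    def _w_flipped(self) -> np.ndarray:
        """(C_out*k^3, C_in) matrix implementing the transposed convolution."""
        k = self.k
        wk = self.W.reshape(self.c_out, self.c_in, k, k, k)
        wk = wk[:, :, ::-1, ::-1, ::-1]                       # spatial flip
        return np.ascontiguousarray(wk.transpose(0, 2, 3, 4, 1)
                                    ).reshape(self.c_out * k ** 3, self.c_in)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        col, (b, c, d, h, w) = self._cache
        gout = np.ascontiguousarray(gout, dtype=DTYPE)
        gmat = np.ascontiguousarray(gout.transpose(0, 2, 3, 4, 1)
                                    ).reshape(-1, self.c_out)
        self.gW += gmat.T @ col
        self.gb += gmat.sum(axis=0)
        gcol = _im2col(gout, self.k)                 # (B*V, C_out*k^3)
        gin = gcol @ self._w_flipped()               # (B*V, C_in)
        return gin.reshape(b, d, h, w, c).transpose(0, 4, 1, 2, 3)

    @property
    def params(self):
        return [("W", self), ("b", self)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class MaxPool2x:
    """2x2x2 max pooling with argmax routing for the backward pass."""

    def forward(self, x):
        b, c, d, h, w = x.shape
        assert d % 2 == 0 and h % 2 == 0 and w % 2 == 0, "pooling needs even dims"
        blocks = x.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
        flat = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(b, c, d // 2, h // 2, w // 2, 8)
        self._idx = flat.argmax(axis=-1)
        self._shape = (b, c, d, h, w)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g):
        b, c, d, h, w = self._shape
        gflat = np.zeros((b, c, d // 2, h // 2, w // 2, 8), dtype=g.dtype)
        np.put_along_axis(gflat, self._idx[..., None], g[..., None], axis=-1)
        gblocks = gflat.reshape(b, c, d // 2, h // 2, w // 2, 2, 2, 2)
        return gblocks.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(b, c, d, h, w)


class Upsample2x:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, g):
        b, c, d, h, w = g.shape
        return g.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(3, 5, 7))


class _Block:
    """conv-relu-conv-relu."""

    def __init__(self, c_in, c_out, ksize, rng):
        self.layers = [Conv3d(c_in, c_out, ksize, rng), ReLU(),
                       Conv3d(c_out, c_out, ksize, rng), ReLU()]

    def forward(self, x):
        for lyr in self.layers:
            x = lyr.forward(x)
        return x

    def backward(self, g):
        for lyr in reversed(self.layers):
            g = lyr.backward(g)
        return g

    def convs(self):
        return [l for l in self.layers if isinstance(l, Conv3d)]


class VNetLite:
    """Encoder-decoder with additive skips and a K-way 1x1x1 head."""

    def __init__(self, in_channels: int, num_classes: int,
                 channels: Sequence[int] = (8, 16, 32), ksize: int = 3,
                 rng: Optional[np.random.Generator] = None, seed: Optional[int] = None):
        if rng is None:
            rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.num_classes = num_classes
        self.in_channels = in_channels
        levels = len(self.channels)
        self.enc: List[_Block] = []
        prev = in_channels
        for c in self.channels:
            self.enc.append(_Block(prev, c, ksize, rng))
            prev = c
        self.pools = [MaxPool2x() for _ in range(levels - 1)]
        self.ups = [Upsample2x() for _ in range(levels - 1)]
        self.upconvs = [Conv3d(self.channels[i + 1], self.channels[i], 1, rng)
                        for i in reversed(range(levels - 1))]
        self.dec = [_Block(self.channels[i], self.channels[i], ksize, rng)
                    for i in reversed(range(levels - 1))]
        self.head = Conv3d(self.channels[0], num_classes, 1, rng)
        self._skips = None

    # -- parameter plumbing -------------------------------------------------
    def _convs(self) -> List[Conv3d]:
        convs = []
        for blk in self.enc:
            convs.extend(blk.convs())
        convs.extend(self.upconvs)
        for blk in self.dec:
            convs.extend(blk.convs())
        convs.append(self.head)
        return convs

    def parameters(self) -> List[np.ndarray]:
        out = []
        for cv in self._convs():
            out.extend([cv.W, cv.b])
        return out

    def gradients(self) -> List[np.ndarray]:
        out = []
        for cv in self._convs():
            out.extend([cv.gW, cv.gb])
        return out

    def set_parameters(self, values: Sequence[np.ndarray]) -> None:
        convs = self._convs()
        if len(values) != 2 * len(convs):
            raise ValueError("parameter count mismatch: architectures differ")
        it = iter(values)
        for cv in convs:
            w, b = next(it), next(it)
            if w.shape != cv.W.shape or b.shape != cv.b.shape:
                raise ValueError("parameter shape mismatch: architectures differ")
            cv.W = w.astype(DTYPE)
            cv.b = b.astype(DTYPE)
            cv.gW = np.zeros_like(cv.W)
            cv.gb = np.zeros_like(cv.b)

    def zero_grad(self) -> None:
        for cv in self._convs():
            cv.gW[...] = 0.0
            cv.gb[...] = 0.0

    def clone(self) -> "VNetLite":
        twin = VNetLite(self.in_channels, self.num_classes, self.channels,
                        ksize=self.enc[0].convs()[0].k, seed=0)
        twin.set_parameters([p.copy() for p in self.parameters()])
        return twin

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        div = 2 ** (len(self.channels) - 1)
        if any(s % div for s in x.shape[2:]):
            raise ValueError(f"spatial dims must be divisible by {div}")
        skips = []
        h = x
        for i, blk in enumerate(self.enc):
            h = blk.forward(h)
            if i < len(self.enc) - 1:
                skips.append(h)
                h = self.pools[i].forward(h)
        for j in range(len(self.dec)):
            i = len(self.channels) - 2 - j
            h = self.ups[j].forward(h)
            h = self.upconvs[j].forward(h)
            h = h + skips[i]
            h = self.dec[j].forward(h)
        self._skip_count = len(skips)
        return self.head.forward(h)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        levels = len(self.channels)
        g = self.head.backward(gout)
        skip_grads = [None] * (levels - 1)
        for j in reversed(range(len(self.dec))):
            i = levels - 2 - j
            g = self.dec[j].backward(g)
            skip_grads[i] = g.copy()          # addition node fans out
            g = self.upconvs[j].backward(g)
            g = self.ups[j].backward(g)
        g = self.enc[-1].backward(g)
        for i in reversed(range(levels - 1)):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)
        return g

    def predict_logits(self, x: np.ndarray) -> np.ndarray:
        """Forward pass without touching gradient state semantics (the
        network is stateless apart from caches, so this is just forward)."""
        return self.forward(x)


class SGD:
    """SGD with momentum and polynomial learning-rate decay
    ``lr_t = lr0 * (1 - t/t_max)^power``."""

    def __init__(self, net: VNetLite, lr: float = 0.03, momentum: float = 0.9,
                 power: float = 0.9, t_max: int = 10000):
        self.net = net
        self.lr0 = lr
        self.momentum = momentum
        self.power = power
        self.t_max = t_max
        self.t = 0
        self.velocity = [np.zeros_like(p) for p in net.parameters()]

    def current_lr(self) -> float:
        frac = min(self.t / self.t_max, 1.0) if self.t_max > 0 else 0.0
        return self.lr0 * (1.0 - frac) ** self.power

    def step(self) -> None:
        lr = self.current_lr()
        params = self.net.parameters()
        grads = self.net.gradients()
        for p, g, v in zip(params, grads, self.velocity):
            v *= self.momentum
            v -= lr * g
            p += v
        self.t += 1
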