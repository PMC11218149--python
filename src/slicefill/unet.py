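"""A compact 2D U-Net written directly on numpy.

Encoder of repeated (conv3x3 -> [norm] -> ReLU) x2 blocks with 2x2
max-pooling, a mirrored decoder with nearest-neighbour up-sampling and
skip-connection concatenation, and a final 1x1 convolution to per-pixel
class scores.  Forward and backward passes are explicit (im2col
convolutions, hand-derived gradients), which keeps the whole training
stack dependency-free, deterministic under a seed, and fast enough on a
CPU for the per-volume overfit regime this package implements.

The loss couples per-pixel cross-entropy (stabilises early epochs) with a
soft-Dice term over the foreground classes (aligns training with the
evaluation metric); Adam is the optimiser.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet2D", "Adam", "softmax", "segmentation_loss"]


# ---------------------------------------------------------------- primitives

def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N, C*9, H*W) patches of the 3x3 neighbourhood."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, c, 9, h, w), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, k] = xp[:, :, di:di + h, dj:dj + w]
            k += 1
    return cols.reshape(n, c * 9, h * w)


def _col2im3(dcols: np.ndarray, shape) -> np.ndarray:
    """Adjoint of :func:`_im2col3`."""
    n, c, h, w = shape
    d = dcols.reshape(n, c, 9, h, w)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di:di + h, dj:dj + w] += d[:, :, k]
            k += 1
    return dxp[:, :, 1:-1, 1:-1]


class Conv3x3:
    """3x3 convolution, stride 1, same padding; He-initialised."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.w = (rng.standard_normal((c_out, c_in * 9)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col3(x)
        out = np.matmul(self.w, cols) + self.b[:, None]
        self._cache = (cols, x.shape)
        return out.reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, co, h, w = dout.shape
        do = dout.reshape(n, co, h * w)
        self.dw = np.einsum("nop,ncp->oc", do, cols).astype(np.float32)
        self.db = do.sum(axis=(0, 2)).astype(np.float32)
        dcols = np.matmul(self.w.T, do)
        return _col2im3(dcols, xshape)

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.dw, self.db]


class Conv1x1:
    """1x1 convolution (the classification head)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_out, c_in)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("oc,nchw->nohw", self.w, x) + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dw = np.einsum("nohw,nchw->oc", dout, self._x).astype(np.float32)
        self.db = dout.sum(axis=(0, 2, 3)).astype(np.float32)
        return np.einsum("oc,nohw->nchw", self.w, dout)

    def params(self):
        return [("w", self.w), ("b", self.b)]

    def grads(self):
        return [self.dw, self.db]


class InstanceNorm:
    """Per-sample, per-channel normalisation with learnable scale/shift."""

    eps = 1e-5

    def __init__(self, channels: int):
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3)).astype(np.float32)
        self.dbeta = dout.sum(axis=(0, 2, 3)).astype(np.float32)
        g = dout * self.gamma[None, :, None, None]
        m = xhat.shape[2] * xhat.shape[3]
        return (g - g.mean(axis=(2, 3), keepdims=True)
                - xhat * (g * xhat).mean(axis=(2, 3), keepdims=True)) * inv

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def grads(self):
        return [self.dgamma, self.dbeta]


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []

    def grads(self):
        return []


def maxpool2(x: np.ndarray):
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    return xr.max(axis=-1), (idx, x.shape)


def maxpool2_backward(dout: np.ndarray, cache) -> np.ndarray:
    idx, (n, c, h, w) = cache
    d4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(d4, idx[..., None], dout[..., None], axis=-1)
    d4 = d4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return d4.reshape(n, c, h, w)


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ConvBlock:
    """(conv3x3 -> [norm] -> ReLU) x 2."""

    def __init__(self, c_in: int, c_out: int, rng, normalization: bool):
        self.layers = []
        for cin in (c_in, c_out):
            self.layers.append(Conv3x3(cin, c_out, rng))
            if normalization:
                self.layers.append(InstanceNorm(c_out))
            self.layers.append(ReLU())

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]


# --------------------------------------------------------------------- U-Net

class UNet2D:
    """Encoder/decoder segmentation network with skip connections.

    Parameters
    ----------
    depth : int
        Number of max-pooling (down-sampling) stages.
    base_channels : int
        Channels of the first encoder block; doubled at every stage.
    in_channels, n_classes : int
        Input image channels and output classes.
    normalization : bool
        Insert instance normalisation after each convolution.
    seed : int
        Weight-initialisation seed; two builds from the same spec and seed
        have identical initial weights.
    """

    def __init__(self, depth: int = 3, base_channels: int = 16, in_channels: int = 1,
                 n_classes: int = 3, normalization: bool = True, seed: int = 0):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        self.depth = depth
        self.base_channels = base_channels
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.normalization = normalization
        rng = np.random.default_rng(seed)

        ch = [base_channels * 2 ** i for i in range(depth + 1)]
        self.enc = []
        c_prev = in_channels
        for i in range(depth):
            self.enc.append(ConvBlock(c_prev, ch[i], rng, normalization))
            c_prev = ch[i]
        self.bottleneck = ConvBlock(c_prev, ch[depth], rng, normalization)
        self.up = []       # channel-halving conv after upsampling
        self.dec = []
        for i in reversed(range(depth)):
            self.up.append(Conv3x3(ch[i + 1], ch[i], rng))
            self.dec.append(ConvBlock(2 * ch[i], ch[i], rng, normalization))
        self.head = Conv1x1(ch[0], n_classes, rng)

    # -- padding so any H, W works regardless of depth
    def _pad(self, x: np.ndarray):
        m = 2 ** self.depth
        h, w = x.shape[2], x.shape[3]
        ph = (-h) % m
        pw = (-w) % m
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
        return x, (h, w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class scores, same spatial shape as the input."""
        x = np.asarray(x, dtype=np.float32)
        x, (h0, w0) = self._pad(x)
        skips = []
        pools = []
        for block in self.enc:
            x = block.forward(x)
            skips.append(x)
            x, cache = maxpool2(x)
            pools.append(cache)
        x = self.bottleneck.forward(x)
        self._skip_channels = []
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            x = up.forward(upsample2(x))
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = dec.forward(x)
        scores = self.head.forward(x)
        self._pools = pools
        self._orig_hw = (h0, w0)
        self._padded_hw = scores.shape[2:]
        return scores[:, :, :h0, :w0]

    def backward(self, dscores: np.ndarray) -> None:
        """Accumulate parameter gradients from the loss gradient on scores."""
        ph, pw = self._padded_hw
        h0, w0 = self._orig_hw
        if (ph, pw) != (h0, w0):
            d = np.zeros(dscores.shape[:2] + (ph, pw), dtype=np.float32)
            d[:, :, :h0, :w0] = dscores
            dscores = d
        dx = self.head.backward(dscores)
        # decoder stage i consumed the skip of encoder level depth-1-i
        dskip_by_level: dict[int, np.ndarray] = {}
        for i in reversed(range(self.depth)):
            dx = self.dec[i].backward(dx)
            c_skip = self._skip_channels[i]
            dskip_by_level[self.depth - 1 - i] = dx[:, :c_skip]
            dx = upsample2_backward(self.up[i].backward(dx[:, c_skip:]))
        dx = self.bottleneck.backward(dx)
        for level in reversed(range(self.depth)):
            dx = maxpool2_backward(dx, self._pools[level])
            dx = dx + dskip_by_level[level]
            dx = self.enc[level].backward(dx)

    def modules(self):
        mods = list(self.enc) + [self.bottleneck] + list(self.up) + list(self.dec) + [self.head]
        return mods

    def parameters(self) -> list[np.ndarray]:
        return [arr for m in self.modules() for _, arr in m.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for m in self.modules() for g in m.grads()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise ValueError("weight list does not match architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape {w.shape} != parameter shape {p.shape}")
            p[...] = w

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class labels for a batch of images."""
        return np.argmax(self.forward(x), axis=1).astype(np.int16)


# ---------------------------------------------------------------- optimiser

class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# --------------------------------------------------------------------- loss

def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def segmentation_loss(scores: np.ndarray, targets: np.ndarray,
                      loss: str = "ce+dice") -> tuple[float, np.ndarray]:
    """Loss value and gradient w.r.t. the raw scores.

    ``targets`` is (N, H, W) integer labels.  ``loss`` is one of
    ``"ce"``, ``"dice"`` or ``"ce+dice"`` (cross-entropy plus one minus
    the mean foreground soft-Dice).
    """
    n, k, h, w = scores.shape
    p = softmax(scores.astype(np.float64))
    onehot = np.zeros_like(p)
    idx0, idx2, idx3 = np.ogrid[:n, :h, :w]
    onehot[idx0, targets, idx2, idx3] = 1.0

    npix = n * h * w
    total = 0.0
    dp = np.zeros_like(p)

    if "ce" in loss:
        total += float(-(onehot * np.log(np.maximum(p, 1e-12))).sum() / npix)
        dp += -onehot / np.maximum(p, 1e-12) / npix

    if "dice" in loss:
        eps = 1e-6
        fg = range(1, k)
        dices = []
        for c in fg:
            pc, yc = p[:, c], onehot[:, c]
            num = 2.0 * (pc * yc).sum()
            den = pc.sum() + yc.sum() + eps
            dices.append(num / den)
            # d(1 - dice)/dpc = -(2*yc*den - num) / den^2
            dp[:, c] += -(2.0 * yc * den - num) / den**2 / len(list(fg))
        total += float(1.0 - np.mean(dices))

    # chain rule through softmax: dz = p * (dp - sum_c dp_c p_c)
    dz = p * (dp - (dp * p).sum(axis=1, keepdims=True))
    return total, dz.astype(np.float32)
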