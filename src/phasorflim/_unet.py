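"""Compact encoder-decoder pixel classifier in pure numpy.

A scaled-down U-Net-style network: ``depth`` 2x2 max-pool stages, two 3x3
convolutions per level, nearest-neighbour upsampling with skip
concatenation, and a 1x1 two-class head with a softmax output.  Convolutions
run as im2col + matmul; gradients are hand-derived; optimization is Adam on
a class-weighted cross-entropy.  Everything is deterministic for a fixed
seed and thread count.
"""
from __future__ import annotations

import hashlib

import numpy as np


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, C*9, H*W) for a 3x3 same-padded convolution."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((b, c, 9, h, w), dtype=x.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[:, :, k] = xp[:, :, di:di + h, dj:dj + w]
            k += 1
    return cols.reshape(b, c * 9, h * w)


def _col2im(cols: np.ndarray, c: int, h: int, w: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add columns back to (B, C, H, W)."""
    b = cols.shape[0]
    cols = cols.reshape(b, c, 9, h, w)
    xp = np.zeros((b, c, h + 2, w + 2), dtype=cols.dtype)
    k = 0
    for di in range(3):
        for dj in range(3):
            xp[:, :, di:di + h, dj:dj + w] += cols[:, :, k]
            k += 1
    return xp[:, :, 1:1 + h, 1:1 + w]


class _Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * 9))
        self.b = np.zeros(c_out)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        self._cols = _im2col(x)
        self._shape = (b, c, h, w)
        out = np.einsum("oc,bcp->bop", self.W, self._cols,
                        optimize=True) + self.b[None, :, None]
        return out.reshape(b, self.c_out, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        g = grad.reshape(b, self.c_out, h * w)
        self.dW = np.einsum("bop,bcp->oc", g, self._cols, optimize=True)
        self.db = g.sum(axis=(0, 2))
        dcols = np.einsum("oc,bop->bcp", self.W, g, optimize=True)
        return _col2im(dcols, c, h, w)

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_out, c_in))
        self.b = np.zeros(c_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return np.einsum("oc,bchw->bohw", self.W, x,
                         optimize=True) + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dW = np.einsum("bohw,bchw->oc", grad, self._x, optimize=True)
        self.db = grad.sum(axis=(0, 2, 3))
        return np.einsum("oc,bohw->bchw", self.W, grad, optimize=True)

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


def _relu_forward(x):
    return np.maximum(x, 0.0), x > 0


def _maxpool_forward(x):
    b, c, h, w = x.shape
    xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(b, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, (idx, (b, c, h, w))


def _maxpool_backward(grad, cache):
    idx, (b, c, h, w) = cache
    gr = np.zeros((b, c, h // 2, w // 2, 4), dtype=grad.dtype)
    np.put_along_axis(gr, idx[..., None], grad[..., None], axis=-1)
    gr = gr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return gr.reshape(b, c, h, w)


def _upsample_forward(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def _upsample_backward(grad):
    b, c, h, w = grad.shape
    return grad.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UNet:
    """Two-class pixel classifier with ``depth`` pooling stages."""

    def __init__(self, in_channels: int = 4, base_channels: int = 8,
                 depth: int = 2, seed: int = 0):
        self.in_channels = in_channels
        self.base_channels = base_channels
        self.depth = depth
        rng = np.random.default_rng(seed)
        self.enc: list[tuple[_Conv3x3, _Conv3x3]] = []
        c_prev = in_channels
        for d in range(depth):
            c = base_channels * 2 ** d
            self.enc.append((_Conv3x3(c_prev, c, rng), _Conv3x3(c, c, rng)))
            c_prev = c
        c_bot = base_channels * 2 ** depth
        self.bot = (_Conv3x3(c_prev, c_bot, rng), _Conv3x3(c_bot, c_bot, rng))
        self.dec: list[tuple[_Conv3x3, _Conv3x3]] = []
        c_up = c_bot
        for d in reversed(range(depth)):
            c_skip = base_channels * 2 ** d
            self.dec.append((_Conv3x3(c_up + c_skip, c_skip, rng),
                             _Conv3x3(c_skip, c_skip, rng)))
            c_up = c_skip
        self.head = _Conv1x1(c_up, 2, rng)

    # ---- plumbing -------------------------------------------------------
    def _layers(self):
        for pair in self.enc:
            yield from pair
        yield from self.bot
        for pair in self.dec:
            yield from pair
        yield self.head

    def n_parameters(self) -> int:
        return sum(arr.size for lay in self._layers()
                   for _, arr, _ in lay.params())

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for lay in self._layers():
            for _, arr, _ in lay.params():
                h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
        return h.hexdigest()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}_{name}": arr for i, lay in enumerate(self._layers())
                for name, arr, _ in lay.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, lay in enumerate(self._layers()):
            for name, arr, _ in lay.params():
                arr[...] = state[f"p{i}_{name}"]

    # ---- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._cache: list = []
        skips = []
        h = x
        for conv_a, conv_b in self.enc:
            h, m1 = _relu_forward(conv_a.forward(h))
            h, m2 = _relu_forward(conv_b.forward(h))
            skips.append(h)
            h, pc = _maxpool_forward(h)
            self._cache.append((m1, m2, pc))
        h, mb1 = _relu_forward(self.bot[0].forward(h))
        h, mb2 = _relu_forward(self.bot[1].forward(h))
        self._bot_cache = (mb1, mb2)
        self._dec_cache = []
        for (conv_a, conv_b), skip in zip(self.dec, reversed(skips)):
            h = _upsample_forward(h)
            c_up = h.shape[1]
            h = np.concatenate([h, skip], axis=1)
            h, m1 = _relu_forward(conv_a.forward(h))
            h, m2 = _relu_forward(conv_b.forward(h))
            self._dec_cache.append((m1, m2, c_up))
        return self.head.forward(h)

    def backward(self, grad: np.ndarray) -> None:
        g = self.head.backward(grad)
        # skip_grads[k] is the gradient at the skip input of encoder level k
        # (the last decoder block consumes the shallowest skip)
        skip_grads = []
        for (conv_a, conv_b), (m1, m2, c_up) in zip(reversed(self.dec),
                                                    reversed(self._dec_cache)):
            g = conv_a.backward(conv_b.backward(g * m2) * m1)
            skip_grads.append(g[:, c_up:])
            g = _upsample_backward(g[:, :c_up])
        mb1, mb2 = self._bot_cache
        g = self.bot[0].backward(self.bot[1].backward(g * mb2) * mb1)
        for (conv_a, conv_b), (m1, m2, pc), sg in zip(
                reversed(self.enc), reversed(self._cache), reversed(skip_grads)):
            g = _maxpool_backward(g, pc) + sg
            g = conv_a.backward(conv_b.backward(g * m2) * m1)


class Adam:
    def __init__(self, net: UNet, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(arr) for lay in net._layers()
                  for _, arr, _ in lay.params()]
        self.v = [np.zeros_like(arr) for lay in net._layers()
                  for _, arr, _ in lay.params()]

    def step(self) -> None:
        self.t += 1
        i = 0
        for lay in self.net._layers():
            for _, arr, gname in lay.params():
                g = getattr(lay, gname)
                self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
                self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
                mhat = self.m[i] / (1 - self.b1 ** self.t)
                vhat = self.v[i] / (1 - self.b2 ** self.t)
                arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1


def softmax_xent(logits: np.ndarray, target: np.ndarray,
                 fg_weight: float = 3.0) -> tuple[float, np.ndarray]:
    """Class-weighted pixel cross-entropy; returns (loss, dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    prob = ez / ez.sum(axis=1, keepdims=True)
    t = target.astype(np.int64)
    weights = np.where(t == 1, fg_weight, 1.0)
    b = np.arange(logits.shape[0])[:, None, None]
    pt = np.clip(prob[b, t, np.arange(logits.shape[2])[:, None],
                      np.arange(logits.shape[3])[None, :]], 1e-12, None)
    loss = float((-weights * np.log(pt)).sum() / weights.sum())
    onehot = np.zeros_like(prob)
    np.put_along_axis(onehot, t[:, None], 1.0, axis=1)
    dlogits = (prob - onehot) * weights[:, None] / weights.sum()
    return loss, dlogits


def softmax_prob(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)
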