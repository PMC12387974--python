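"""Minimal CPU convolutional-network core (NumPy, float32).

Just enough machinery for small encoder-decoder segmentation networks:
3x3 same-padding convolutions via im2col + GEMM, 2x2 max pooling,
nearest-neighbour 2x upsampling, ReLU, a softmax cross-entropy +
soft-dice loss, and Adam.  Everything is deterministic for a fixed seed
(no threading of our own; BLAS order is fixed by the shapes).

Array layout is NCHW float32 throughout.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

F32 = np.float32


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (C*9, N*H*W) patch matrix for a 3x3 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (C, 3, 3, N, H, W) -> (C*9, N*H*W)
    return np.ascontiguousarray(win.transpose(1, 4, 5, 0, 2, 3)).reshape(
        c * 9, n * h * w)


class Conv3x3:
    """3x3 convolution, stride 1, same padding, with bias."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = (rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(F32)
        self.b = np.zeros(c_out, F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._col: np.ndarray | None = None
        self._shape: Tuple[int, ...] | None = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        col = _im2col3(x)
        out = (self.W.reshape(len(self.W), -1) @ col)
        out += self.b[:, None]
        if train:
            self._col, self._shape = col, x.shape
        return np.ascontiguousarray(
            out.reshape(len(self.W), n, h, w).transpose(1, 0, 2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        co = len(self.W)
        dflat = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(co, -1)
        self.dW += (dflat @ self._col.T).reshape(self.W.shape)
        self.db += dflat.sum(axis=1)
        self._col = None
        # dx = "full" correlation of dout with spatially flipped, transposed W
        wt = np.ascontiguousarray(
            self.W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        col = _im2col3(dout)
        dx = wt.reshape(c, -1) @ col
        return np.ascontiguousarray(dx.reshape(c, n, h, w).transpose(1, 0, 2, 3))


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask

    params: List = []


class MaxPool2:
    """2x2 max pooling, stride 2; ties resolve to the first maximum."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        v = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        v = v.reshape(n, c, h // 2, w // 2, 4)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dv = np.zeros((n, c, h // 2, w // 2, 4), dout.dtype)
        np.put_along_axis(dv, self._idx[..., None], dout[..., None], axis=-1)
        dv = dv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dv).reshape(n, c, h, w)

    params: List = []


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    params: List = []


def softmax(z: np.ndarray) -> np.ndarray:
    """Softmax over the class (channel) axis of (N, K, H, W) logits."""
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def ce_dice_loss(logits: np.ndarray, labels: np.ndarray,
                 dice_smooth: float = 1.0, pixel_mask: np.ndarray = None):
    """Pixel cross-entropy + (1 - mean soft dice), equally weighted.

    labels: (N, H, W) integer classes.  When pixel_mask (N, H, W, bool)
    is given, only those pixels contribute (used for the wound-masked
    second stage, whose predictions outside the mask are discarded
    anyway).  Returns (loss, dlogits, probs).
    """
    n, k, h, w = logits.shape
    p = softmax(logits.astype(np.float64))
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, labels[:, None].astype(np.intp), 1.0, axis=1)
    if pixel_mask is not None:
        wgt = pixel_mask[:, None].astype(np.float64)
        onehot = onehot * wgt
        p_eff = p * wgt
        npix = max(1, int(pixel_mask.sum()))
    else:
        p_eff = p
        npix = n * h * w
    ce = -(onehot * np.log(p.clip(1e-12))).sum() / npix
    s_c = (p_eff * onehot).sum(axis=(0, 2, 3))
    d_c = p_eff.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
    dice_c = (2 * s_c + dice_smooth) / (d_c + dice_smooth)
    loss = ce + (1.0 - dice_c.mean())
    # gradient w.r.t. probabilities, then through the softmax
    g = -onehot / npix / p.clip(1e-12)                      # CE part
    num = (2 * s_c + dice_smooth)
    den = (d_c + dice_smooth)
    # d(1 - mean dice)/dp_c = -(1/k) * (2 y_c den_c - num_c) / den_c^2
    gd = (2 * onehot * den[None, :, None, None]
          - num[None, :, None, None]) / (den ** 2)[None, :, None, None] / k
    if pixel_mask is not None:
        gd = gd * wgt
    g -= gd
    dlogits = p * (g - (g * p).sum(axis=1, keepdims=True))
    return float(loss), dlogits.astype(F32), p


class Adam:
    """Adam over a flat list of (param, grad) array pairs."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.pairs = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)

    def zero_grad(self) -> None:
        for _, g in self.pairs:
            g[...] = 0
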