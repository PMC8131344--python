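"""NumPy building blocks for the network: dilated 2D convolution with
forward and backward passes, activations, weight initialisation and an
RMSprop optimiser.

Convolutions are stride-1, size-preserving ("same") with centred zero
padding (non-causal: for even kernel extents the extra pad goes after, as
in the TensorFlow convention).  Dilation applies along the first spatial
axis only.  Tensors are laid out (batch, height, width, channels);
kernels (kh, kw, in_channels, out_channels).
"""

from __future__ import annotations

import numpy as np

__all__ = ["conv2d", "conv2d_backward", "glorot_uniform", "RMSProp",
           "sigmoid", "tanh", "relu"]


def _pad_amounts(kh: int, kw: int, dil: int) -> tuple[int, int, int, int]:
    th = (kh - 1) * dil
    tw = kw - 1
    return th // 2, th - th // 2, tw // 2, tw - tw // 2


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, dil: int = 1) -> np.ndarray:
    """Size-preserving dilated convolution, accumulated tap by tap.

    Each kernel tap contributes one (B*H*W, C) x (C, F) matrix product;
    memory stays O(input) regardless of kernel size and the arithmetic is
    done in the dtype of ``x``.
    """
    B, H, W, C = x.shape
    kh, kw, cin, F = w.shape
    if cin != C:
        raise ValueError(f"input has {C} channels, kernel expects {cin}")
    pt, pb, pl, pr = _pad_amounts(kh, kw, dil)
    xp = np.zeros((B, H + pt + pb, W + pl + pr, C), dtype=x.dtype)
    xp[:, pt:pt + H, pl:pl + W, :] = x
    out = np.zeros((B * H * W, F), dtype=x.dtype)
    out += b.astype(x.dtype)
    for p in range(kh):
        row = xp[:, p * dil:p * dil + H]
        for q in range(kw):
            out += row[:, :, q:q + W, :].reshape(-1, C) @ w[p, q]
    return out.reshape(B, H, W, F)


def conv2d_backward(
    x: np.ndarray, w: np.ndarray, dil: int, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dw, db) of ``conv2d`` for upstream gradient ``dout``."""
    B, H, W, C = x.shape
    kh, kw, _, F = w.shape
    pt, pb, pl, pr = _pad_amounts(kh, kw, dil)
    xp = np.zeros((B, H + pt + pb, W + pl + pr, C), dtype=x.dtype)
    xp[:, pt:pt + H, pl:pl + W, :] = x
    dxp = np.zeros_like(xp)
    dw = np.zeros_like(w)
    dflat = np.ascontiguousarray(dout.reshape(-1, F))
    db = dflat.sum(axis=0)
    for p in range(kh):
        row = xp[:, p * dil:p * dil + H]
        drow = dxp[:, p * dil:p * dil + H]
        for q in range(kw):
            patch = row[:, :, q:q + W, :].reshape(-1, C)
            dw[p, q] = patch.T @ dflat
            drow[:, :, q:q + W, :] += (dflat @ w[p, q].T).reshape(B, H, W, C)
    dx = dxp[:, pt:pt + H, pl:pl + W, :]
    return dx, dw, db


def glorot_uniform(shape: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Glorot/Xavier uniform init for a (kh, kw, cin, f) kernel."""
    kh, kw, cin, f = shape
    fan_in = kh * kw * cin
    fan_out = kh * kw * f
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def tanh(x: np.ndarray) -> np.ndarray:
    return np.tanh(x)


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class RMSProp:
    """Hinton-style RMSprop with optional heavy-ball momentum:

        s   <- rho * s + (1 - rho) * g^2
        m   <- mu * m + lr * g / (sqrt(s) + eps)
        w   <- w - m
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 rho: float = 0.9, eps: float = 1e-7, momentum: float = 0.0):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.momentum = momentum
        self.cache = {k: np.zeros_like(v) for k, v in params.items()}
        self.vel = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, g in grads.items():
            c = self.cache[k]
            c *= self.rho
            c += (1.0 - self.rho) * g * g
            update = self.lr * g / (np.sqrt(c) + self.eps)
            if self.momentum:
                v = self.vel[k]
                v *= self.momentum
                v += update
                update = v
            self.params[k] -= update
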