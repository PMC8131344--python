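"""FID-Net architecture: stacked gated dilated convolutional residual units.

Each residual unit applies a dilated 8x4 convolution with n filters to its
input, splits the filters into a tanh half and a sigmoid half, multiplies
the two activations (gated activation unit) and passes the n/2-channel
product through a second, undilated 8x4 convolution with n filters.  That
output is added to the unit input (residual path) and also summed across
units (skip path).  The first unit consumes the raw single-channel frame
directly; its residual addition broadcasts over channels.  The skip sum
feeds an 8x4 convolution with n/2 filters and ReLU activation, and a final
single-filter 8x4 convolution with tanh activation bounds the output to
[-1, 1].

Dilation rates cycle through (1, 2, 4, 6, 8, 10, 12, 14, 16, 20, 24, 28,
32), repeated ``n_blocks`` times; dilation acts only along the 512-point
interleaved-FID axis.  With this wiring the trainable parameter total is
1856 n^2 + 126.5 n + 1: 30,424,897 for n = 128 and 7,610,273 for n = 64.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np

from . import _nn

__all__ = ["ModelConfig", "FIDNet", "IdentityModel", "build_model",
           "count_trainable_parameters", "DILATION_CYCLE", "CheckpointError"]

DILATION_CYCLE = (1, 2, 4, 6, 8, 10, 12, 14, 16, 20, 24, 28, 32)


class CheckpointError(Exception):
    """Raised when stored weights do not match the requested configuration."""


@dataclass(frozen=True)
class ModelConfig:
    n_filters: int = 128
    kernel: tuple[int, int] = (8, 4)
    dilation_cycle: tuple[int, ...] = DILATION_CYCLE
    n_blocks: int = 3
    frame_length: int = 512
    n_columns: int = 4

    def __post_init__(self) -> None:
        if self.n_filters % 2:
            raise ValueError("n_filters must be even (half tanh / half sigmoid)")
        if self.n_blocks < 1 or not self.dilation_cycle:
            raise ValueError("need at least one block and one dilation rate")
        if self.frame_length % 2:
            raise ValueError("frame_length must be even (interleaved re/im)")

    @property
    def dilations(self) -> tuple[int, ...]:
        return self.dilation_cycle * self.n_blocks

    @property
    def n_units(self) -> int:
        return len(self.dilation_cycle) * self.n_blocks

    @classmethod
    def reconstruction(cls) -> "ModelConfig":
        return cls(n_filters=128)

    @classmethod
    def decoupling(cls) -> "ModelConfig":
        return cls(n_filters=64)

    def to_dict(self) -> dict:
        return {
            "n_filters": self.n_filters,
            "kernel": list(self.kernel),
            "dilation_cycle": list(self.dilation_cycle),
            "n_blocks": self.n_blocks,
            "frame_length": self.frame_length,
            "n_columns": self.n_columns,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            n_filters=d["n_filters"],
            kernel=tuple(d["kernel"]),
            dilation_cycle=tuple(d["dilation_cycle"]),
            n_blocks=d["n_blocks"],
            frame_length=d["frame_length"],
            n_columns=d["n_columns"],
        )


class FIDNet:
    """A built network: configuration plus weight tensors."""

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params

    # -- construction -------------------------------------------------

    @classmethod
    def build(cls, config: ModelConfig, rng: np.random.Generator,
              dtype=np.float32) -> "FIDNet":
        """Initialise weights (Glorot uniform, zero biases) from ``rng``.

        float32 is the working precision; float64 is available for
        numerical checks.
        """
        kh, kw = config.kernel
        n = config.n_filters
        params: dict[str, np.ndarray] = {}
        cin = 1
        for i, _ in enumerate(config.dilations):
            params[f"u{i}_dil_w"] = _nn.glorot_uniform((kh, kw, cin, n), rng).astype(dtype)
            params[f"u{i}_dil_b"] = np.zeros(n, dtype)
            params[f"u{i}_out_w"] = _nn.glorot_uniform((kh, kw, n // 2, n), rng).astype(dtype)
            params[f"u{i}_out_b"] = np.zeros(n, dtype)
            cin = n
        params["end_relu_w"] = _nn.glorot_uniform((kh, kw, n, n // 2), rng).astype(dtype)
        # small positive bias keeps the narrow ReLU summary layer alive early on
        params["end_relu_b"] = np.full(n // 2, 0.1, dtype)
        params["end_out_w"] = _nn.glorot_uniform((kh, kw, n // 2, 1), rng).astype(dtype)
        params["end_out_b"] = np.zeros(1, dtype)
        return cls(config, params)

    @property
    def dtype(self):
        return self.params["end_out_b"].dtype

    def count_trainable_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- forward / backward -------------------------------------------

    def forward(self, x: np.ndarray, return_cache: bool = False):
        """Map (batch of) real frames (L, 4) -> (L, 4) with values in [-1, 1]."""
        xb = np.asarray(x, dtype=self.dtype)
        single = xb.ndim == 2
        if single:
            xb = xb[None]
        L, W = self.config.frame_length, self.config.n_columns
        if xb.shape[1:] != (L, W):
            raise ValueError(f"expected frames of shape ({L}, {W}), got {xb.shape[1:]}")
        h = xb[..., None]
        n = self.config.n_filters
        skip = None
        cache = {"inputs": [], "acts": []} if return_cache else None
        for i, dil in enumerate(self.config.dilations):
            pre = _nn.conv2d(h, self.params[f"u{i}_dil_w"], self.params[f"u{i}_dil_b"], dil)
            a = _nn.tanh(pre[..., : n // 2])
            g = _nn.sigmoid(pre[..., n // 2:])
            p = a * g
            z = _nn.conv2d(p, self.params[f"u{i}_out_w"], self.params[f"u{i}_out_b"], 1)
            if return_cache:
                cache["inputs"].append(h)
                cache["acts"].append((a, g, p))
            skip = z if skip is None else skip + z
            h = z + h  # broadcasts over channels for the first unit
        u = _nn.conv2d(skip, self.params["end_relu_w"], self.params["end_relu_b"], 1)
        r = _nn.relu(u)
        v = _nn.conv2d(r, self.params["end_out_w"], self.params["end_out_b"], 1)
        y = _nn.tanh(v)
        out = y[..., 0]
        if return_cache:
            cache.update(skip=skip, u=u, r=r, y=y)
            return (out[0] if single else out), cache
        return out[0] if single else out

    def backward(self, cache: dict, dy: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. all weights.

        ``dy`` is the loss gradient w.r.t. the network output (batch, L, 4).
        """
        dy = np.asarray(dy, dtype=self.dtype)
        dyt = (dy[..., None]) * (1.0 - cache["y"] ** 2)  # through tanh
        dr, dw, db = _nn.conv2d_backward(cache["r"], self.params["end_out_w"], 1, dyt)
        grads = {"end_out_w": dw, "end_out_b": db}
        du = dr * (cache["u"] > 0)
        dskip, dw, db = _nn.conv2d_backward(cache["skip"], self.params["end_relu_w"], 1, du)
        grads["end_relu_w"] = dw
        grads["end_relu_b"] = db
        dh = np.zeros_like(dskip)  # gradient w.r.t. the running residual stream
        dils = self.config.dilations
        for i in range(len(dils) - 1, -1, -1):
            a, g, p = cache["acts"][i]
            h_in = cache["inputs"][i]
            dz = dh + dskip
            dp, dw, db = _nn.conv2d_backward(p, self.params[f"u{i}_out_w"], 1, dz)
            grads[f"u{i}_out_w"] = dw
            grads[f"u{i}_out_b"] = db
            da = dp * g
            dg = dp * a
            dpre = np.concatenate([da * (1.0 - a * a), dg * g * (1.0 - g)], axis=-1)
            dx, dw, db = _nn.conv2d_backward(h_in, self.params[f"u{i}_dil_w"], dils[i], dpre)
            grads[f"u{i}_dil_w"] = dw
            grads[f"u{i}_dil_b"] = db
            if h_in.shape[-1] == 1 and dh.shape[-1] != 1:
                # first unit: residual add was a 1 -> n channel broadcast
                dh = dh.sum(axis=-1, keepdims=True) + dx
            else:
                dh = dh + dx
        return grads

    def predict(self, frames: np.ndarray) -> np.ndarray:
        """Inference entry point used by the spectrum pipelines."""
        return self.forward(frames)

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        meta = json.dumps(self.config.to_dict(), sort_keys=True)
        buf = io.BytesIO()
        np.savez(buf, __config__=np.array(meta), **self.params)
        with open(path, "wb") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path, config: ModelConfig | None = None) -> "FIDNet":
        with np.load(path, allow_pickle=False) as npz:
            stored = ModelConfig.from_dict(json.loads(str(npz["__config__"][()])))
            if config is not None and config != stored:
                raise CheckpointError(
                    f"checkpoint was built for {stored}, requested {config}"
                )
            params = {k: npz[k] for k in npz.files if k != "__config__"}
        return cls(stored, params)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k, v in params.items():
            self.params[k][...] = v


class IdentityModel:
    """Oracle model returning its input untouched (pipeline plumbing checks)."""

    def __init__(self, frame_length: int = 512, n_columns: int = 4):
        self.config = ModelConfig(
            n_filters=2, dilation_cycle=(1,), n_blocks=1,
            frame_length=frame_length, n_columns=n_columns,
        )

    def predict(self, frames: np.ndarray) -> np.ndarray:
        return np.asarray(frames).copy()


def build_model(config: ModelConfig, rng: np.random.Generator) -> FIDNet:
    return FIDNet.build(config, rng)


def count_trainable_parameters(model: FIDNet) -> int:
    return model.count_trainable_parameters()
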