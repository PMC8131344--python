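"""Whole-spectrum application of a trained network.

2D NUS reconstruction: the spectrum (already Fourier transformed and
phased in the direct dimension, indirect dimension in the time domain) has
its unsampled indirect points zeroed, is cut into overlapping 4-column
frames along the direct axis, each frame is passed through the network,
and the per-frame outputs are stitched back by averaging the (up to four)
estimates each direct position receives.  The standard deviation over
those estimates gives a per-point confidence map.  Virtual decoupling of
HNCA data applies the same sliding-window machinery plane-by-plane along
the 15N axis, with the 13C dimension kept in the time domain.

Module-wide DFT convention: negative-exponent forward transform; after the
shift the frequency axis runs +SW/2 -> -SW/2, so simulated resonances
appear at their drawn frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nusched
from .nusched import SamplingSchedule

__all__ = [
    "Axis",
    "SpectrumPlane",
    "ReconstructionResult",
    "segment",
    "stitch",
    "reconstruct_2d",
    "decouple_plane",
    "decouple_hnca_3d",
    "sine_bell_squared_window",
    "indirect_ft",
    "freq_axis",
    "normalised_rmsd",
]

WIDTH = 4


@dataclass(frozen=True)
class Axis:
    n_points: int
    sw: float
    center: float = 0.0
    domain: str = "time"  # "time" | "freq"
    half_dwell: bool = False

    def __post_init__(self) -> None:
        if self.domain not in ("time", "freq"):
            raise ValueError("domain must be 'time' or 'freq'")
        if self.n_points < 1 or self.sw <= 0:
            raise ValueError("invalid axis metadata")


@dataclass(frozen=True)
class SpectrumPlane:
    """Complex 2D grid, direct x indirect, with per-axis metadata."""

    data: np.ndarray
    direct: Axis
    indirect: Axis

    def __post_init__(self) -> None:
        if self.data.shape != (self.direct.n_points, self.indirect.n_points):
            raise ValueError(
                f"data shape {self.data.shape} does not match axes "
                f"({self.direct.n_points}, {self.indirect.n_points})"
            )


@dataclass(frozen=True)
class ReconstructionResult:
    """Stitched output plus per-point confidence (std over window estimates)."""

    spectrum: SpectrumPlane
    confidence: np.ndarray
    n_estimates: np.ndarray


def segment(data: np.ndarray, width: int = WIDTH, stride: int = 1) -> np.ndarray:
    """Cut (n_direct, n_indirect) into overlapping frames of ``width``
    adjacent direct positions; returns (n_frames, n_indirect, width)."""
    n_direct = data.shape[0]
    if n_direct < width:
        raise ValueError(f"need at least {width} direct points, got {n_direct}")
    frames = [data[j:j + width].T for j in range(0, n_direct - width + 1, stride)]
    return np.stack(frames)


def stitch(outputs: np.ndarray, n_direct: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average per-position estimates from overlapping frames.

    ``outputs``: (n_frames, n_indirect, width) complex, frame j covering
    direct positions j..j+width-1 (stride 1).  Returns (mean, std,
    n_estimates) with shapes (n_direct, n_indirect); std is the population
    standard deviation of the complex estimates (0 for single-estimate
    edge positions).  Positions where all estimates are bitwise identical
    are passed through exactly.
    """
    n_frames, n_indirect, width = outputs.shape
    if n_frames != n_direct - width + 1:
        raise ValueError("missing frames: expected one frame per direct offset")
    est = np.full((n_direct, n_indirect, width), np.nan + 0j, dtype=complex)
    for slot in range(width):
        # frame j contributes its column ``slot`` to direct position j + slot
        est[slot:slot + n_frames, :, slot] = outputs[:, :, slot]
    valid = ~np.isnan(est.real)
    counts = valid.sum(axis=-1)
    filled = np.where(valid, est, 0.0)
    mean = filled.sum(axis=-1) / counts
    var = (np.where(valid, np.abs(est - mean[..., None]) ** 2, 0.0).sum(axis=-1)) / counts
    std = np.sqrt(var)
    # exactness guard: positions whose estimates all agree bitwise pass through
    first_slot = np.argmax(valid, axis=-1)
    first = np.take_along_axis(est, first_slot[..., None], axis=-1)[..., 0]
    same = np.where(valid, est == first[..., None], True).all(axis=-1)
    mean = np.where(same, first, mean)
    std = np.where(same, 0.0, std)
    return mean, std, counts


def _frame_scale(values: np.ndarray) -> float:
    peak = float(np.max(np.abs(values)))
    if peak == 0.0:
        return 1.0
    return float(2.0 ** np.ceil(np.log2(peak)))


def _apply_model_sliding(data: np.ndarray, model) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared sliding-window machinery: segment, normalise per frame
    (power-of-two scale, inverted on stitch), batched forward, stitch."""
    n_direct, n_indirect = data.shape
    frame_length = model.config.frame_length
    if 2 * n_indirect > frame_length:
        raise ValueError(
            f"{n_indirect} indirect complex points exceed the model's "
            f"{frame_length}-point frame capacity"
        )
    frames = segment(data)
    batch = np.empty((frames.shape[0], frame_length, WIDTH))
    scales = np.empty(frames.shape[0])
    for k, frame in enumerate(frames):
        values, _ = nusched.prepare_input(frame, frame_length)
        scales[k] = _frame_scale(values)
        batch[k] = values / scales[k]
    out = model.predict(batch)
    cols = out[:, 0::2, :] + 1j * out[:, 1::2, :]  # de-interleave along the frame axis
    cols = cols[:, :n_indirect, :] * scales[:, None, None]
    return stitch(cols, n_direct)


def reconstruct_2d(
    plane: SpectrumPlane, schedule: SamplingSchedule, model
) -> ReconstructionResult:
    """Reconstruct a 2D NUS plane (direct dim already transformed/phased).

    Unsampled indirect points are zeroed, the sliding-window network fills
    them in, and the stitched output is returned with the indirect
    dimension still in the time domain.
    """
    if plane.direct.domain != "freq":
        raise ValueError("direct dimension must be frequency domain (transformed/phased)")
    if plane.indirect.domain != "time":
        raise ValueError("indirect dimension must be in the time domain")
    if schedule.n_grid != plane.indirect.n_points:
        raise ValueError("schedule grid does not match the indirect dimension")
    masked = nusched.apply_schedule(plane.data, schedule)
    mean, std, counts = _apply_model_sliding(masked, model)
    out_plane = SpectrumPlane(mean, plane.direct, plane.indirect)
    return ReconstructionResult(out_plane, std, counts)


def decouple_plane(plane: SpectrumPlane, model) -> ReconstructionResult:
    """Virtually decouple one 1H(freq) x 13C(time) plane (fully sampled)."""
    if plane.direct.domain != "freq":
        raise ValueError("1H dimension must be frequency domain")
    if plane.indirect.domain != "time":
        raise ValueError("13C dimension must be in the time domain")
    mean, std, counts = _apply_model_sliding(plane.data, model)
    out_plane = SpectrumPlane(mean, plane.direct, plane.indirect)
    return ReconstructionResult(out_plane, std, counts)


def decouple_hnca_3d(
    cube: np.ndarray,
    model,
    sw_h: float,
    sw_c: float,
    window: np.ndarray | None = None,
    zero_fill_factor: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Decouple a 3D HNCA cube laid out (1H, 15N, 13C-time).

    The 1H and 15N dimensions must already be transformed; each 1H-13C
    plane is decoupled independently and the planes recombined in order.
    The 13C dimension is then windowed and Fourier transformed, yielding
    the frequency-domain cube plus the (time-domain) confidence cube.
    """
    n_h, n_n, n_c = cube.shape
    out_planes = []
    confidences = []
    for k in range(n_n):
        plane = SpectrumPlane(
            cube[:, k, :],
            Axis(n_h, sw_h, domain="freq"),
            Axis(n_c, sw_c, domain="time"),
        )
        result = decouple_plane(plane, model)
        out_planes.append(result.spectrum)
        confidences.append(result.confidence)
    freq_planes = [
        indirect_ft(p, window=window, zero_fill_factor=zero_fill_factor).data
        for p in out_planes
    ]
    out = np.stack(freq_planes, axis=1)
    conf = np.stack(confidences, axis=1)
    return out, conf


def sine_bell_squared_window(
    n_points: int, offset: float = 0.42, end: float = 0.98, power: float = 2.0
) -> np.ndarray:
    """Apodization weights sin(pi*offset + pi*(end-offset)*k/(N-1))^power."""
    if n_points < 2:
        raise ValueError("need at least two points")
    if not 0.0 <= offset <= end <= 1.0:
        raise ValueError("require 0 <= offset <= end <= 1")
    k = np.arange(n_points)
    return np.sin(np.pi * offset + np.pi * (end - offset) * k / (n_points - 1)) ** power


def freq_axis(n: int, sw: float) -> np.ndarray:
    """Frequency axis after the shifted forward transform: +SW/2 descending."""
    return sw / 2.0 - np.arange(n) * sw / n


def indirect_ft(
    plane: SpectrumPlane,
    window: np.ndarray | None = None,
    zero_fill_factor: int = 1,
) -> SpectrumPlane:
    """Window and Fourier transform the indirect dimension.

    A half-dwell first point triggers scaling of the first indirect point
    by 0.5 before the transform.  ``zero_fill_factor`` multiplies the
    transform size.
    """
    if plane.indirect.domain != "time":
        raise ValueError("indirect dimension is already in the frequency domain")
    data = plane.data.copy()
    if window is not None:
        if window.shape[0] != data.shape[1]:
            raise ValueError("window length does not match the indirect dimension")
        data = data * window[None, :]
    if plane.indirect.half_dwell:
        data[:, 0] *= 0.5
    n_out = plane.indirect.n_points * zero_fill_factor
    spec = np.fft.fftshift(np.fft.fft(data, n=n_out, axis=1), axes=1)
    new_axis = Axis(n_out, plane.indirect.sw, plane.indirect.center, "freq",
                    plane.indirect.half_dwell)
    return SpectrumPlane(spec, plane.direct, new_axis)


def normalised_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMS difference after each spectrum is scaled by its own maximum
    intensity point."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na = np.max(np.abs(a))
    nb = np.max(np.abs(b))
    if na == 0 or nb == 0:
        raise ValueError("cannot normalise an all-zero spectrum")
    return float(np.sqrt(np.mean(np.abs(a / na - b / nb) ** 2)))
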