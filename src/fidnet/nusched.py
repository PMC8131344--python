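"""Non-uniform sampling schedules and network input framing.

Schedules are ordered, unique, 0-based indices over *complex* points of the
indirect grid (each index keeps both quadrature components).  Two
generators are provided: uniform random and sinusoidally weighted
Poisson-gap sampling, which biases sampling toward early evolution times.
The first grid point is always sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingSchedule",
    "target_count",
    "random_schedule",
    "poisson_gap_schedule",
    "apply_schedule",
    "prepare_input",
    "deinterleave",
    "read_nuslist",
    "write_nuslist",
]

FRAME_LENGTH = 512
N_COLUMNS = 4


@dataclass(frozen=True)
class SamplingSchedule:
    indices: np.ndarray  # strictly increasing, unique, 0-based
    n_grid: int
    sparsity: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.size < 1:
            raise ValueError("schedule must contain at least one index")
        if idx[0] != 0:
            raise ValueError("first grid point (index 0) must be sampled")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("indices must be strictly increasing and unique")
        if idx[-1] >= self.n_grid or idx[0] < 0:
            raise ValueError("indices outside [0, n_grid)")
        if idx.size != target_count(self.n_grid, self.sparsity):
            raise ValueError("index count inconsistent with sparsity")

    @property
    def n_sampled(self) -> int:
        return int(self.indices.size)

    def mask(self) -> np.ndarray:
        m = np.zeros(self.n_grid, dtype=bool)
        m[self.indices] = True
        return m


def target_count(n_grid: int, sparsity: float) -> int:
    """Number of sampled points: round-half-up of sparsity * n_grid."""
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    n = int(np.floor(sparsity * n_grid + 0.5))
    if n < 1:
        raise ValueError("sparsity too low: no points would be sampled")
    return n


def random_schedule(n_grid: int, sparsity: float, rng: np.random.Generator) -> SamplingSchedule:
    """Uniform draw without replacement, with index 0 forced."""
    n = target_count(n_grid, sparsity)
    rest = rng.choice(np.arange(1, n_grid), size=n - 1, replace=False) if n > 1 else []
    idx = np.sort(np.concatenate([[0], np.asarray(rest, dtype=int)]))
    return SamplingSchedule(idx, n_grid, sparsity)


def _poisson_gap_pass(n_grid: int, lam: float, rng: np.random.Generator) -> np.ndarray:
    """One sequential pass: gaps ~ Poisson(lam * sin(theta)), theta 0 -> pi/2."""
    idx = []
    i = 0
    while i < n_grid:
        idx.append(i)
        theta = np.pi / 2.0 * (i + 0.5) / n_grid
        gap = rng.poisson(lam * np.sin(theta)) if lam > 0 else 0
        i += 1 + gap
    return np.asarray(idx, dtype=int)


def poisson_gap_schedule(
    n_grid: int, sparsity: float, rng: np.random.Generator, max_tries: int = 20000
) -> SamplingSchedule:
    """Sinusoidally weighted Poisson-gap schedule (sequential gap drawing).

    Gaps between consecutive sampled indices follow a Poisson law whose
    rate is modulated by sin(theta) with theta advancing 0 -> pi/2 across
    the grid, so gaps grow toward late evolution times.  The base rate is
    rescaled in +/-2% steps and passes redrawn until the sampled count
    exactly equals ``target_count(n_grid, sparsity)``.
    """
    n = target_count(n_grid, sparsity)
    if n == n_grid:
        return SamplingSchedule(np.arange(n_grid), n_grid, sparsity)
    # mean gap needed is n_grid/n - 1; E[sin(theta)] over the grid is ~2/pi
    lam = (n_grid / n - 1.0) * np.pi / 2.0
    for _ in range(max_tries):
        idx = _poisson_gap_pass(n_grid, lam, rng)
        if idx.size == n:
            return SamplingSchedule(idx, n_grid, sparsity)
        lam *= 1.02 if idx.size > n else 0.98
    raise RuntimeError("Poisson-gap rate adjustment did not converge")


def apply_schedule(plane: np.ndarray, schedule: SamplingSchedule) -> np.ndarray:
    """Zero all unsampled indirect points (last axis); sampled ones untouched."""
    if plane.shape[-1] != schedule.n_grid:
        raise ValueError(
            f"plane indirect size {plane.shape[-1]} != schedule grid {schedule.n_grid}"
        )
    out = np.zeros_like(plane)
    out[..., schedule.indices] = plane[..., schedule.indices]
    return out


def prepare_input(columns: np.ndarray, frame_length: int = FRAME_LENGTH) -> tuple[np.ndarray, int]:
    """Interleave re/im of four adjacent columns and zero-fill to the frame.

    ``columns``: complex array (n_indirect, 4).  Returns (values, valid_length)
    where ``values`` is real of shape (frame_length, 4) holding
    re(0), im(0), re(1), im(1), ... per column, and entries beyond
    ``valid_length`` = 2 * n_indirect are exactly zero.
    """
    columns = np.asarray(columns)
    if columns.ndim != 2 or columns.shape[1] != N_COLUMNS:
        raise ValueError(f"expected (n_indirect, {N_COLUMNS}) columns, got {columns.shape}")
    n_indirect = columns.shape[0]
    valid = 2 * n_indirect
    if valid > frame_length:
        raise ValueError(
            f"{n_indirect} complex points exceed the {frame_length}-point frame capacity"
        )
    values = np.zeros((frame_length, N_COLUMNS))
    values[0:valid:2] = columns.real
    values[1:valid:2] = columns.imag
    return values, valid


def deinterleave(values: np.ndarray, n_indirect: int | None = None) -> np.ndarray:
    """Invert ``prepare_input``: real (L, 4) -> complex (L/2 or n_indirect, 4)."""
    if values.shape[0] % 2:
        raise ValueError("frame length must be even")
    cols = values[0::2] + 1j * values[1::2]
    if n_indirect is not None:
        cols = cols[:n_indirect]
    return cols


def read_nuslist(path) -> np.ndarray:
    """Read a plain-text schedule, one sampled index per line.

    Tolerates a second (weight) column and blank/comment lines.
    """
    indices = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            indices.append(int(line.split()[0]))
    return np.asarray(sorted(set(indices)), dtype=int)


def write_nuslist(schedule: SamplingSchedule, path) -> None:
    with open(path, "w") as fh:
        for i in schedule.indices:
            fh.write(f"{int(i)}\n")
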