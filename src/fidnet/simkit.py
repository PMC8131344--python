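"""Synthetic 2D NMR time-domain data.

Planes are sums of exponentially decaying complex sinusoids with optional
cosine J-modulation in the indirect dimension:

    S(t1, t2) = sum_n A_n exp(-i 2 pi nu1_n t1) exp(-R2_1n t1)
                      cos(pi J_n t2) exp(-i 2 pi nu2_n t2) exp(-R2_2n t2)

with evolution times t_k = k / SW for k = 0 .. N-1.  Two shipped generator
presets mirror the training conditions of the reconstruction and virtual
decoupling tasks respectively.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "SignalParams",
    "GridSpec",
    "GeneratorSpec",
    "reconstruction_preset",
    "decoupling_preset",
    "PRESETS",
    "sample_grid",
    "sample_signal_params",
    "synthesize_plane",
    "synthesize_interferogram",
    "add_noise",
    "normalise_plane",
]


@dataclass(frozen=True)
class SignalParams:
    """One synthetic resonance.

    amplitude : dimensionless, in [0, 2]
    nu1, nu2  : direct / indirect frequency (Hz), in [-SW/2, +SW/2]
    r2_direct, r2_indirect : transverse relaxation rates (1/s), > 0
    j : scalar coupling (Hz); 0 encodes an uncoupled ("glycine") signal
    """

    amplitude: float
    nu1: float
    nu2: float
    r2_direct: float
    r2_indirect: float
    j: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude <= 2.0:
            raise ValueError(f"amplitude {self.amplitude} outside [0, 2]")
        if self.r2_direct <= 0 or self.r2_indirect <= 0:
            raise ValueError("relaxation rates must be positive")
        if self.j < 0:
            raise ValueError("J coupling must be non-negative")


@dataclass(frozen=True)
class GridSpec:
    """Acquisition grid of a 2D plane (complex points and sweep widths)."""

    n_direct: int
    n_indirect: int
    sw_direct: float
    sw_indirect: float
    half_dwell_first: bool = False

    def __post_init__(self) -> None:
        if self.n_direct < 1 or self.n_indirect < 1:
            raise ValueError("point counts must be >= 1")
        if self.sw_direct <= 0 or self.sw_indirect <= 0:
            raise ValueError("sweep widths must be positive")

    def t_direct(self) -> np.ndarray:
        return np.arange(self.n_direct) / self.sw_direct

    def t_indirect(self) -> np.ndarray:
        t = np.arange(self.n_indirect, dtype=float)
        if self.half_dwell_first:
            t = t + 0.5
        return t / self.sw_indirect


def _check_range(name, rng_pair, lo=None, hi=None):
    a, b = rng_pair
    if a > b:
        raise ValueError(f"{name}: empty range ({a}, {b})")
    if lo is not None and a < lo:
        raise ValueError(f"{name}: lower bound {a} < {lo}")
    if hi is not None and b > hi:
        raise ValueError(f"{name}: upper bound {b} > {hi}")


@dataclass
class GeneratorSpec:
    """Parameter ranges for random plane generation.

    All ``*_range`` pairs are inclusive uniform intervals.  Amplitudes are
    drawn from Normal(amp_mean, amp_sd) truncated (by redrawing) to
    ``amp_bounds``.  ``glycine_fraction`` is the probability that a signal's
    J coupling is forced to 0 Hz.
    """

    n_signals_range: tuple[int, int] = (50, 250)
    amp_mean: float = 1.0
    amp_sd: float = 0.5
    amp_bounds: tuple[float, float] = (0.0, 2.0)
    n_direct_range: tuple[int, int] = (128, 512)
    n_indirect_range: tuple[int, int] = (100, 256)
    sw_direct_range: tuple[float, float] = (1500.0, 3000.0)
    sw_indirect_range: tuple[float, float] = (1800.0, 5400.0)
    j_range: tuple[float, float] = (0.0, 0.0)
    glycine_fraction: float = 0.0
    r2_direct_range: tuple[float, float] = (5.0, 60.0)
    r2_indirect_range: tuple[float, float] = (5.0, 60.0)
    noise_sigma_range: tuple[float, float] = (0.001, 0.03)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_range("n_signals_range", self.n_signals_range, lo=0)
        _check_range("amp_bounds", self.amp_bounds)
        _check_range("n_direct_range", self.n_direct_range, lo=1)
        _check_range("n_indirect_range", self.n_indirect_range, lo=1)
        _check_range("sw_direct_range", self.sw_direct_range, lo=0)
        _check_range("sw_indirect_range", self.sw_indirect_range, lo=0)
        _check_range("j_range", self.j_range, lo=0)
        _check_range("r2_direct_range", self.r2_direct_range, lo=0)
        _check_range("r2_indirect_range", self.r2_indirect_range, lo=0)
        _check_range("noise_sigma_range", self.noise_sigma_range, lo=0.0, hi=1.0)
        if not 0.0 <= self.glycine_fraction <= 1.0:
            raise ValueError("glycine_fraction must lie in [0, 1]")

    # -- serialisation ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - fields
        if unknown:
            raise ValueError(f"unknown generator fields: {sorted(unknown)}")
        kwargs = {}
        for k, v in d.items():
            kwargs[k] = tuple(v) if isinstance(v, (list, tuple)) else v
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def reconstruction_preset() -> GeneratorSpec:
    """Training conditions for the NUS reconstruction task (J = 0)."""
    return GeneratorSpec()


def decoupling_preset() -> GeneratorSpec:
    """Training conditions for virtual decoupling (J 28-40 Hz, 12% glycine)."""
    return GeneratorSpec(
        n_signals_range=(10, 70),
        n_indirect_range=(192, 256),
        sw_direct_range=(1800.0, 5400.0),
        sw_indirect_range=(4000.0, 8000.0),
        j_range=(28.0, 40.0),
        glycine_fraction=0.12,
    )


PRESETS = {
    "reconstruction": reconstruction_preset,
    "decoupling": decoupling_preset,
}


def sample_grid(spec: GeneratorSpec, rng: np.random.Generator) -> GridSpec:
    """Draw an acquisition grid uniformly from the spec's ranges."""
    lo, hi = spec.n_direct_range
    n_direct = int(rng.integers(lo, hi + 1))
    lo, hi = spec.n_indirect_range
    n_indirect = int(rng.integers(lo, hi + 1))
    sw_direct = float(rng.uniform(*spec.sw_direct_range))
    sw_indirect = float(rng.uniform(*spec.sw_indirect_range))
    return GridSpec(n_direct, n_indirect, sw_direct, sw_indirect)


def _truncated_normal(mean, sd, bounds, size, rng):
    lo, hi = bounds
    if sd == 0:
        if not lo <= mean <= hi:
            raise ValueError("degenerate amplitude draw outside bounds")
        return np.full(size, float(mean))
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draw = rng.normal(mean, sd, remaining.size)
        ok = (draw >= lo) & (draw <= hi)
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return out


def sample_signal_params(
    spec: GeneratorSpec, grid: GridSpec, rng: np.random.Generator
) -> list[SignalParams]:
    """Draw a random set of resonances for one plane.

    Frequencies are uniform in [-SW/2, +SW/2] for each dimension; couplings
    are forced to 0 Hz with probability ``glycine_fraction`` and otherwise
    uniform in ``j_range``.
    """
    lo, hi = spec.n_signals_range
    n = int(rng.integers(lo, hi + 1))
    amps = _truncated_normal(spec.amp_mean, spec.amp_sd, spec.amp_bounds, n, rng)
    nu1 = rng.uniform(-0.5, 0.5, n) * grid.sw_direct
    nu2 = rng.uniform(-0.5, 0.5, n) * grid.sw_indirect
    r2_1 = rng.uniform(*spec.r2_direct_range, n)
    r2_2 = rng.uniform(*spec.r2_indirect_range, n)
    j = rng.uniform(*spec.j_range, n)
    glycine = rng.random(n) < spec.glycine_fraction
    j[glycine] = 0.0
    return [
        SignalParams(float(amps[i]), float(nu1[i]), float(nu2[i]),
                     float(r2_1[i]), float(r2_2[i]), float(j[i]))
        for i in range(n)
    ]


def _direct_factor(p: SignalParams, t1: np.ndarray) -> np.ndarray:
    return np.exp((-2j * np.pi * p.nu1 - p.r2_direct) * t1)


def _indirect_factor(p: SignalParams, t2: np.ndarray) -> np.ndarray:
    return np.cos(np.pi * p.j * t2) * np.exp((-2j * np.pi * p.nu2 - p.r2_indirect) * t2)


def _factor_matrices(params: list[SignalParams], grid: GridSpec):
    """Per-signal direct and indirect evolution factors as two matrices."""
    t1 = grid.t_direct()
    t2 = grid.t_indirect()
    amp = np.array([p.amplitude for p in params])
    nu1 = np.array([p.nu1 for p in params])
    nu2 = np.array([p.nu2 for p in params])
    r21 = np.array([p.r2_direct for p in params])
    r22 = np.array([p.r2_indirect for p in params])
    j = np.array([p.j for p in params])
    direct = amp[:, None] * np.exp(np.outer(-2j * np.pi * nu1 - r21, t1))
    indirect = (np.cos(np.pi * np.outer(j, t2))
                * np.exp(np.outer(-2j * np.pi * nu2 - r22, t2)))
    return direct, indirect


def synthesize_plane(params: list[SignalParams], grid: GridSpec) -> np.ndarray:
    """Evaluate the signal equation on the grid.

    Returns a complex array of shape (n_direct, n_indirect); an empty
    parameter list gives a zero plane.  The sum is additive in ``params``.
    """
    if not params:
        return np.zeros((grid.n_direct, grid.n_indirect), dtype=np.complex128)
    direct, indirect = _factor_matrices(params, grid)
    return direct.T @ indirect


def synthesize_interferogram(params: list[SignalParams], grid: GridSpec) -> np.ndarray:
    """Plane after direct-dimension Fourier transform and phasing.

    Emulates hypercomplex (States-style) processing of real data: the direct
    dimension is transformed and phased to pure absorption (imaginaries
    discarded) while the indirect dimension keeps both quadrature
    components.  For the separable signal model this equals, per resonance,
    the real part of the direct-dimension DFT times the complex indirect
    evolution.  Direct frequency axis follows the module convention
    (+SW/2 at index 0, descending).
    """
    if not params:
        return np.zeros((grid.n_direct, grid.n_indirect), dtype=np.complex128)
    direct, indirect = _factor_matrices(params, grid)
    direct[:, 0] *= 0.5  # first-point scaling halves the one-sided DFT's DC offset
    absorption = np.fft.fftshift(np.fft.fft(direct, axis=1), axes=1).real
    return absorption.T @ indirect


def add_noise(plane: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Additive i.i.d. Gaussian noise on real and imaginary parts."""
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if sigma == 0:
        return plane.copy()
    noise = rng.normal(0.0, sigma, plane.shape) + 1j * rng.normal(0.0, sigma, plane.shape)
    return plane + noise


def normalise_plane(plane: np.ndarray) -> np.ndarray:
    """Scale so the highest-intensity point has magnitude 1."""
    peak = np.max(np.abs(plane))
    if peak == 0:
        raise ValueError("cannot normalise an all-zero plane")
    return plane / peak
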