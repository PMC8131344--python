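"""On-the-fly training for the reconstruction and decoupling tasks.

Each training example is generated fresh from the synthetic-signal
generator: a plane is simulated, Fourier transformed in the direct
dimension, four consecutive direct positions are picked at random, noise is
added to the input copy and (reconstruction task) a fresh random sampling
schedule is applied.  The target is built from the same resonance draw with
no noise — fully sampled for reconstruction, J set to 0 for decoupling —
and stored in the frequency domain, where the loss lives.

Training follows a two-stage learning-rate schedule: the first stage runs
until the validation loss plateaus, after which the rate is lowered and
training continues until a second plateau.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace

import numpy as np

from . import nusched, simkit
from .model import FIDNet
from .simkit import GeneratorSpec, GridSpec

__all__ = [
    "TrainingExample",
    "TrainConfig",
    "PlateauDetector",
    "make_training_example",
    "freq_domain_mse",
    "freq_domain_mse_grad",
    "train",
]

TASKS = ("reconstruction", "decoupling")


@dataclass(frozen=True)
class TrainingExample:
    input: np.ndarray        # real (frame_length, 4), interleaved, in [-1, 1]
    target: np.ndarray       # complex (frame_length/2, 4), frequency domain
    task: str
    valid_length: int        # 2 * n_indirect


@dataclass
class TrainConfig:
    batch_size: int = 16
    lr_stage1: float = 1e-4
    lr_stage2: float = 1e-5
    patience: int = 3
    min_rel_delta: float = 0.005
    steps_per_epoch: int = 50
    max_epochs: int = 1000
    rho: float = 0.9
    eps: float = 1e-7
    momentum: float = 0.9
    clip_norm: float | None = 10.0
    warmup_steps: int = 100

    def __post_init__(self) -> None:
        if self.lr_stage2 >= self.lr_stage1:
            raise ValueError("stage-2 learning rate must be below stage 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


class PlateauDetector:
    """Fires when the relative improvement of the tracked loss stays below
    ``min_rel_delta`` for ``patience`` consecutive updates."""

    def __init__(self, patience: int, min_rel_delta: float):
        self.patience = patience
        self.min_rel_delta = min_rel_delta
        self.best = np.inf
        self.count = 0

    def update(self, loss: float) -> bool:
        if np.isfinite(self.best) and self.best > 0:
            improvement = (self.best - loss) / self.best
        else:
            improvement = np.inf if loss < self.best else 0.0
        if improvement < self.min_rel_delta:
            self.count += 1
        else:
            self.count = 0
        self.best = min(self.best, loss)
        return self.count >= self.patience

    def reset(self) -> None:
        self.best = np.inf
        self.count = 0


def _frame_scale(values: np.ndarray) -> float:
    """Power-of-two scale >= max|values| (lossless to divide and re-multiply)."""
    peak = float(np.max(np.abs(values)))
    if peak == 0.0:
        return 1.0
    return float(2.0 ** np.ceil(np.log2(peak)))


def _spectrum_target(columns: np.ndarray, frame_length: int) -> np.ndarray:
    """Zero-fill complex columns to frame_length/2 and DFT along the indirect
    axis (negative-exponent forward transform, shifted)."""
    n_freq = frame_length // 2
    padded = np.zeros((n_freq, columns.shape[1]), dtype=complex)
    padded[: columns.shape[0]] = columns
    return np.fft.fftshift(np.fft.fft(padded, axis=0), axes=0)


@dataclass(frozen=True)
class TrainingPlane:
    """One simulated plane held in a training pool.

    ``interferogram`` is the plane after the direct-dimension transform,
    normalised to unit maximum intensity; for the decoupling task
    ``target_interferogram`` holds the J = 0 version on the same scale.
    Each epoch draws a fresh crop, noise realisation and (reconstruction)
    sampling schedule from it.
    """

    interferogram: np.ndarray
    target_interferogram: np.ndarray | None
    grid: GridSpec


def make_training_plane(
    spec: GeneratorSpec, task: str, rng: np.random.Generator
) -> TrainingPlane:
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    grid = simkit.sample_grid(spec, rng)
    params = simkit.sample_signal_params(spec, grid, rng)
    plane = simkit.synthesize_interferogram(params, grid)
    # plane-level normalisation sets the scale the noise std refers to
    peak = np.max(np.abs(plane))
    if peak > 0:
        plane = plane / peak
    target = None
    if task == "decoupling":
        decoupled = [replace(p, j=0.0) for p in params]
        target = simkit.synthesize_interferogram(decoupled, grid)
        if peak > 0:
            target = target / peak
        target = target.astype(np.complex64)
    return TrainingPlane(plane.astype(np.complex64), target, grid)


def example_from_plane(
    plane: TrainingPlane,
    task: str,
    sparsity: float,
    rng: np.random.Generator,
    frame_length: int = 512,
    noise_sigma_range: tuple[float, float] = (0.001, 0.03),
) -> TrainingExample:
    """Crop four consecutive direct positions, add noise, and (for the
    reconstruction task) apply a fresh random schedule."""
    grid = plane.grid
    if 2 * grid.n_indirect > frame_length:
        raise ValueError("indirect grid exceeds the frame capacity")
    j = int(rng.integers(0, grid.n_direct - 3))
    cols = plane.interferogram[j:j + 4].T.astype(complex)  # (n_indirect, 4)

    sigma = float(rng.uniform(*noise_sigma_range))
    noisy = simkit.add_noise(cols, sigma, rng)
    if task == "reconstruction":
        schedule = nusched.random_schedule(grid.n_indirect, sparsity, rng)
        noisy = nusched.apply_schedule(noisy.T, schedule).T
        target_cols = cols
    else:
        target_cols = plane.target_interferogram[j:j + 4].T.astype(complex)

    values, valid = nusched.prepare_input(noisy, frame_length)
    scale = _frame_scale(values)
    values /= scale
    target = _spectrum_target(target_cols / scale, frame_length)
    return TrainingExample(values, target, task, valid)


def make_training_example(
    spec: GeneratorSpec,
    task: str,
    sparsity: float,
    rng: np.random.Generator,
    frame_length: int = 512,
) -> TrainingExample:
    """Generate one (input, frequency-domain target) pair from a fresh plane.

    For the decoupling task the input is fully sampled (``sparsity`` is
    ignored) and the target has all couplings removed.
    """
    plane = make_training_plane(spec, task, rng)
    return example_from_plane(plane, task, sparsity, rng, frame_length,
                              spec.noise_sigma_range)


def freq_domain_mse(output: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error in the frequency domain.

    ``output`` is a real interleaved frame (L, 4) (or a batch); it is
    de-interleaved to complex FIDs, transformed along the indirect axis and
    compared with the complex frequency-domain ``target``; the mean runs
    over the complex grid.
    """
    output = np.asarray(output)
    target = np.asarray(target)
    cols = output[..., 0::2, :] + 1j * output[..., 1::2, :]
    spec = np.fft.fftshift(np.fft.fft(cols, axis=-2), axes=-2)
    if spec.shape != target.shape:
        raise ValueError(f"shape mismatch: {spec.shape} vs {target.shape}")
    return float(np.mean(np.abs(spec - target) ** 2))


def freq_domain_mse_grad(output: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the real interleaved output."""
    output = np.asarray(output)
    cols = output[..., 0::2, :] + 1j * output[..., 1::2, :]
    spec = np.fft.fftshift(np.fft.fft(cols, axis=-2), axes=-2)
    err = spec - target
    loss = float(np.mean(np.abs(err) ** 2))
    n_freq = err.shape[-2]
    # d/d cols of mean |F cols - T|^2: adjoint DFT of the error
    g_cols = np.fft.ifft(np.fft.ifftshift(err, axes=-2), axis=-2) * n_freq
    g_cols *= 2.0 / err.size
    grad = np.empty_like(output)
    grad[..., 0::2, :] = g_cols.real
    grad[..., 1::2, :] = g_cols.imag
    return loss, grad


def _clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    """Scale the whole gradient so its global L2 norm is at most max_norm.

    The frequency-domain loss is heavy-tailed across examples (sharp lines
    concentrate spectral energy), so occasional batches produce gradients
    orders of magnitude above typical; unclipped they saturate the gated
    units and can kill the ReLU summary layer outright.
    """
    total = sum(float((g.astype(np.float64) ** 2).sum()) for g in grads.values())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / norm
        for k in grads:
            grads[k] = grads[k] * scale


def _batch(examples: list[TrainingExample]):
    x = np.stack([e.input for e in examples])
    t = np.stack([e.target for e in examples])
    return x, t


def evaluate_loss(model: FIDNet, examples: list[TrainingExample]) -> float:
    x, t = _batch(examples)
    return freq_domain_mse(model.forward(x), t)


def train(
    model: FIDNet,
    spec: GeneratorSpec,
    task: str,
    config: TrainConfig,
    rng: np.random.Generator,
    validation_size: int = 64,
    sparsity: float = 0.125,
    plane_pool_size: int | None = None,
    log=None,
) -> list[dict]:
    """Two-stage training loop; returns the per-epoch loss history.

    With ``plane_pool_size`` set, that many planes are generated up front
    and every epoch revisits each plane once with a fresh crop, noise
    realisation and sampling schedule (the effective training set grows
    with the epoch count).  Otherwise planes are generated on the fly,
    ``steps_per_epoch`` batches per epoch.  The validation set comes from
    a stream split off ``rng`` and stays fixed; the weights with the best
    validation loss are restored at the end.
    """
    from . import _nn

    frame_length = model.config.frame_length
    val_rng = np.random.default_rng(rng.integers(0, 2**31))
    val_set = [
        make_training_example(spec, task, sparsity, val_rng, frame_length)
        for _ in range(validation_size)
    ]
    pool = None
    if plane_pool_size is not None:
        pool = [make_training_plane(spec, task, rng) for _ in range(plane_pool_size)]
    opt = _nn.RMSProp(model.params, config.lr_stage1, config.rho, config.eps,
                      config.momentum)
    plateau = PlateauDetector(config.patience, config.min_rel_delta)
    stage = 1
    history: list[dict] = []
    best_val = np.inf
    best_params = model.copy_params()
    global_step = 0
    for epoch in range(config.max_epochs):
        train_losses = []
        if pool is not None:
            order = rng.permutation(len(pool))
            batches = [
                order[k:k + config.batch_size]
                for k in range(0, len(pool), config.batch_size)
            ]
        else:
            batches = [None] * config.steps_per_epoch
        for batch_idx in batches:
            if pool is not None:
                examples = [
                    example_from_plane(pool[i], task, sparsity, rng, frame_length,
                                       spec.noise_sigma_range)
                    for i in batch_idx
                ]
            else:
                examples = [
                    make_training_example(spec, task, sparsity, rng, frame_length)
                    for _ in range(config.batch_size)
                ]
            x, t = _batch(examples)
            global_step += 1
            if stage == 1 and config.warmup_steps:
                # ramp in while the RMSprop preconditioner calibrates
                opt.lr = config.lr_stage1 * min(1.0, global_step / config.warmup_steps)
            y, cache = model.forward(x, return_cache=True)
            loss, dy = freq_domain_mse_grad(y, t)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            grads = model.backward(cache, dy)
            if config.clip_norm is not None:
                _clip_global_norm(grads, config.clip_norm)
            opt.step(grads)
            train_losses.append(loss)
        val_loss = evaluate_loss(model, val_set)
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        history.append(
            {"epoch": epoch, "stage": stage,
             "train_loss": float(np.mean(train_losses)), "val_loss": val_loss}
        )
        if log is not None:
            log(history[-1])
        if val_loss < best_val:
            best_val = val_loss
            best_params = model.copy_params()
        if plateau.update(val_loss):
            if stage == 1:
                stage = 2
                opt.lr = config.lr_stage2
                plateau.reset()
            else:
                break
    model.set_params(best_params)
    return history


def write_history(history: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "stage", "train_loss", "val_loss"])
        writer.writeheader()
        writer.writerows(history)
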