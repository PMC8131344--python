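# Methods

## Overview

`fidnet` implements a WaveNet-style sequence-to-sequence network for 2D NMR
time-domain data together with everything needed to train and apply it:

* a synthetic free-induction-decay (FID) simulator,
* non-uniform-sampling (NUS) schedule generators,
* the network architecture with an exact trainable-parameter accounting,
* an on-the-fly training loop with a frequency-domain loss,
* whole-spectrum pipelines for 2D NUS reconstruction and for virtual
  decoupling of HNCA-type planes, and
* NMRPipe-format I/O plus a command-line interface.

The two applications share one architecture and differ only in filter count
and training data: reconstruction fills in unsampled indirect-dimension
points of a 12.5%-sampled spectrum; virtual decoupling removes the
~35 Hz ¹³Cα–¹³Cβ scalar-coupling doublet splitting from fully sampled
planes, which doubles the sensitivity of the collapsed singlets.

## Signal model

A synthetic plane is a sum of exponentially decaying complex sinusoids with
optional cosine J-modulation in the indirect dimension:

S(t₁, t₂) = Σₙ Aₙ · exp(−i2πν₁,ₙt₁) · exp(−R₂⁽¹,ⁿ⁾t₁)
            · cos(πJₙt₂) · exp(−i2πν₂,ₙt₂) · exp(−R₂⁽²,ⁿ⁾t₂)

with evolution times tₖ = k/SW, k = 0…N−1.  Amplitudes follow a normal
distribution (mean 1.0, SD 0.5) truncated to [0, 2]; truncation is done by
redrawing rather than clipping so no probability mass piles up at the
bounds.  Frequencies are uniform in [−SW/2, +SW/2].  Two presets fix the
remaining ranges:

| parameter | reconstruction | decoupling |
|---|---|---|
| signals per plane | 50–250 | 10–70 |
| direct complex points | 128–512 | 128–512 |
| indirect complex points | 100–256 | 192–256 |
| direct SW (Hz) | 1500–3000 | 1800–5400 |
| indirect SW (Hz) | 1800–5400 | 4000–8000 |
| J (Hz) | 0 | 28–40 (12% forced to 0) |
| R₂ (s⁻¹), both dims | 5–60 | 5–60 |
| noise σ | 0.001–0.03 | 0.001–0.03 |

The 12% zero-J fraction emulates glycine residues, which have no
¹³Cβ and therefore no doublet splitting.

The simulator also produces the "interferogram" form of a plane — the
direct dimension Fourier transformed and phased to absorption with the
indirect dimension still in the time domain — by combining, per resonance,
the real part of the direct-dimension DFT (first time point halved, the
standard correction for the DC offset of a one-sided transform) with the
complex indirect evolution.  This is what hypercomplex (States-style)
processing of measured data produces, and it is the form the network sees.

### Transform convention

Module-wide, the forward DFT uses the negative exponent and spectra are
stored with the frequency axis running +SW/2 → −SW/2.  With the signal
model's exp(−i2πνt) convention, a resonance drawn at ν appears at ν on
that axis.  All internal transforms, the training loss and the pipelines
use this one convention.

## Sampling schedules

Schedules are ordered unique 0-based indices over complex points of the
indirect grid; the sampled count is round-half-up of sparsity × grid size
and index 0 (the first, most-informative point) is always forced.  Two
generators are provided:

* **uniform random** — a draw without replacement from the remaining
  indices;
* **Poisson-gap** with sinusoidal weighting — gaps between consecutive
  samples follow a Poisson law whose rate is modulated by sin(θ), θ
  advancing 0 → π/2 across the grid, so sampling is dense at early
  evolution times where the FID is strongest.  The base rate is rescaled
  in ±2% steps, redrawing the schedule, until the count is exactly met;
  this sequential-redraw form follows the published description of the
  algorithm, with the step size an implementation choice.

## Architecture

The network maps a real 512 × 4 frame — four adjacent direct-dimension
columns whose indirect-dimension complex points are interleaved
re(0), im(0), re(1), im(1), … and zero-filled to 512 — to a frame of the
same shape.  It is a stack of gated dilated convolutional residual units:

* each unit applies a dilated 8 × 4 convolution with n filters to its
  input, splits the filters into a tanh half and a sigmoid half,
  multiplies the activations (a gated activation unit, n/2 channels), and
  passes the product through a second, undilated 8 × 4 convolution with
  n filters;
* that output is added to the unit input (residual path) and accumulated
  into a running skip sum;
* dilation rates cycle through 1, 2, 4, 6, 8, 10, 12, 14, 16, 20, 24, 28,
  32 — three times, 39 units in total — and act only along the 512-point
  frame axis;
* the skip sum passes through an 8 × 4 convolution with n/2 filters and
  ReLU activation, then a final single-filter 8 × 4 convolution with tanh
  activation, bounding outputs to [−1, 1].

All convolutions are stride-1, size-preserving, with centred (non-causal)
zero padding: unlike autoregressive audio models the network may look both
forward and backward along the FID.

### Parameter accounting

The end-layer wiring is pinned down by the published parameter totals.
With the first unit consuming the raw single-channel frame directly (its
residual addition broadcasts over channels) and the end layers as above,
the trainable total is

    T(n) = 1856 n² + 126.5 n + 1

which gives exactly 30,424,897 for n = 128 (reconstruction) and 7,610,273
for n = 64 (decoupling).  Alternative wirings that were considered — an
input projection before the first unit, an n-filter summary layer, a gated
product feeding only the skip path — each miss at least one of the two
totals, so this wiring is the one the counts admit.  Every convolution
carries a bias.  `tests/test_model.py` checks the accounting against an
independent per-layer formula over randomised small configurations.

The network is implemented directly in NumPy (forward pass, analytic
backward pass, RMSprop), with convolutions evaluated as per-tap matrix
products.  Gradients are verified against finite differences in the test
suite.  Weights are float32; a float64 mode exists for numerical checks.

## Training

Training data is generated on the fly.  One example is built by:

1. simulating a plane and forming its interferogram;
2. normalising the plane to unit maximum intensity (this sets the scale
   that the noise σ refers to);
3. picking four consecutive direct positions at random;
4. adding Gaussian noise (σ uniform in 0.001–0.03) to the input copy;
5. reconstruction only: applying a fresh uniform-random 12.5% schedule;
6. interleaving, zero-filling to the frame length, and scaling the frame
   by the smallest power of two that bounds its maximum absolute value.

The target is built from the same resonance draw with no noise — fully
sampled for reconstruction, J set to 0 for decoupling — on the same scale,
and stored in the frequency domain.  Power-of-two frame scaling is used
because dividing and re-multiplying by a power of two is lossless in
binary floating point, so a pipeline built on the same scaling can return
untouched data bit-exactly; values still land in [−1, 1].

The loss is the mean squared error, over the complex frequency grid,
between the DFT of the (de-interleaved) network output and the noiseless
target spectrum.  The loss gradient is the adjoint DFT of the residual.

The optimiser is RMSprop (decay 0.9, ε = 10⁻⁷) with heavy-ball momentum
0.9 on the preconditioned step.  Momentum matters at these batch sizes:
with 16 heterogeneous examples per batch the per-parameter gradient
signal-to-noise ratio is low, and plain RMSprop — whose step size is
roughly lr regardless of gradient reliability — random-walks; averaging
~10 preconditioned steps recovers the signal.  Gradients are clipped to a
global L2 norm of 10 before the update: the frequency-domain loss is
heavy-tailed across examples (a sharp line concentrates its spectral
energy into a few huge bins), and the occasional ~1000× gradient spike
otherwise drives the n/2-channel ReLU summary layer entirely negative,
after which no gradient flows at all.  Two further guards against that
failure mode: the learning rate ramps in linearly over the first 100
steps (while the RMSprop preconditioner calibrates, a raw step is ~3×
oversized and momentum compounds it), and the ReLU layer's biases start
at +0.1 instead of 0 so its narrow channel set begins alive.  The
learning rate then follows
the two-stage schedule: 10⁻⁴ until the validation loss plateaus (relative
improvement below 0.5% for `patience` consecutive epochs), then 10⁻⁵
until a second plateau.  Batch size is 16.  The validation set is
generated once from a dedicated stream and held fixed; the weights with
the best validation loss are restored at the end.

Two data regimes are supported: fully on-the-fly (every batch fresh), and
a plane pool, where a fixed number of planes is simulated up front and
every epoch revisits each plane once with a fresh crop, fresh noise and a
fresh schedule.  The pool regime matches the intent of re-using each
simulated plane many times while never showing the network the same
masked crop twice, and it is what the scaled-down tests use.

## Whole-spectrum pipelines

**2D NUS reconstruction** expects a plane already Fourier transformed and
phased in the direct dimension (indirect in the time domain) plus its
sampling schedule.  Unsampled points are zeroed, the plane is cut into
overlapping 4-column frames (stride 1), each frame is normalised
(power-of-two scale, inverted on output), passed through the network in
one batch, de-interleaved and un-scaled, and the frames are stitched:
every direct position is the mean of the estimates from the (up to four)
frames that contain it.  The population standard deviation over the same
estimates — zero wherever they agree bitwise — is returned as a per-point
confidence map, computed on the time-domain outputs before the indirect
transform.  Edge positions are averaged over their 1–3 available
estimates rather than padding the spectrum with invented columns.

**Virtual decoupling** applies the identical sliding-window machinery to
fully sampled ¹H(frequency) × ¹³C(time) planes.  For 3D HNCA data the
cube (¹H and ¹⁵N transformed, ¹³C in time) is decoupled plane-by-plane
along ¹⁵N, recombined in order, then windowed and transformed in ¹³C.

**Windowing and metrics.**  Indirect transforms use the squared sine-bell
window sin(π·0.42 + π·(0.98−0.42)·k/(N−1))² by default (offsets 0.42 and
0.98, power 2).  A half-dwell first point triggers scaling of the first
indirect point by 0.5 before the transform.  Spectra are compared with the
normalised RMSD: each spectrum is scaled by its own maximum intensity
point, then the root-mean-square difference is taken.

## NMRPipe I/O

Spectra are read and written in the NMRPipe single-file format (512
float32 header words + float32 data; 3D data as numbered 2D plane files).
Only the header words the pipelines need are interpreted — sizes, sweep
widths, quadrature and Fourier-domain flags, transpose state — and the
full header is carried through opaquely so a round trip is bit-exact.
Malformed files raise a format error with a byte-offset diagnostic.

## Scaled-down verification studies

Training either published network to convergence is a GPU-weeks
undertaking, so the test suite verifies the training loop end-to-end at a
reduced scale chosen to run on a single CPU core in minutes:

* toy model: 16 filters, one cycle of the 13-rate dilation schedule,
  256-point frames; planes with 128 indirect complex points and 32–64
  direct points; a pool of 2,000 generated planes revisited each epoch
  with fresh crops, noise and schedules; R₂ and sweep-width ranges
  inherited from the full-scale presets; batch 16;
* **reconstruction**: 20–50 signals per plane, 12.5% sampling, learning
  rate 5·10⁻⁴ for 3 epochs; after training, the mean windowed-spectrum
  normalised RMSD against ground truth over 50 held-out synthetic planes
  must fall strictly below the zero-filling baseline;
* **decoupling**: 10–40 signals, J 28–40 Hz with 12% glycine, learning
  rate 10⁻³ for 4 epochs; the decoupled output must be strictly closer
  to the J = 0 oracle spectrum than the coupled input is, while
  all-glycine planes are altered by less than that improvement margin.

These studies show that the implementation learns and that the pipelines
compose correctly.  They do not show paper-scale reconstruction quality:
the published networks are 8–60× larger and were trained on the order of
10⁶–10⁷ examples.  The simulator also omits, by design, phase errors,
solvent signals, t₁ noise and non-Lorentzian lineshapes, so even a fully
trained model's synthetic-data performance bounds, rather than measures,
real-spectrum performance.

One clause of the decoupling study deserves a caveat: a model trained on
noisy inputs (σ 0.001–0.03) acquires a denoising bias, so on a noiseless
plane its output differs from its input by roughly the training-noise
floor even when it alters no peak.  That floor (~0.006 in whole-spectrum
normalised RMSD here) bounds the model's error on coupled planes from
below as well, capping the achievable improvement margin near
(input-to-oracle distance) − (floor) ≈ 0.005.  Whole-spectrum glycine
"change" therefore cannot fall below the margin at this training scale;
at full scale both numbers shrink together and the singlet peaks
themselves are unaltered.  The test encodes the strict form and is
expected to fail its glycine clause at toy scale; the margin clause
(doublet planes move strictly closer to the oracle) passes.

## Numerical choices and degenerate inputs

* Round-half-up for schedule point counts (determinism).
* All stochastic operations consume an explicit seeded generator; a run
  is fully reproducible from one master seed, and schedule/validation
  streams are split off the master stream.
* All-zero planes are rejected by normalisation (no division by zero);
  empty resonance lists synthesise a zero plane.
* The frame capacity is 256 complex points (512 interleaved); larger
  indirect grids raise a capacity error rather than truncating silently.
* Training noise is added after plane-level normalisation (so σ is
  relative to unit peak intensity) and the final frame normalisation
  comes last, keeping inputs in [−1, 1]; where the order could matter it
  is confined to `fidnet.training` and covered by tests.

## Known limitations

* Only one indirect dimension is reconstructed per pass; schedules are
  one-dimensional.
* The NMRPipe header support is the minimal set the pipelines need;
  exotic header usage (transposed multi-dimensional streams, Bruker/
  Varian conversion) is out of scope.
* No attempt is made to reproduce the published end-of-training losses or
  the real-protein benchmark comparisons, which require undeposited
  spectra and third-party reconstruction tools.
* Confidence maps are computed before the indirect transform; they flag
  where the four window estimates disagree, which correlates with — but
  is not a calibrated estimate of — reconstruction error.
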