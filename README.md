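# fidnet

Dilated gated convolutional networks for NMR time-domain data, with two
applications: reconstruction of non-uniformly sampled (NUS) 2D spectra and
virtual ¹³Cα–¹³Cβ decoupling of HNCA planes.

## The problem

Multidimensional NMR experiments build their indirect dimensions one scan
at a time, so resolution costs acquisition time.  Non-uniform sampling
records only a subset of the indirect-dimension grid (here 12.5%) and
leaves the rest to be reconstructed; scalar couplings split ¹³Cα
resonances into ~35 Hz doublets that halve sensitivity and clutter
spectra.  Both problems can be phrased as sequence-to-sequence maps on the
free-induction decay (FID): fill in missing complex points, or remove the
cos(πJt) modulation.  This package implements a WaveNet-style network for
those maps — stacked gated dilated convolutional residual units with skip
connections, dilation rates cycling 1…32 three times, and tanh-bounded
output — trained purely on synthetic FIDs

S(t₁,t₂) = Σₙ Aₙ e^{−i2πν₁t₁} e^{−R₂⁽¹⁾t₁} cos(πJt₂) e^{−i2πν₂t₂} e^{−R₂⁽²⁾t₂}

with a mean-squared-error loss in the frequency domain.  The network sees
four adjacent direct-dimension columns at a time (a 512 × 4 real frame of
interleaved quadrature components) and is slid across the spectrum; each
column is therefore estimated four times, and the spread of those
estimates yields a per-point confidence map alongside the reconstruction.

The reconstruction configuration (128 filters) has 30,424,897 trainable
parameters; the decoupling configuration (64 filters) has 7,610,273.  The
network and its training (backpropagation, RMSprop) are implemented
directly in NumPy — no deep-learning framework is required.

See `docs/methods.md` for the model, training protocol, conventions and
limitations.

## Worked example

Simulate a small ground-truth plane, make a 12.5% Poisson-gap schedule,
and reconstruct with an untrained toy checkpoint (the `fixtures`
subcommand writes all three), then score it:

```sh
fidnet fixtures --out fx
fidnet reconstruct --in fx/plane.pipe --schedule fx/schedule.nuslist \
                   --model fx/toy_model.npz --out recon.pipe
fidnet evaluate recon.pipe fx/plane.pipe
```

which prints (untrained weights, so the reconstruction is poor):

```
normalised RMSD: 0.378928
```

The number is the root-mean-square difference between the two spectra
after each is scaled by its own maximum intensity point — the metric used
throughout for comparing reconstructions; identical spectra give 0.
A trained model is produced by, e.g.

```sh
fidnet train --task reconstruction --filters 16 --blocks 1 \
             --frame-length 256 --epochs 4 --seed 7 --out run/
```

which writes a config snapshot, per-epoch loss history (CSV) and the
best-validation checkpoint `run/model.npz`.  Python API:

```python
import numpy as np
from fidnet import (GeneratorSpec, ModelConfig, build_model, train,
                    TrainConfig, reconstruct_2d, normalised_rmsd)

rng = np.random.default_rng(7)
model = build_model(ModelConfig.reconstruction(), rng)   # 30,424,897 params
print(model.count_trainable_parameters())
```

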