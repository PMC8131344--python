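import numpy as np
import pytest

from fidnet import simkit


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return simkit.GridSpec(n_direct=16, n_indirect=64,
                           sw_direct=2000.0, sw_indirect=3000.0)


@pytest.fixture
def tiny_generator():
    """Scaled-down generator for fast pipeline tests."""
    return simkit.GeneratorSpec(
        n_signals_range=(5, 10),
        n_direct_range=(16, 16),
        n_indirect_range=(32, 32),
        sw_direct_range=(1500.0, 3000.0),
        sw_indirect_range=(1800.0, 5400.0),
        j_range=(0.0, 0.0),
    )


def brute_dft(x):
    """Reference DFT: explicit O(N^2) sum with the negative-exponent
    convention and the +SW/2 -> -SW/2 shifted ordering."""
    x = np.asarray(x, dtype=complex)
    n = x.size
    k = np.arange(n)
    m = np.arange(n)
    mat = np.exp(-2j * np.pi * np.outer(m, k) / n)
    return np.concatenate([(mat @ x)[n - n // 2:], (mat @ x)[: n - n // 2]])
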