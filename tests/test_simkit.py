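"""Simulator checks against brute-force DFT oracles and sample statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fidnet import simkit
from fidnet.simkit import GeneratorSpec, GridSpec, SignalParams

from conftest import brute_dft


class TestSignalParams:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SignalParams(amplitude=2.5, nu1=0, nu2=0, r2_direct=1, r2_indirect=1)
        with pytest.raises(ValueError):
            SignalParams(amplitude=1, nu1=0, nu2=0, r2_direct=0, r2_indirect=1)
        with pytest.raises(ValueError):
            SignalParams(amplitude=1, nu1=0, nu2=0, r2_direct=1, r2_indirect=1, j=-3)


class TestSampling:
    def test_reconstruction_preset_draws(self, rng):
        spec = simkit.reconstruction_preset()
        grid = simkit.sample_grid(spec, rng)
        assert 128 <= grid.n_direct <= 512
        assert 100 <= grid.n_indirect <= 256
        params = simkit.sample_signal_params(spec, grid, rng)
        assert 50 <= len(params) <= 250
        assert all(p.j == 0.0 for p in params)
        for p in params:
            assert -grid.sw_direct / 2 <= p.nu1 <= grid.sw_direct / 2
            assert -grid.sw_indirect / 2 <= p.nu2 <= grid.sw_indirect / 2
            assert 0.0 <= p.amplitude <= 2.0
            assert 5.0 <= p.r2_direct <= 60.0

    def test_glycine_fraction_statistics(self, rng):
        spec = simkit.decoupling_preset()
        spec = GeneratorSpec(**{**spec.to_dict(), "n_signals_range": (100_000, 100_000)})
        grid = GridSpec(8, 8, 2000.0, 4000.0)
        params = simkit.sample_signal_params(spec, grid, rng)
        frac = np.mean([p.j == 0.0 for p in params])
        assert abs(frac - 0.12) < 0.01
        coupled = [p.j for p in params if p.j > 0]
        assert min(coupled) >= 28.0 and max(coupled) <= 40.0

    def test_degenerate_ranges_give_exact_values(self, rng):
        spec = GeneratorSpec(
            n_signals_range=(3, 3), amp_mean=1.5, amp_sd=0.0,
            n_direct_range=(8, 8), n_indirect_range=(8, 8),
            sw_direct_range=(2000.0, 2000.0), sw_indirect_range=(4000.0, 4000.0),
            j_range=(30.0, 30.0), r2_direct_range=(7.0, 7.0),
            r2_indirect_range=(9.0, 9.0),
        )
        grid = simkit.sample_grid(spec, rng)
        assert (grid.n_direct, grid.sw_indirect) == (8, 4000.0)
        params = simkit.sample_signal_params(spec, grid, rng)
        assert len(params) == 3
        for p in params:
            assert (p.amplitude, p.j, p.r2_direct, p.r2_indirect) == (1.5, 30.0, 7.0, 9.0)

    def test_amplitude_truncated_normal(self, rng):
        spec = simkit.reconstruction_preset()
        draws = simkit._truncated_normal(1.0, 0.5, (0.0, 2.0), 200_000, rng)
        assert draws.min() >= 0.0 and draws.max() <= 2.0
        assert abs(draws.mean() - 1.0) < 0.01  # symmetric truncation keeps the mean

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec(n_signals_range=(10, 5))
        with pytest.raises(ValueError):
            GeneratorSpec(glycine_fraction=1.5)


class TestSynthesize:
    def test_empty_params_zero_plane(self, small_grid):
        plane = simkit.synthesize_plane([], small_grid)
        assert plane.shape == (16, 64)
        assert np.all(plane == 0)

    def test_time_zero_value(self, small_grid):
        p = SignalParams(1.0, 321.0, -432.0, 11.0, 13.0, 0.0)
        plane = simkit.synthesize_plane([p], small_grid)
        assert plane[0, 0] == pytest.approx(1.0 + 0.0j)

    def test_linearity(self, small_grid, rng):
        spec = GeneratorSpec(n_signals_range=(4, 4), n_direct_range=(16, 16),
                             n_indirect_range=(64, 64))
        pa = simkit.sample_signal_params(spec, small_grid, rng)
        pb = simkit.sample_signal_params(spec, small_grid, rng)
        lhs = simkit.synthesize_plane(pa + pb, small_grid)
        rhs = simkit.synthesize_plane(pa, small_grid) + simkit.synthesize_plane(pb, small_grid)
        np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-12)

    def test_doublet_positions_against_brute_dft(self):
        grid = GridSpec(1, 256, 2000.0, 1000.0)
        p = SignalParams(1.0, 0.0, 120.0, 10.0, 4.0, 35.0)
        fid = simkit.synthesize_plane([p], grid)[0]
        spec = np.abs(brute_dft(fid))
        axis = grid.sw_indirect / 2 - np.arange(256) * grid.sw_indirect / 256
        top2 = np.sort(np.argsort(spec)[-2:])
        bin_width = grid.sw_indirect / 256
        for peak_nu, idx in zip((120.0 + 17.5, 120.0 - 17.5), top2):
            assert abs(axis[idx] - peak_nu) <= bin_width

    @pytest.mark.parametrize("case", range(5))
    def test_frequency_fidelity_2d(self, case):
        rng = np.random.default_rng(100 + case)
        grid = GridSpec(64, 64, 2500.0, 3500.0)
        p = SignalParams(1.0, float(rng.uniform(-0.45, 0.45) * grid.sw_direct),
                         float(rng.uniform(-0.45, 0.45) * grid.sw_indirect),
                         float(rng.uniform(5, 40)), float(rng.uniform(5, 40)), 0.0)
        plane = simkit.synthesize_plane([p], grid)
        s1 = np.stack([brute_dft(col) for col in plane.T], axis=1)
        spec = np.stack([brute_dft(row) for row in s1], axis=0)
        i, j = np.unravel_index(np.argmax(np.abs(spec)), spec.shape)
        ax1 = grid.sw_direct / 2 - np.arange(64) * grid.sw_direct / 64
        ax2 = grid.sw_indirect / 2 - np.arange(64) * grid.sw_indirect / 64
        assert abs(ax1[i] - p.nu1) <= grid.sw_direct / 64
        assert abs(ax2[j] - p.nu2) <= grid.sw_indirect / 64

    def test_decay_monotonicity(self, small_grid):
        p = SignalParams(1.3, 200.0, -300.0, 8.0, 20.0, 0.0)
        plane = simkit.synthesize_plane([p], small_grid)
        mags = np.abs(plane[0])
        assert np.all(np.diff(mags) <= 1e-15)

    def test_half_dwell_shifts_time_origin(self):
        grid = GridSpec(2, 8, 1000.0, 1000.0, half_dwell_first=True)
        p = SignalParams(1.0, 0.0, 0.0, 1.0, 10.0, 0.0)
        plane = simkit.synthesize_plane([p], grid)
        assert abs(plane[0, 0]) == pytest.approx(np.exp(-10.0 * 0.5 / 1000.0))


class TestNoiseAndNormalise:
    def test_zero_sigma_identity(self, small_grid, rng):
        plane = np.ones((4, 5), dtype=complex)
        out = simkit.add_noise(plane, 0.0, rng)
        assert np.array_equal(out, plane)
        assert out is not plane

    def test_noise_statistics(self, rng):
        plane = np.zeros((400, 250), dtype=complex)
        out = simkit.add_noise(plane, 0.02, rng)
        assert abs(np.std(out.real) - 0.02) < 0.001
        assert abs(np.std(out.imag) - 0.02) < 0.001

    def test_noise_deterministic_under_seed(self):
        plane = np.zeros((10, 10), dtype=complex)
        a = simkit.add_noise(plane, 0.01, np.random.default_rng(5))
        b = simkit.add_noise(plane, 0.01, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_negative_sigma_rejected(self, rng):
        with pytest.raises(ValueError):
            simkit.add_noise(np.zeros((2, 2), complex), -0.1, rng)

    def test_normalise_scales_by_max(self):
        plane = np.array([[1.0, -5.0], [2.0, 0.5]], dtype=complex)
        out = simkit.normalise_plane(plane)
        assert np.max(np.abs(out)) == 1.0
        np.testing.assert_allclose(out, plane / 5.0)

    def test_normalise_idempotent(self, rng):
        plane = rng.normal(size=(6, 6)) + 1j * rng.normal(size=(6, 6))
        once = simkit.normalise_plane(plane)
        np.testing.assert_allclose(simkit.normalise_plane(once), once, atol=1e-15)

    def test_normalise_brute_force_max(self, rng):
        plane = rng.normal(size=(7, 9)) + 1j * rng.normal(size=(7, 9))
        best = max(abs(v) for v in plane.ravel())  # exhaustive scan
        np.testing.assert_allclose(simkit.normalise_plane(plane), plane / best)

    def test_normalise_zero_plane_rejected(self):
        with pytest.raises(ValueError):
            simkit.normalise_plane(np.zeros((3, 3), complex))


class TestSerialisation:
    def test_yaml_round_trip(self, tmp_path):
        spec = simkit.decoupling_preset()
        spec.to_yaml(tmp_path / "gen.yaml")
        back = GeneratorSpec.from_yaml(tmp_path / "gen.yaml")
        assert back == spec

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError):
            GeneratorSpec.from_dict({"bogus": 1})

    def test_presets_match_tasks(self):
        rec = simkit.PRESETS["reconstruction"]()
        dec = simkit.PRESETS["decoupling"]()
        assert rec.j_range == (0.0, 0.0)
        assert dec.j_range == (28.0, 40.0)
        assert dec.glycine_fraction == 0.12
        assert dec.n_signals_range == (10, 70)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(1, 50), st.integers(1, 50))
def test_synthesize_interferogram_matches_column_fft(n_sig_seed, grid_seed):
    """The interferogram equals absorption-mode direct FT per resonance."""
    rng = np.random.default_rng(n_sig_seed * 1000 + grid_seed)
    grid = GridSpec(8, 8, 2000.0, 3000.0)
    p = SignalParams(1.0, float(rng.uniform(-900, 900)), float(rng.uniform(-1400, 1400)),
                     float(rng.uniform(5, 50)), float(rng.uniform(5, 50)), 0.0)
    inter = simkit.synthesize_interferogram([p], grid)
    fid1 = np.exp((-2j * np.pi * p.nu1 - p.r2_direct) * grid.t_direct())
    fid1[0] *= 0.5
    absorption = np.fft.fftshift(np.fft.fft(fid1)).real
    fid2 = np.exp((-2j * np.pi * p.nu2 - p.r2_indirect) * grid.t_indirect())
    np.testing.assert_allclose(inter, np.outer(absorption, fid2), atol=1e-10)
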