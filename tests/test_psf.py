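import numpy as np
import pytest

from edofmask.characterize import fwhm
from edofmask.doe import BasisCoefficients, order_field
from edofmask.optics import OpticalConfig, grin_aberration, make_pupil_grid, AberrationModel
from edofmask.psf import (
    IntensityStack,
    make_source,
    on_axis_profile,
    simulate_stack,
)


class TestMakeSource:
    def test_zero_diameter_is_unit_impulse(self, small_config):
        src = make_source(0.0, small_config)
        assert src.energy == pytest.approx(1.0)
        c = small_config.grid_size // 2
        assert src.amplitude[c, c] == 1.0
        assert np.count_nonzero(src.amplitude) == 1

    def test_five_um_disk_is_about_13_pixels_across(self):
        cfg = OpticalConfig(grid_size=64)  # 0.375 um object pixels
        src = make_source(5.0, cfg)
        c = 32
        row = src.amplitude[c] > 0
        assert row.sum() == 13

    @pytest.mark.parametrize("diameter", [0.0, 2.0, 5.0, 10.0])
    def test_unit_energy_for_any_diameter(self, diameter, small_config):
        src = make_source(diameter, small_config)
        assert src.energy == pytest.approx(1.0, rel=1e-12)

    def test_rejects_source_larger_than_field(self, small_config):
        with pytest.raises(ValueError):
            make_source(1e5, small_config)


class TestSimulateStack:
    def test_unaberrated_focus_peaks_at_center(self, small_config, small_grid):
        src = make_source(0.0, small_config)
        stack = simulate_stack(
            src,
            np.ones(small_grid.shape),
            np.zeros(small_grid.shape),
            np.array([0.0]),
            np.inf,
            small_config,
            grid=small_grid,
        )
        c = small_config.grid_size // 2
        peak = np.unravel_index(np.argmax(stack.data[0]), stack.data[0].shape)
        assert peak == (c, c)

    def test_scattering_decay_factorizes_exactly(self, small_config, small_grid):
        src = make_source(5.0, small_config)
        pupil = np.ones(small_grid.shape)
        ab = np.zeros(small_grid.shape)
        depths = small_config.depths()
        free = simulate_stack(src, pupil, ab, depths, np.inf, small_config,
                              grid=small_grid, stack_dtype=np.float64)
        dec = simulate_stack(src, pupil, ab, depths, 100.0, small_config,
                             grid=small_grid, stack_dtype=np.float64)
        rel = depths - depths.min()
        expected = free.data * np.exp(-rel / 100.0)[:, None, None]
        np.testing.assert_allclose(dec.data, expected, rtol=1e-12)

    def test_parseval_energy_conservation(self, small_config, small_grid):
        """Unit-modulus pupil over full support, no decay: per-slice energy
        equals the source energy at every depth (orthonormal transforms)."""
        src = make_source(5.0, small_config)
        phase = np.random.default_rng(0).uniform(0, 2 * np.pi, small_grid.shape)
        stack = simulate_stack(
            src,
            np.exp(1j * phase),
            np.zeros(small_grid.shape),
            small_config.depths(),
            np.inf,
            small_config,
            grid=small_grid,
            apply_aperture=False,
            stack_dtype=np.float64,
        )
        energies = stack.data.sum(axis=(1, 2))
        np.testing.assert_allclose(energies, src.energy, rtol=1e-9)

    def test_lateral_shift_invariance(self, small_config, small_grid):
        """Translating the source translates every slice identically."""
        cfg, grid = small_config, small_grid
        src = make_source(2.0, cfg)
        shifted_amp = np.roll(src.amplitude, (3, -2), axis=(0, 1))
        shifted = type(src)(diameter_um=2.0, amplitude=shifted_amp)
        ab = grin_aberration(AberrationModel(5.0), grid)
        depths = np.array([-10.0, 0.0, 10.0])
        a = simulate_stack(src, np.ones(grid.shape), ab, depths, np.inf, cfg, grid=grid,
                           stack_dtype=np.float64)
        b = simulate_stack(shifted, np.ones(grid.shape), ab, depths, np.inf, cfg, grid=grid,
                           stack_dtype=np.float64)
        rolled = np.roll(a.data, (3, -2), axis=(1, 2))
        np.testing.assert_allclose(b.data, rolled, atol=1e-10 * a.data.max())

    def test_conjugate_orders_mirror_in_z(self, small_config, small_grid):
        """With zero native aberration the +1/-1 order stacks are z-mirrored."""
        cfg, grid = small_config, small_grid
        src = make_source(0.0, cfg)
        coeffs = BasisCoefficients(0.0, 6.0, 3.0)
        depths = np.arange(-16.0, 17.0, 4.0)
        zero_ab = np.zeros(grid.shape)
        plus = simulate_stack(src, order_field(coeffs, +1, grid, cfg), zero_ab,
                              depths, np.inf, cfg, grid=grid, stack_dtype=np.float64)
        minus = simulate_stack(src, order_field(coeffs, -1, grid, cfg), zero_ab,
                               depths, np.inf, cfg, grid=grid, stack_dtype=np.float64)
        np.testing.assert_allclose(
            on_axis_profile(plus), on_axis_profile(minus)[::-1], rtol=1e-9
        )

    def test_grid_mismatch_rejected(self, small_config, small_grid):
        src = make_source(0.0, small_config)
        with pytest.raises(ValueError):
            simulate_stack(src, np.ones((8, 8)), np.zeros((8, 8)),
                           np.array([0.0]), np.inf, small_config, grid=small_grid)

    def test_nonpositive_scattering_length_rejected(self, small_config, small_grid):
        src = make_source(0.0, small_config)
        with pytest.raises(ValueError):
            simulate_stack(src, np.ones(small_grid.shape), np.zeros(small_grid.shape),
                           np.array([0.0]), -5.0, small_config, grid=small_grid)

    def test_axial_fwhm_against_oversampled_resimulation(self):
        """Native-aberration axial width is stable under 4x lateral
        oversampling of the pupil (discretization oracle)."""
        depths = np.arange(-60.0, 121.0, 2.0)
        widths = {}
        for n in (256, 512):
            cfg = OpticalConfig(grid_size=n)
            grid = make_pupil_grid(cfg)
            ab = grin_aberration(AberrationModel(29.4), grid)
            src = make_source(0.0, cfg)
            st = simulate_stack(src, np.ones(grid.shape), ab, depths, np.inf, cfg,
                                grid=grid, working_dtype=np.complex64)
            widths[n], _ = fwhm(on_axis_profile(st), 2.0)
        assert abs(widths[256] - widths[512]) <= 2.0  # within one axial step


class TestOnAxisProfile:
    def test_impulse_slice(self, small_config):
        data = np.zeros((5, 8, 8))
        data[3, 4, 4] = 2.0
        stack = IntensityStack(data, np.arange(5.0), False, np.inf)
        profile = on_axis_profile(stack)
        assert profile.tolist() == [0, 0, 0, 2.0, 0]

    def test_length_equals_n_depths(self, small_config, small_grid):
        src = make_source(0.0, small_config)
        stack = simulate_stack(src, np.ones(small_grid.shape), np.zeros(small_grid.shape),
                               small_config.depths(), np.inf, small_config, grid=small_grid)
        assert len(on_axis_profile(stack)) == small_config.n_depths

    def test_decay_scales_profile(self, small_config, small_grid):
        src = make_source(2.0, small_config)
        depths = small_config.depths()
        free = simulate_stack(src, np.ones(small_grid.shape), np.zeros(small_grid.shape),
                              depths, np.inf, small_config, grid=small_grid,
                              stack_dtype=np.float64)
        dec = simulate_stack(src, np.ones(small_grid.shape), np.zeros(small_grid.shape),
                             depths, 50.0, small_config, grid=small_grid,
                             stack_dtype=np.float64)
        rel = depths - depths.min()
        np.testing.assert_allclose(
            on_axis_profile(dec), on_axis_profile(free) * np.exp(-rel / 50.0), rtol=1e-12
        )


class TestStackIO:
    def test_tiff_round_trip(self, tmp_path, small_config, small_grid):
        src = make_source(0.0, small_config)
        stack = simulate_stack(src, np.ones(small_grid.shape), np.zeros(small_grid.shape),
                               small_config.depths(), 100.0, small_config, grid=small_grid)
        tiff, sidecar = stack.save(tmp_path / "stack.tif")
        back = IntensityStack.load(tiff)
        np.testing.assert_array_equal(back.data, stack.data.astype(np.float32))
        np.testing.assert_allclose(back.z_coords, stack.z_coords)
        assert back.scattering_length == 100.0
        assert back.decay_applied

    def test_invalid_z_coords_rejected(self):
        with pytest.raises(ValueError):
            IntensityStack(np.zeros((3, 4, 4)), np.array([0.0, 2.0, 1.0]), False, np.inf)
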