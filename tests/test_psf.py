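"""Vectorial focusing engine: fields, minima, displacement slopes, contrast."""

import math
import warnings

import numpy as np
import pytest

from phaseplate import (
    OpticalConfig,
    PhaseMask,
    Polarization,
    build_pupil,
    compute_psf,
    contrast,
    focus_field,
    minimum_position,
    phase_to_displacement,
    scan_quality_curves,
)
from phaseplate.psf import (
    MinimumOnBoundaryError,
    _beam_amplitude,
    _mask_modulation,
    _pupil_grid,
    default_polarization,
    minimum_value,
)


@pytest.fixture(scope="module")
def small_config():
    """Reduced pupil sampling for the cross-check against plain DFT sums."""
    return OpticalConfig(pupil_samples=64)


def _direct_dft(pupil, xs, ys, z):
    """Brute-force evaluation of the diffraction sum (oracle for the CZT)."""
    _, _, KX, KY, *_ = _pupil_grid(pupil.config)
    out = np.zeros((3, len(xs), len(ys)), dtype=complex)
    for c in range(3):
        g = pupil.g[c] * np.exp(-1j * pupil.kz * z)
        for i, x in enumerate(xs):
            for j, y in enumerate(ys):
                out[c, i, j] = np.sum(g * np.exp(1j * (KX * x + KY * y)))
    return out


class TestFocusField:
    def test_czt_matches_direct_sum(self, small_config):
        pupil = build_pupil(small_config, PhaseMask.bisected("x"))
        xs = np.arange(-40.0, 41.0, 20.0)
        ys = np.arange(-20.0, 21.0, 20.0)
        got = focus_field(pupil, xs, ys, np.array([30.0]))[:, :, :, 0]
        want = _direct_dft(pupil, xs, ys, 30.0)
        np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-6 * np.abs(want).max())

    def test_airy_reference_max_is_one(self, config):
        pupil = build_pupil(config, PhaseMask.flat())
        stack = compute_psf(pupil, shape=(33, 33, 1), warn_small_grid=False)
        assert stack.data.max() == pytest.approx(1.0, rel=1e-9)
        assert stack.center_value == pytest.approx(1.0, rel=1e-9)

    def test_flat_mask_intensity_independent_of_eom_phase(self, config):
        mask = PhaseMask.flat()
        stacks = [
            compute_psf(build_pupil(config, mask, eom_phase=ph),
                        shape=(9, 9, 1), warn_small_grid=False).data
            for ph in (0.0, 1.0, math.pi)
        ]
        np.testing.assert_allclose(stacks[0], stacks[1], atol=1e-10)
        np.testing.assert_allclose(stacks[0], stacks[2], atol=1e-10)

    def test_energy_conservation_across_masks(self, config):
        # phase-only masks redistribute but do not create or destroy light
        powers = [build_pupil(config, PhaseMask(k)).total_power
                  for k in ("flat", "bisected_x", "tophat", "vortex")]
        np.testing.assert_allclose(powers, powers[0], rtol=1e-2)
        # and the focal-plane integral (full-plane FFT oracle) agrees per mask
        import numpy.fft as fft
        integrals = []
        for kind in ("flat", "bisected_x"):
            pupil = build_pupil(config, PhaseMask(kind))
            pad = 512
            total = 0.0
            for c in range(3):
                G = np.zeros((pad, pad), dtype=complex)
                G[:pupil.g.shape[1], :pupil.g.shape[2]] = pupil.g[c]
                E = fft.ifft2(G) * pad * pad
                total += np.sum(np.abs(E) ** 2)
            integrals.append(total)
        assert integrals[1] == pytest.approx(integrals[0], rel=1e-2)

    def test_bisected_true_zero_at_high_na(self, config):
        pupil = build_pupil(config, PhaseMask.bisected("x"))
        stack = compute_psf(pupil, shape=(33, 1, 1), warn_small_grid=False)
        assert stack.center_value < 1e-6  # units of the Airy max

    def test_vortex_donut_on_axis_zero(self, config):
        pupil = build_pupil(config, PhaseMask.vortex())
        stack = compute_psf(pupil, shape=(17, 17, 1), warn_small_grid=False)
        assert stack.center_value < 1e-6
        assert stack.data.max() > 1e-3  # a donut ring does surround the zero

    def test_bisected_mirror_symmetry(self, config):
        pupil = build_pupil(config, PhaseMask.bisected("x"))
        stack = compute_psf(pupil, shape=(17, 9, 3), warn_small_grid=False)
        np.testing.assert_allclose(stack.data, stack.data[::-1], atol=1e-10)

    def test_tophat_rotational_symmetry(self, config):
        pupil = build_pupil(config, PhaseMask.tophat())
        stack = compute_psf(pupil, shape=(17, 17, 1), warn_small_grid=False)
        quarter = stack.data[:, :, 0]
        np.testing.assert_allclose(quarter, quarter.T, atol=1e-10)
        np.testing.assert_allclose(quarter, quarter[::-1, :], atol=1e-10)

    def test_small_grid_warning(self, config):
        pupil = build_pupil(config, PhaseMask.flat())
        with pytest.warns(UserWarning, match="Airy ring"):
            compute_psf(pupil, shape=(9, 9, 1))

    def test_scalar_limit_at_low_na(self):
        # at NA 0.2 in air the vectorial result collapses onto scalar
        # Fourier optics (the low-NA test-bench regime)
        cfg = OpticalConfig(numerical_aperture=0.2, refractive_index=1.0,
                            pupil_samples=128)
        mask = PhaseMask.bisected("x")
        pupil = build_pupil(cfg, mask)
        xs = np.arange(-4000.0, 4001.0, 250.0)
        vec = np.sum(np.abs(focus_field(pupil, xs, [0.0], [0.0])) ** 2,
                     axis=0)[:, 0, 0]
        _, _, KX, KY, inside, *_ = _pupil_grid(cfg)
        amp = _beam_amplitude(cfg, KX, KY, inside)
        mod, _ = _mask_modulation(cfg, mask, math.pi, KX, KY, inside)
        g = np.where(inside, amp * mod, 0.0)
        scal = np.array([abs(np.sum(g * np.exp(1j * KX * x))) ** 2 for x in xs])
        np.testing.assert_allclose(vec / vec.max(), scal / scal.max(), atol=1e-2)


class TestMinimumAndSlopes:
    def test_bisected_minimum_at_center_for_pi(self, config):
        pupil = build_pupil(config, PhaseMask.bisected("x"))
        stack = compute_psf(pupil, shape=(33, 1, 1), warn_small_grid=False)
        assert abs(minimum_position(stack, "x")) < config.voxel_size_nm / 4

    def test_tophat_minimum_in_focus_for_pi(self, config):
        pupil = build_pupil(config, PhaseMask.tophat())
        stack = compute_psf(pupil, shape=(1, 1, 65), warn_small_grid=False)
        assert abs(minimum_position(stack, "z")) < config.voxel_size_nm / 4

    def test_boundary_minimum_raises(self, config):
        pupil = build_pupil(config, PhaseMask.bisected("x"),
                            eom_phase=math.pi + math.radians(25))
        stack = compute_psf(pupil, shape=(9, 1, 1), warn_small_grid=False)
        with pytest.raises(MinimumOnBoundaryError):
            minimum_position(stack, "x")

    def test_lateral_slope_value(self, lateral_slope):
        assert lateral_slope == pytest.approx(1.4, rel=0.15)

    def test_axial_slope_value(self, axial_slope):
        assert axial_slope == pytest.approx(3.6, rel=0.15)

    def test_minimum_displacement_matches_slope(self, config, lateral_slope):
        # pi + 10 degrees puts the x minimum at slope * 10 (about 14 nm)
        pupil = build_pupil(config, PhaseMask.bisected("x"),
                            eom_phase=math.pi + math.radians(10))
        stack = compute_psf(pupil, shape=(33, 1, 1), warn_small_grid=False)
        pos = minimum_position(stack, "x")
        assert pos == pytest.approx(10 * lateral_slope, rel=0.05)

    def test_displacement_linearity(self, config, lateral_slope):
        for off_deg in (-20.0, -10.0, 10.0, 20.0):
            pupil = build_pupil(config, PhaseMask.bisected("x"),
                                eom_phase=math.pi + math.radians(off_deg))
            stack = compute_psf(pupil, shape=(41, 1, 1), warn_small_grid=False)
            pos = minimum_position(stack, "x")
            assert pos == pytest.approx(off_deg * lateral_slope, rel=0.05)

    def test_slope_doubles_with_wavelength(self, config, lateral_slope):
        cfg2 = OpticalConfig(wavelength_nm=2 * config.wavelength_nm)
        s2 = phase_to_displacement(cfg2, PhaseMask.bisected("x"))
        assert s2 / lateral_slope == pytest.approx(2.0, rel=0.02)

    def test_slope_requires_scan_axis(self, config):
        with pytest.raises(ValueError):
            phase_to_displacement(config, PhaseMask.flat())


class TestContrast:
    def test_ideal_bisected_contrast_below_1e6(self, config):
        pupil = build_pupil(config, PhaseMask.bisected("x"))
        stack = compute_psf(pupil, shape=(17, 1, 1), warn_small_grid=False)
        assert contrast(stack, axis="x") < 1e-6

    def test_flat_mask_contrast_is_reference_max(self, config):
        pupil = build_pupil(config, PhaseMask.flat())
        stack = compute_psf(pupil, shape=(9, 9, 1), warn_small_grid=False)
        assert contrast(stack) == pytest.approx(1.0, rel=1e-9)

    def test_rotated_polarization_fills_the_zero(self, config):
        # 11.5 degrees off boundary-parallel: the axial field component no
        # longer cancels, leaving at least the published 0.6% of the Airy max
        pol = Polarization("linear", math.pi / 2 - math.radians(11.5))
        pupil = build_pupil(config, PhaseMask.bisected("x"), pol)
        stack = compute_psf(pupil, shape=(17, 17, 1), warn_small_grid=False)
        value = contrast(stack, axis="x")
        assert value >= 0.006
        assert value < 0.05  # still a deep, usable minimum

    def test_default_polarizations(self):
        assert default_polarization("tophat").kind == "circular"
        assert default_polarization("bisected_x").angle == pytest.approx(math.pi / 2)
        assert default_polarization("bisected_y").angle == 0.0


@pytest.fixture(scope="module")
def axial_table(config):
    return scan_quality_curves(config, PhaseMask.tophat(),
                               displacements_nm=(0.0, 450.0, 900.0))


class TestScanQuality:
    def test_zero_displacement_has_best_contrast(self, axial_table):
        assert axial_table.contrast.idxmin() == 0

    def test_axial_contrast_degrades_at_900nm(self, axial_table):
        c = axial_table.set_index("displacement_nm").contrast
        assert c[900.0] > c[0.0]

    def test_lateral_steepness_stable_within_50nm(self, config):
        table = scan_quality_curves(config, PhaseMask.bisected("x"),
                                    displacements_nm=(0.0, 25.0, 50.0))
        s0 = table.steepness.iloc[0]
        assert np.all(np.abs(table.steepness - s0) <= 0.2 * s0)

    def test_out_of_range_displacement_truncated(self, config):
        with pytest.warns(UserWarning, match="truncated"):
            table = scan_quality_curves(config, PhaseMask.bisected("x"),
                                        displacements_nm=(0.0, 5000.0))
        assert len(table) == 1


class TestValidation:
    def test_na_must_be_below_index(self):
        with pytest.raises(ValueError):
            OpticalConfig(numerical_aperture=1.5, refractive_index=1.406)

    def test_grid_shape_must_be_odd(self):
        with pytest.raises(ValueError):
            OpticalConfig(grid_shape=(64, 65, 65))

    def test_unknown_mask_kind(self):
        with pytest.raises(ValueError):
            PhaseMask("spiral")

    def test_unequal_spacing_rejected(self, config):
        pupil = build_pupil(config, PhaseMask.flat())
        with pytest.raises(ValueError):
            focus_field(pupil, np.array([0.0, 1.0, 3.0]), [0.0], [0.0])
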