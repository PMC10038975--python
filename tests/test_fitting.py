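"""Bounded NLLS fitting: spectra, water-shift pre-fit, volumes, region stats."""

import numpy as np
import pytest

from cestfit import (
    CESTVolume,
    FitOptions,
    ParameterMaps,
    PoolSpec,
    PoolTable,
    ZSpectrum,
    apply_shift,
    eval_model,
    fit_spectrum,
    fit_volume,
    normalize,
    prefit_water_shift,
    region_stats,
)
from conftest import PHANTOM1_TRUTH, single_pool_table


def left_spectrum(phantom):
    """Noiseless z-spectrum of a left-circle pixel."""
    spec, vol = phantom
    i, j, k = np.argwhere(spec.labels == spec.label_of("left"))[0]
    y = normalize(vol.data[i, j, k], vol.i0[i, j, k])
    return ZSpectrum(vol.offsets, y)


class TestFitSpectrum:
    def test_noiseless_recovery_of_known_composition(self, phantom1_small, table1):
        result = fit_spectrum(left_spectrum(phantom1_small), table1)
        for pool, (a, w, s) in PHANTOM1_TRUTH["left"].items():
            assert result.amplitude(pool) == pytest.approx(a, abs=1e-3)
            assert result.frequency(pool) == pytest.approx(w, abs=1e-2)
            assert result.width(pool) == pytest.approx(s, abs=1e-2)
        assert result.ssq < 1e-10

    def test_already_at_optimum(self, table1):
        offsets = np.linspace(-7, 7, 63)
        y = eval_model(table1.start_vector(), offsets)
        result = fit_spectrum(ZSpectrum(offsets, y), table1)
        assert result.ssq == pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(
            result.params.ravel(), table1.start_vector(), atol=1e-6
        )

    def test_beats_grid_search_oracle(self):
        # the bounded fit must reach at least the best point of a coarse
        # exhaustive lattice over (amplitude, center, width)
        rng = np.random.default_rng(3)
        offsets = np.linspace(-7, 7, 63)
        truth = (0.4, 1.2, 0.9)
        y = eval_model([truth], offsets) + 0.02 * rng.standard_normal(63)
        spectrum = ZSpectrum(offsets, y)
        table = single_pool_table(0.2, 1.0, 1.5)
        best = np.inf
        for a in np.linspace(0.0, 1.0, 21):
            for w in np.linspace(0.0, 2.0, 21):
                for s in np.linspace(0.05, 5.0, 21):
                    phi = np.sum((y - eval_model([(a, w, s)], offsets)) ** 2)
                    best = min(best, phi)
        result = fit_spectrum(spectrum, table)
        assert result.ssq <= best

    def test_bounds_respected_and_objective_decreases(self, table1, rng):
        offsets = np.linspace(-7, 7, 63)
        truth = [v for vals in PHANTOM1_TRUTH["left"].values() for v in vals]
        y = eval_model(np.array(truth).reshape(-1, 3), offsets)
        y = y + 0.05 * rng.standard_normal(63)
        spectrum = ZSpectrum(offsets, y)
        result = fit_spectrum(spectrum, table1)
        lo, hi = table1.bound_vectors()
        x = result.params.ravel()
        assert np.all(x >= lo) and np.all(x <= hi)
        phi_start = np.sum((y - eval_model(table1.start_vector(), offsets)) ** 2)
        assert result.ssq <= phi_start

    def test_ssq_recomputable_from_estimate(self, phantom1_small, table1):
        spectrum = left_spectrum(phantom1_small)
        result = fit_spectrum(spectrum, table1)
        phi = np.sum((spectrum.values - eval_model(result.params, spectrum.offsets)) ** 2)
        assert result.ssq == pytest.approx(phi, rel=1e-12, abs=1e-15)

    def test_iteration_budget_flags_not_raises(self, phantom1_small, table1):
        result = fit_spectrum(
            left_spectrum(phantom1_small), table1, FitOptions(max_iterations=1)
        )
        assert result.converged is False

    def test_integral_consistent_with_fitted_parameters(self, phantom1_small, table1):
        result = fit_spectrum(left_spectrum(phantom1_small), table1)
        for k in range(len(table1)):
            a, _, s = result.params[k]
            assert result.integrals[k] == pytest.approx(a * np.pi * s / 2)


class TestWaterShift:
    def test_centered_spectrum_has_no_shift(self, phantom1_small):
        assert abs(prefit_water_shift(left_spectrum(phantom1_small))) <= 0.01

    def test_displacement_recovered(self, phantom1_small):
        spectrum = left_spectrum(phantom1_small)
        displaced = ZSpectrum(spectrum.offsets + 0.3, spectrum.values)
        assert prefit_water_shift(displaced) == pytest.approx(0.3, abs=0.02)

    def test_fit_invariant_under_displacement(self, phantom1_small, table1):
        spectrum = left_spectrum(phantom1_small)
        base = fit_spectrum(spectrum, table1)
        displaced = ZSpectrum(spectrum.offsets + 0.3, spectrum.values)
        corrected = apply_shift(displaced, prefit_water_shift(displaced))
        result = fit_spectrum(corrected, table1)
        for pool in table1.names:
            assert result.frequency(pool) == pytest.approx(
                base.frequency(pool), abs=0.02
            )

    def test_spectrum_without_water_window_rejected(self):
        with pytest.raises(ValueError, match="0 ppm"):
            prefit_water_shift(ZSpectrum(np.linspace(1, 5, 20), np.zeros(20)))


class TestApplyShift:
    def test_zero_shift_is_identity(self, phantom1_small):
        spectrum = left_spectrum(phantom1_small)
        assert apply_shift(spectrum, 0.0) is spectrum

    def test_involution_on_representable_grid(self):
        # offsets chosen binary-representable so the round trip is exact
        offsets = np.arange(-8.0, 8.5, 0.5)
        spectrum = ZSpectrum(offsets, np.linspace(0, 1, offsets.size))
        back = apply_shift(apply_shift(spectrum, 0.25), -0.25)
        np.testing.assert_array_equal(back.offsets, spectrum.offsets)

    def test_values_never_resampled(self, phantom1_small):
        spectrum = left_spectrum(phantom1_small)
        shifted = apply_shift(spectrum, 0.3172)
        np.testing.assert_array_equal(shifted.values, spectrum.values)


class TestFitVolume:
    def test_noiseless_phantom_maps_match_truth(self, phantom1_small, table1):
        spec, vol = phantom1_small
        maps = fit_volume(vol, table1)
        for region, pools in PHANTOM1_TRUTH.items():
            sel = (spec.labels == spec.label_of(region)) & maps.converged
            assert sel.sum() > 0
            for pool, (a, w, s) in pools.items():
                assert np.abs(maps.amplitude[pool][sel] - a).max() < 1e-3
                assert np.abs(maps.frequency[pool][sel] - w).max() < 1e-2
                assert np.abs(maps.width[pool][sel] - s).max() < 1e-2

    def test_absent_pool_fits_to_zero_amplitude(self, table1):
        # pure-water pixels fitted with an amide pool: amide amplitude ~ 0
        offsets = np.linspace(-7, 7, 63)
        water = eval_model([(0.95, 0.0, 0.5)], offsets)
        data = np.tile(1000 * (1 - water), (4, 4, 1, 1))
        vol = CESTVolume(data=data, i0=np.full((4, 4, 1), 1000.0), offsets=offsets)
        maps = fit_volume(vol, table1)
        assert np.nanmax(maps.amplitude["amide"]) < 1e-3

    def test_empty_volume_fully_masked(self, table1):
        offsets = np.linspace(-7, 7, 63)
        vol = CESTVolume(
            data=np.zeros((4, 4, 1, 63)), i0=np.zeros((4, 4, 1)), offsets=offsets
        )
        maps = fit_volume(vol, table1)
        assert not maps.fitted.any()
        assert np.isnan(maps.ssq).all()

    def test_unknown_method_rejected(self, phantom1_small, table1):
        with pytest.raises(ValueError, match="preprocess"):
            fit_volume(phantom1_small[1], table1, preprocess="median")


def tiny_maps(values):
    """1-pool ParameterMaps over a flat array of amplitudes (all converged)."""
    arr = np.asarray(values, dtype=float)[:, None, None]
    ones = np.ones_like(arr)
    return ParameterMaps(
        pool_names=("p",),
        amplitude={"p": arr},
        frequency={"p": ones},
        width={"p": ones},
        integral={"p": ones},
        ssq=np.zeros_like(arr),
        converged=np.ones_like(arr, dtype=bool),
        fitted=np.ones_like(arr, dtype=bool),
        water_shift=np.zeros_like(arr),
    )


class TestRegionStats:
    def test_constant_region_has_zero_sd(self):
        maps = tiny_maps([0.2, 0.2, 0.2])
        labels = np.ones((3, 1, 1), dtype=int)
        stats = region_stats(maps, labels)
        row = stats[(stats.pool == "p") & (stats.parameter == "amplitude")]
        assert row["sd"].item() == pytest.approx(0.0, abs=1e-12)

    def test_two_pixel_hand_calculation(self):
        maps = tiny_maps([0.1, 0.3])
        labels = np.ones((2, 1, 1), dtype=int)
        stats = region_stats(maps, labels)
        row = stats[(stats.pool == "p") & (stats.parameter == "amplitude")]
        assert row["mean"].item() == pytest.approx(0.2)
        # sample SD of {0.1, 0.3}: sqrt(((0.1-0.2)^2+(0.3-0.2)^2)/1)
        assert row["sd"].item() == pytest.approx(np.sqrt(0.02))

    def test_region_without_converged_pixels_gives_nan(self):
        maps = tiny_maps([0.1, 0.3])
        maps.converged[:] = False
        labels = np.ones((2, 1, 1), dtype=int)
        stats = region_stats(maps, labels)
        row = stats[(stats.pool == "p") & (stats.parameter == "amplitude")]
        assert np.isnan(row["mean"].item()) and row["count"].item() == 0

    def test_includes_regional_ssq_quality_rows(self):
        maps = tiny_maps([0.1, 0.3])
        labels = np.ones((2, 1, 1), dtype=int)
        stats = region_stats(maps, labels)
        assert ((stats.pool == "(global)") & (stats.parameter == "ssq")).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="label shape"):
            region_stats(tiny_maps([0.1]), np.ones((5, 5, 1), dtype=int))
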