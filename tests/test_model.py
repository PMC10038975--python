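"""Lorentzian model mathematics: line shapes, Jacobian, integrals."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from cestfit import (
    PoolSpec,
    PoolTable,
    ZSpectrum,
    design_matrix,
    eval_model,
    jacobian,
    normalize,
    pool_integral,
    residuals,
)
from conftest import PHANTOM1_TRUTH, random_pools


def lorentzian_sum_oracle(pools, offsets):
    """Independent scalar-loop implementation of the sum-of-Lorentzians."""
    out = np.zeros(len(offsets))
    for i, w in enumerate(offsets):
        total = 0.0
        for a, wc, s in pools:
            total += a / (1.0 + 4.0 * ((w - wc) / s) ** 2)
        out[i] = total
    return out


class TestNormalize:
    def test_no_saturation_gives_zero(self):
        assert np.allclose(normalize(np.array([10.0, 10.0, 10.0]), 10.0), 0.0)

    def test_water_suppression_level(self):
        # a 95% signal drop corresponds to y = 0.95
        assert normalize(np.array([0.05 * 800.0]), 800.0) == pytest.approx([0.95])

    def test_round_trip(self, rng):
        i0 = 1234.5
        intensities = rng.uniform(0, i0, 50)
        y = normalize(intensities, i0)
        np.testing.assert_allclose(i0 * (1 - y), intensities, rtol=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_invalid_reference_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize(np.array([1.0]), bad)


class TestEvalModel:
    def test_peak_equals_amplitude_at_center(self):
        assert eval_model([(0.3, 3.5, 0.5)], np.array([3.5]))[0] == pytest.approx(0.3)

    def test_width_is_fwhm(self):
        y = eval_model([(0.3, 3.5, 0.5)], np.array([3.25, 3.75]))
        np.testing.assert_allclose(y, 0.15, rtol=1e-14)

    def test_matches_handcoded_oracle_on_phantom_composition(self):
        pools = list(PHANTOM1_TRUTH["left"].values())
        grid = np.linspace(-8, 8, 1001)
        np.testing.assert_allclose(
            eval_model(pools, grid), lorentzian_sum_oracle(pools, grid),
            atol=1e-12,
        )

    def test_zero_pools_gives_zeros(self):
        assert np.all(eval_model(np.empty((0, 3)), np.linspace(-5, 5, 7)) == 0)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            eval_model([(0.3, 0.0, 0.0)], np.array([0.0]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=1, max_value=6), st.integers(0, 2**31 - 1))
    def test_linearity_in_amplitudes(self, k, seed):
        # the model is exactly the design matrix applied to the amplitudes
        pools = random_pools(np.random.default_rng(seed), k)
        offsets = np.linspace(-7, 7, 41)
        psi = design_matrix(pools, offsets)
        np.testing.assert_allclose(
            psi @ pools[:, 0], eval_model(pools, offsets), rtol=1e-13, atol=1e-15
        )


class TestResiduals:
    def test_exact_model_gives_zero_residuals(self, rng):
        pools = random_pools(rng, 3)
        offsets = np.linspace(-6, 6, 30)
        spectrum = ZSpectrum(offsets, eval_model(pools, offsets))
        assert np.abs(residuals(pools, spectrum)).max() < 1e-15

    def test_zero_amplitudes_return_signal(self, rng):
        offsets = np.linspace(-6, 6, 30)
        y = rng.random(30)
        pools = np.array([[0.0, 1.0, 0.5]])
        np.testing.assert_array_equal(residuals(pools, ZSpectrum(offsets, y)), y)

    def test_objective_matches_brute_force(self, rng):
        # brute-force objective: loop over points, accumulate squared misfit
        pools = np.array([[0.3, 1.0, 0.8]])
        offsets = np.linspace(-5, 5, 25)
        spectrum = ZSpectrum(offsets, eval_model(pools, offsets))
        perturbed = pools + np.array([[0.07, 0.0, 0.0]])
        phi_brute = sum(
            (spectrum.values[i] - lorentzian_sum_oracle(perturbed, [w])[0]) ** 2
            for i, w in enumerate(offsets)
        )
        phi = float(np.sum(residuals(perturbed, spectrum) ** 2))
        assert phi == pytest.approx(phi_brute, abs=1e-12)

    def test_objective_invariant_under_pool_reordering(self, rng):
        pools = random_pools(rng, 4)
        offsets = np.linspace(-7, 7, 63)
        y = rng.random(63)
        spectrum = ZSpectrum(offsets, y)
        phi1 = np.sum(residuals(pools, spectrum) ** 2)
        phi2 = np.sum(residuals(pools[::-1], spectrum) ** 2)
        assert phi1 == pytest.approx(phi2, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ZSpectrum(np.linspace(-1, 1, 5), np.zeros(4))


class TestDesignMatrix:
    def test_single_pool_center_row_is_one(self):
        offsets = np.array([-1.0, 0.0, 1.0, 3.5, 5.0])
        psi = design_matrix([(0.5, 3.5, 0.5)], offsets)
        assert psi.shape == (5, 1)
        assert psi[3, 0] == pytest.approx(1.0)

    def test_full_rank_on_default_grid(self):
        # phantom-2 composition: six distinguishable lines on the 63-point grid
        from conftest import PHANTOM2_TRUTH

        pools = list(PHANTOM2_TRUTH["np"].values())
        psi = design_matrix(pools, np.linspace(-7, 7, 63))
        assert np.linalg.matrix_rank(psi) == 6


class TestJacobian:
    def test_center_is_stationary_in_position_and_width(self):
        J = jacobian([(0.4, 2.0, 1.0)], np.array([2.0]))
        np.testing.assert_allclose(J[0], [1.0, 0.0, 0.0], atol=1e-15)

    def test_zero_amplitude_kills_shape_derivatives(self):
        J = jacobian([(0.0, 2.0, 1.0)], np.linspace(-5, 5, 21))
        assert np.all(J[:, 1] == 0) and np.all(J[:, 2] == 0)

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(7)
        offsets = np.linspace(-7, 7, 63)
        h = 1e-6
        for _ in range(100):
            pools = random_pools(rng, rng.integers(1, 5))
            x = pools.ravel()
            J = jacobian(x, offsets)
            for col in range(x.size):
                xp, xm = x.copy(), x.copy()
                xp[col] += h
                xm[col] -= h
                fd = (eval_model(xp, offsets) - eval_model(xm, offsets)) / (2 * h)
                scale = max(np.abs(fd).max(), 1e-12)
                assert np.abs(J[:, col] - fd).max() / scale < 1e-5


class TestPoolIntegral:
    def test_zero_amplitude(self):
        assert pool_integral(0.0, 1.0) == 0.0

    def test_matches_quadrature(self):
        a, s = 0.3, 0.5
        num, _ = quad(lambda w: a / (1 + 4 * (w / s) ** 2), -np.inf, np.inf,
                      limit=200)
        assert pool_integral(a, s) == pytest.approx(num, rel=1e-6)

    def test_linear_in_width(self):
        assert pool_integral(0.2, 2.0) == pytest.approx(2 * pool_integral(0.2, 1.0))

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            pool_integral(0.1, 0.0)


class TestTypes:
    def test_start_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            PoolSpec("p", 0.9, 0.0, 0.5, 0, -1, 1, 1, 0.1, 2)

    def test_zero_width_lower_bound_rejected(self):
        with pytest.raises(ValueError, match="width lower bound"):
            PoolSpec("p", 0.5, 0.0, 1.0, 0, -1, 1, 1, 0.0, 2)

    def test_duplicate_pool_names_rejected(self):
        p = PoolSpec("p", 0.5, 0.0, 1.0, 0, -1, 1, 1, 0.1, 2)
        with pytest.raises(ValueError, match="duplicate"):
            PoolTable([p, p])

    def test_unsorted_offsets_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            ZSpectrum(np.array([0.0, -1.0, 1.0]), np.zeros(3))

    def test_dof_guard(self):
        spectrum = ZSpectrum(np.linspace(-1, 1, 5), np.zeros(5))
        with pytest.raises(ValueError, match="pools"):
            spectrum.check_dof(2)
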