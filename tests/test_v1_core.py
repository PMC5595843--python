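"""Unit and property tests of the tuning and conductance primitives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from tiltcsf.v1_core import (
    ConnectionWidths,
    FixedParams,
    PopulationGrid,
    conductances_closed_form_tilt,
    conductances_numeric,
    contrast_response,
    default_orientation_grid,
    firing_rate,
    first_layer_response,
    half_amplitude_constant,
    membrane_derivative,
    orientation_tuning,
    population_rates,
    sf_tuning,
    steady_state_voltage,
    wrapped_gaussian_sum,
)


class TestGrids:
    def test_default_grid_matches_sampling_conventions(self):
        g = PopulationGrid()
        assert g.orientations.size == 90 and g.orientation_spacing == 2.0
        assert g.sfs[0] == 0.5 and g.sfs[-1] == 64.0
        assert np.allclose(np.diff(np.log2(g.sfs)), 0.25)

    def test_semisaturations_above_limit_are_pruned(self):
        g = PopulationGrid(contrast_semisaturations=np.array([0.1, 999.0, 1001.0]))
        assert g.contrast_semisaturations.max() <= 1000.0
        assert 0.1 in g.contrast_semisaturations

    @pytest.mark.parametrize("bad", [
        np.arange(-90.0, 88.0, 2.0),          # does not close the period
        np.array([0.5, 1.0, 1.9]),            # not log2-equispaced (as sfs)
    ])
    def test_malformed_grids_rejected(self, bad):
        with pytest.raises(ValueError):
            if bad[0] < 0:
                PopulationGrid(orientations=bad)
            else:
                PopulationGrid(sfs=bad)

    def test_connection_widths_are_half_the_tuning_widths(self):
        w = ConnectionWidths.from_tuning(sigma_theta=20.0, sigma_sf=1.0)
        assert w.sigma_theta_cs == 10.0 and w.sigma_sf_cs == 0.5

    def test_reversal_potential_ordering_enforced(self):
        with pytest.raises(ValueError):
            FixedParams(v_i=0.5)


class TestOrientationTuning:
    def test_peak_and_periodicity(self):
        assert orientation_tuning(37.0, 37.0, 15.0) == pytest.approx(1.0)
        assert orientation_tuning(37.0 + 180.0, 37.0, 15.0) == pytest.approx(1.0)

    def test_one_width_from_peak_matches_explicit_wrap_sum(self):
        # small width: wrap terms negligible, value ~ exp(-1/2)
        sigma = 8.0
        val = orientation_tuning(sigma, 0.0, sigma)
        explicit = sum(np.exp(-0.5 * ((sigma + 180.0 * k) / sigma) ** 2)
                       for k in range(-2, 3))
        explicit /= sum(np.exp(-0.5 * ((180.0 * k) / sigma) ** 2)
                        for k in range(-2, 3))
        assert val == pytest.approx(explicit, rel=1e-12)
        assert val == pytest.approx(np.exp(-0.5), rel=1e-9)

    @given(st.floats(-500, 500), st.floats(-89, 89),
           st.floats(2.0, 40.0))
    @settings(max_examples=50, deadline=None)
    def test_bounded_and_periodic(self, theta, theta_i, sigma):
        v = orientation_tuning(theta, theta_i, sigma)
        # mathematically in (0, 1]; far tails may underflow to exactly 0
        assert 0.0 <= v <= 1.0 + 1e-12
        assert v == pytest.approx(
            orientation_tuning(theta + 180.0, theta_i, sigma), rel=1e-12)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            orientation_tuning(0.0, 0.0, 0.0)


class TestSFTuning:
    def test_peak_octave_and_log_symmetry(self):
        assert sf_tuning(4.0, 4.0, 1.0) == pytest.approx(1.0)
        assert sf_tuning(8.0, 4.0, 1.0) == pytest.approx(np.exp(-0.5))
        assert sf_tuning(2.0, 4.0, 1.0) == pytest.approx(sf_tuning(8.0, 4.0, 1.0))

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            sf_tuning(-1.0, 4.0, 1.0)


class TestContrastResponse:
    def test_semisaturation_definition(self):
        assert contrast_response(0.3, 0.3, n=2.0, normalized=False) == pytest.approx(0.5)

    def test_normalized_is_one_at_full_contrast(self):
        for ck in [0.01, 0.3, 5.0, 900.0]:
            assert contrast_response(1.0, ck, n=2.0) == pytest.approx(1.0)

    def test_zero_contrast_gives_zero(self):
        assert contrast_response(0.0, 0.5) == 0.0

    def test_monotone_in_contrast(self):
        c = np.linspace(0, 1, 50)
        r = contrast_response(c, 0.2)
        assert np.all(np.diff(r) >= 0)

    @given(st.floats(1e-3, 100.0), st.floats(0.5, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_half_amplitude_identity(self, ck, n):
        """Normalised response at c_1/2 is exactly half the response at c=1."""
        c_half = half_amplitude_constant(ck, n)
        r_half = contrast_response(min(c_half, 1.0), ck, n, normalized=True)
        assert r_half == pytest.approx(0.5, abs=1e-9)

    def test_half_amplitude_closed_form_values(self):
        assert half_amplitude_constant(1.0, 2.0) == pytest.approx(np.sqrt(1.0 / 3.0))
        # limits: c_k -> 0 gives c_1/2 -> c_k; c_k -> inf gives sqrt(1/2)
        assert half_amplitude_constant(1e-6, 2.0) == pytest.approx(1e-6, rel=1e-5)
        assert half_amplitude_constant(1e6, 2.0) == pytest.approx(np.sqrt(0.5), rel=1e-6)


class TestFirstLayer:
    def test_separable_product(self, fixed):
        r = first_layer_response(10.0, 3.0, 0.4, theta_i=4.0, f_j=2.0,
                                 c_k=0.3, sigma_theta=15.0)
        expected = (fixed.A * orientation_tuning(10.0, 4.0, 15.0)
                    * sf_tuning(3.0, 2.0, 1.0)
                    * contrast_response(0.4, 0.3))
        assert r == pytest.approx(expected)

    def test_preferred_stimulus_at_full_contrast_fires_at_A(self, fixed):
        r = first_layer_response(4.0, 2.0, 1.0, theta_i=4.0, f_j=2.0, c_k=0.3)
        assert r == pytest.approx(fixed.A)

    def test_zero_contrast_silences(self):
        assert first_layer_response(4.0, 2.0, 0.0, 4.0, 2.0, 0.3) == 0.0


class TestSecondLayer:
    def test_steady_state_closed_forms(self, fixed):
        assert steady_state_voltage(0.0, 0.0) == 0.0
        g = 1.7
        assert steady_state_voltage(g, 0.0) == pytest.approx(
            fixed.v_e * g / (1.0 + g))

    def test_voltage_bounded_by_reversals(self, fixed, rng):
        g_e = rng.uniform(0, 50, 200)
        g_i = rng.uniform(0, 50, 200)
        v = steady_state_voltage(g_e, g_i)
        assert np.all(v <= fixed.v_e) and np.all(v >= fixed.v_i)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            steady_state_voltage(-0.1, 0.0)

    def test_steady_state_is_fixed_point_of_membrane_dynamics(self, fixed, rng):
        """Forward integration of the membrane equation from rest converges
        to the closed-form steady state."""
        for _ in range(5):
            g_e, g_i = rng.uniform(0, 5, 2)
            sol = solve_ivp(
                lambda _, v: membrane_derivative(v, g_e, g_i, fixed),
                (0.0, 200.0 * fixed.tau), [0.0], rtol=1e-10, atol=1e-12)
            assert sol.y[0, -1] == pytest.approx(
                steady_state_voltage(g_e, g_i, fixed), abs=1e-8)

    def test_firing_rate_rectification(self, fixed):
        assert firing_rate(fixed.T) == 0.0
        assert firing_rate(fixed.T + 1.0) == pytest.approx(fixed.m)
        assert firing_rate(fixed.T - 5.0) == 0.0


class TestConductances:
    def test_closed_form_matches_grid_summation(self, orientation_grid, rng):
        """Gaussian-convolution closed form vs direct numeric summation,
        50 random draws, relative error below 1e-6."""
        for _ in range(50):
            sigma = rng.uniform(6.0, 38.0)
            theta_c = rng.uniform(-85.0, 85.0)
            theta_s = rng.uniform(-85.0, 85.0)
            I_inh = rng.uniform(0.01, 1.0)
            ge_n, gi_n = conductances_numeric(
                orientation_grid, theta_c, theta_s, sigma, I_inh)
            ge_c, gi_c = conductances_closed_form_tilt(
                orientation_grid, theta_c, theta_s, sigma, I_inh)
            assert np.max(np.abs(ge_n - ge_c) / ge_c) < 1e-6
            assert np.max(np.abs(gi_n - gi_c) / gi_c) < 1e-6

    def test_no_inhibition_without_surround_drive(self, orientation_grid):
        _, g_i = conductances_numeric(orientation_grid, 0.0, 30.0, 20.0, 0.0)
        assert np.all(g_i == 0.0)
        _, g_i = conductances_numeric(orientation_grid, 0.0, 30.0, 20.0, 0.5,
                                      surround_amplitude=0.0)
        assert np.all(g_i == 0.0)

    def test_inhibition_linear_in_strength(self, orientation_grid):
        _, g1 = conductances_numeric(orientation_grid, 0.0, 15.0, 20.0, 0.2)
        _, g2 = conductances_numeric(orientation_grid, 0.0, 15.0, 20.0, 0.4)
        assert np.allclose(g2, 2.0 * g1)

    def test_excitation_peaks_at_centre_and_is_symmetric(self, orientation_grid):
        g_e, _ = conductances_closed_form_tilt(orientation_grid, 10.0, 40.0,
                                               20.0, 0.1)
        assert orientation_grid[np.argmax(g_e)] == 10.0
        # symmetry about the centre orientation
        idx = np.argsort(np.abs(((orientation_grid - 10.0 + 90) % 180) - 90))
        pairs = np.abs(((orientation_grid - 10.0 + 90) % 180) - 90)
        for d in (10.0, 20.0, 30.0):
            vals = g_e[np.isclose(pairs, d)]
            assert np.allclose(vals, vals[0], rtol=1e-9)

    def test_rates_nonnegative_and_shift_invariant(self, orientation_grid, fixed):
        g_e, g_i = conductances_closed_form_tilt(orientation_grid, 0.0, 15.0,
                                                 20.0, 0.3)
        rates = population_rates(g_e, g_i, fixed)
        assert np.all(rates >= 0.0)
        # a global 180 deg shift of all orientations is the same stimulus
        g_e2, g_i2 = conductances_closed_form_tilt(
            orientation_grid + 180.0, 0.0, 15.0, 20.0, 0.3)
        assert np.allclose(population_rates(g_e2, g_i2, fixed), rates)

    def test_wrap_truncation_error_negligible(self):
        assert wrapped_gaussian_sum(0.0, 40.0, n_wraps=2) == pytest.approx(
            wrapped_gaussian_sum(0.0, 40.0, n_wraps=6), abs=1e-12)
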