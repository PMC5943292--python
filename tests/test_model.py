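"""Kinetic model: rate equations, steady states, endpoint scaling, crossover."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from droptxtl import (
    KineticState,
    ModelParams,
    crossover_radius,
    endpoint_protein,
    integrate_kinetics,
    local_log_slope,
    ode_rhs,
    plasmid_copy_number,
    regime_curve,
    sphere_volume_pl,
    sphere_volume_um3,
    steady_state_mrna,
)


class TestOdeRhs:
    def test_zero_state_produces_only_transcription(self, params):
        dr, drs, dc = ode_rhs(KineticState(0.0, 0.0, 0.0, 0.0), 12.0, params)
        assert dr == params.k_R
        assert drs == 0.0
        assert dc == 0.0

    def test_unregulated_steady_state_is_stationary(self, params):
        p = params.replace(k_on=0.0)
        dr, drs, dc = ode_rhs(KineticState(0.0, p.r0, 0.0, 0.0), 20.0, p)
        assert dr == pytest.approx(0.0, abs=1e-15)
        assert drs == 0.0
        assert dc == pytest.approx(p.alpha * p.r0)

    def test_reference_values_at_unit_concentrations(self, params):
        # hand-evaluated: 3λ/R = 0.009 at R = 10 μm, r = r* = 1
        dr, drs, dc = ode_rhs(KineticState(0.0, 1.0, 1.0, 0.0), 10.0, params)
        assert dr == pytest.approx(3.22e-3 - 9e-3 + 3.86e-3 - 1.39e-3, rel=1e-12)
        assert drs == pytest.approx(9e-3 - 3.86e-3 - 1.39e-3, rel=1e-12)
        assert dc == pytest.approx(9.02 + 0.196, rel=1e-12)

    def test_nonpositive_radius_rejected(self, params):
        with pytest.raises(ValueError, match="radius"):
            ode_rhs(KineticState(0.0, 0.0, 0.0, 0.0), 0.0, params)


class TestSteadyState:
    def test_no_exchange_gives_r0(self, params):
        assert steady_state_mrna(8.0, params.replace(k_on=0.0)) == (params.r0, 0.0)

    def test_large_droplet_limit_approaches_r0(self, params):
        r_bar, rs_bar = steady_state_mrna(1e9, params)
        assert r_bar == pytest.approx(params.r0, rel=1e-6)
        assert rs_bar == pytest.approx(0.0, abs=1e-6 * params.r0)

    def test_half_depletion_at_crossover_radius(self, params):
        # at R = R_c the surface term equals 1, so r̄ = r₀/2
        R_c = crossover_radius(params)
        r_bar, _ = steady_state_mrna(R_c, params)
        assert r_bar == pytest.approx(params.r0 / 2.0, rel=1e-12)

    def test_production_balances_degradation(self, params):
        # stationarity: k_R = γ_R·r̄ + γ*_R·r̄* (per unit volume)
        for R in [5.0, 17.14, 40.0]:
            r_bar, rs_bar = steady_state_mrna(R, params)
            total_deg = params.gamma_R * r_bar + params.gamma_R_star * rs_bar
            assert total_deg == pytest.approx(params.k_R, rel=1e-12)


class TestIntegration:
    def test_unregulated_mrna_relaxes_to_r0(self, params):
        p = params.replace(k_on=0.0)
        traj = integrate_kinetics(10.0, p, t_end=10.0 / p.gamma_R)
        assert traj[-1].r == pytest.approx(p.r0, rel=1e-4)

    def test_mrna_converges_to_closed_form(self, params):
        traj = integrate_kinetics(10.0, params, t_end=10.0 / params.gamma_R)
        r_bar, rs_bar = steady_state_mrna(10.0, params)
        assert traj[-1].r == pytest.approx(r_bar, rel=0.01)
        assert traj[-1].r_star == pytest.approx(rs_bar, rel=0.01)

    def test_protein_slope_matches_linear_accumulation_rate(self, params):
        # after the mRNA transient, dc/dt equals the steady synthesis rate
        traj = integrate_kinetics(10.0, params, t_end=params.T_s)
        r_bar, rs_bar = steady_state_mrna(10.0, params)
        rate = params.alpha * r_bar + params.alpha_star * rs_bar
        tail = [s for s in traj if s.t >= 0.6 * params.T_s]
        slope = (tail[-1].c - tail[0].c) / (tail[-1].t - tail[0].t)
        assert slope == pytest.approx(rate, rel=0.02)

    def test_quasi_steady_start_reproduces_endpoint(self, params):
        # protein from c(0)=0 with mRNA at steady state accumulates linearly,
        # so c(T_s)·V equals the closed-form endpoint
        traj = integrate_kinetics(10.0, params, t_end=params.T_s,
                                  mrna_at_steady_state=True)
        cV = traj[-1].c * sphere_volume_um3(10.0)
        assert cV == pytest.approx(endpoint_protein(10.0, params), rel=1e-6)

    def test_state_is_physical_and_protein_monotone(self, params):
        traj = integrate_kinetics(7.0, params, t_end=params.T_s)
        c = np.array([s.c for s in traj])
        assert all(s.r >= 0 and s.r_star >= 0 for s in traj)
        assert np.all(np.diff(c) >= 0)


class TestEndpointAndRegimes:
    def test_no_translation_means_no_protein(self, params):
        p = params.replace(alpha=0.0, alpha_star=0.0)
        assert endpoint_protein(10.0, p) == 0.0

    def test_unregulated_endpoint_is_exact_cube_law(self, params):
        p = params.replace(k_on=0.0)
        for R in [5.0, 20.0, 50.0]:
            expected = sphere_volume_um3(R) * p.r0 * p.alpha * p.T_s
            assert endpoint_protein(R, p) == pytest.approx(expected, rel=1e-12)

    def test_repression_curve_is_endpoint_with_surface_translation_off(self, params):
        for R in [3.0, 17.0, 60.0]:
            assert regime_curve(R, params, "repression") == pytest.approx(
                endpoint_protein(R, params.replace(alpha_star=0.0)), rel=1e-12
            )

    def test_repression_approaches_cube_law_for_large_droplets(self, params):
        R = 1e4 * crossover_radius(params)
        cube = 4.0 / 3.0 * math.pi * params.r0 * params.alpha * params.T_s * R**3
        assert regime_curve(R, params, "repression") == pytest.approx(cube, rel=1e-3)

    def test_activation_approaches_cube_law_for_small_droplets(self, params):
        R = 1e-4 * crossover_radius(params)
        slope = local_log_slope(lambda r: regime_curve(r, params, "activation"), R)
        assert slope == pytest.approx(3.0, abs=1e-3)

    def test_unknown_regime_rejected(self, params):
        with pytest.raises(ValueError, match="regime"):
            regime_curve(10.0, params, "sideways")


class TestLogSlope:
    def test_exact_cube_law(self):
        assert local_log_slope(lambda R: R**3, 12.3) == pytest.approx(3.0, abs=1e-9)

    def test_repression_slope_at_crossover_is_three_and_a_half(self, params):
        # d ln(R⁴/(R + R_c))/d ln R = 4 − R/(R + R_c) = 3.5 at R = R_c
        R_c = crossover_radius(params)
        slope = local_log_slope(lambda R: regime_curve(R, params, "repression"), R_c)
        assert slope == pytest.approx(3.5, abs=1e-6)

    def test_limiting_exponents(self, params):
        R_c = crossover_radius(params)
        rep = lambda R: regime_curve(R, params, "repression")
        act = lambda R: regime_curve(R, params, "activation")
        assert local_log_slope(rep, 1e-3 * R_c) == pytest.approx(4.0, abs=1e-2)
        assert local_log_slope(act, 1e3 * R_c) == pytest.approx(2.0, abs=1e-2)

    def test_repression_slope_strictly_decreasing_within_bounds(self, params):
        rep = lambda R: regime_curve(R, params, "repression")
        radii = np.logspace(-2, 4, 40) * crossover_radius(params)
        slopes = np.array([local_log_slope(rep, R) for R in radii])
        assert np.all(np.diff(slopes) < 0)
        assert np.all((slopes > 3.0) & (slopes < 4.0))

    def test_activation_slope_strictly_decreasing_within_bounds(self, params):
        act = lambda R: regime_curve(R, params, "activation")
        radii = np.logspace(-2, 4, 40) * crossover_radius(params)
        slopes = np.array([local_log_slope(act, R) for R in radii])
        assert np.all(np.diff(slopes) < 0)
        assert np.all((slopes > 2.0) & (slopes < 3.0))

    def test_nonpositive_curve_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            local_log_slope(lambda R: -1.0, 1.0)


class TestCrossover:
    def test_reference_value_is_about_17_um(self, params):
        assert crossover_radius(params) == pytest.approx(17.142857, abs=1e-5)
        assert round(crossover_radius(params)) == 17

    def test_linear_in_attachment_rate(self, params):
        assert crossover_radius(params.replace(k_on=2.0)) == pytest.approx(
            2.0 * crossover_radius(params), rel=1e-12
        )

    def test_surface_term_is_unity_at_crossover(self, params):
        R_c = crossover_radius(params)
        assert (3.0 * params.lam / R_c) * (params.theta / params.tau) == pytest.approx(
            1.0, rel=1e-12
        )

    def test_undefined_without_exchange(self, params):
        with pytest.raises(ValueError, match="k_on"):
            crossover_radius(params.replace(k_on=0.0))


class TestCopyNumber:
    def test_zero_concentration(self):
        assert plasmid_copy_number(0.0, 5.0) == 0.0

    def test_five_micron_droplet_volume_rounds_to_half_picolitre(self):
        assert sphere_volume_pl(5.0) == pytest.approx(0.5236, abs=1e-4)
        assert round(sphere_volume_pl(5.0), 1) == 0.5

    def test_template_count_is_around_a_thousand(self):
        # 3.5e-9 mol/L × 523.6e-15 L × N_A = 1103.6
        count = plasmid_copy_number(3.5, 5.0)
        assert count == pytest.approx(1103.6, abs=0.5)
        assert count == pytest.approx(1000.0, rel=0.2)


class TestParams:
    def test_unit_conversion_from_config(self, params):
        p = ModelParams.from_mapping(
            {"k_R": 3.22e-3, "k_on": 1.0, "k_off": 3.86e-3, "gamma_R": 1.39e-3,
             "gamma_R_star": 1.39e-3, "alpha": 9.02, "alpha_star": 0.196,
             "T_s_min": 153, "lambda_nm": 30}
        )
        assert p == params

    def test_reference_config_file_loads_to_reference_set(self, params):
        from pathlib import Path

        path = Path(__file__).resolve().parents[1] / "config" / "reference_params.yaml"
        assert ModelParams.from_file(path) == params

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(k_R=0.0, k_on=1.0, k_off=1e-3, gamma_R=1e-3,
                        gamma_R_star=1e-3, alpha=1.0, alpha_star=0.1, T_s=100.0)

    @given(
        k_on=st.floats(0.01, 100.0),
        k_off=st.floats(1e-5, 1.0),
        gamma=st.floats(1e-5, 1.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_derived_quantities_finite_when_exchange_present(self, k_on, k_off, gamma):
        p = ModelParams(k_R=1e-3, k_on=k_on, k_off=k_off, gamma_R=gamma,
                        gamma_R_star=gamma, alpha=1.0, alpha_star=0.1, T_s=100.0)
        assert math.isfinite(p.r0) and math.isfinite(p.theta) and math.isfinite(p.tau)
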