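"""Polytropic index, stiffness, damping decomposition and scattering."""
import math
from dataclasses import replace

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deepbubble import (
    BubbleSpec,
    complex_polytropic_index,
    damping,
    minnaert_frequency,
    minnaert_omega,
    omega0_squared,
    perturbed_specs,
    scattering_cross_section,
    stiffness,
    thermal_state,
)
from deepbubble.bubble_core import TWO_PI, epsilon
from deepbubble.resonance_solvers import solve_undamped

from conftest import ENV_NAMES


def gamma_oracle(gamma: float, X: float) -> complex:
    """Arbitrary-precision (50-digit) evaluation of the polytropic index."""
    with mpmath.workdps(50):
        z = (1 + 1j) * mpmath.mpf(X) / 2
        t = z / mpmath.tanh(z) - 1
        val = gamma / (1 - t * 6j * (gamma - 1) / mpmath.mpf(X) ** 2)
        return complex(val)


class TestMinnaert:
    def test_hand_evaluated_example(self, make_spec):
        # sqrt(3 * 1.401 * 101325 / 1028) / 0.01 / (2 pi)
        spec = make_spec("warm_surface", "N2", 0.01)
        assert minnaert_frequency(spec) == pytest.approx(323.9378, rel=1e-6)

    def test_scaling_with_radius_and_pressure(self, make_spec):
        spec = make_spec("cold_surface", "N2", 0.02)
        double_r = make_spec("cold_surface", "N2", 0.04)
        assert minnaert_omega(double_r) == pytest.approx(
            0.5 * minnaert_omega(spec), rel=1e-14
        )
        quad_p = BubbleSpec(
            R0=0.02,
            env=replace(spec.env, pressure_Pa=4 * spec.env.pressure_Pa),
            gas=spec.gas,
        )
        assert minnaert_omega(quad_p) == pytest.approx(
            2.0 * minnaert_omega(spec), rel=1e-14
        )


class TestPolytropicIndex:
    @settings(derandomize=True, max_examples=40)
    @given(gamma=st.floats(1.3, 2.0))
    def test_isothermal_and_adiabatic_limits(self, gamma):
        assert abs(complex_polytropic_index(gamma, 1e-8) - 1.0) < 1e-6
        assert abs(complex_polytropic_index(gamma, 1e8) - gamma) < 1e-6

    @pytest.mark.parametrize("X", [1e-4, 5e-4, 1e-3, 0.01, 0.5, 1.0, 10.0, 35.0, 40.0, 45.0, 300.0, 1e4])
    def test_matches_arbitrary_precision_oracle(self, X):
        got = complex_polytropic_index(1.4, X)
        want = gamma_oracle(1.4, X)
        assert got == pytest.approx(want, rel=1e-12)

    def test_imaginary_part_nonnegative_and_real_part_bounded(self):
        for X in np.geomspace(1e-3, 1e5, 60):
            g = complex_polytropic_index(1.76, X)
            assert g.imag >= -1e-15
            assert 1.0 - 1e-9 <= g.real <= 1.76 + 1e-9

    def test_surface_bubbles_are_near_adiabatic_at_audio_frequency(self, make_spec):
        # D_p ~ 2e-5 m^2/s at the surface gives X of order 1e2 at audio
        # frequencies, so Re Gamma sits close to gamma
        spec = make_spec("warm_surface", "N2", 0.01)
        ts = thermal_state(spec, TWO_PI * 324.0)
        assert 10 <= ts.X <= 1e3
        assert ts.Gamma.real > 0.98 * spec.gas.gamma

    def test_rejects_nonpositive_frequency(self, make_spec):
        spec = make_spec("warm_surface", "N2", 0.01)
        with pytest.raises(ValueError):
            thermal_state(spec, 0.0)


class TestStiffness:
    def test_surface_tension_term_is_negligible_at_bladder_scale(self, make_spec):
        # 2 tau / (rho R0^3) = 2 * 0.07352 / (1028e-6) ~ 143 s^-2,
        # versus omega_M^2 ~ 4.1e6 s^-2
        spec = make_spec("warm_surface", "N2", 0.01)
        tension_term = 2 * spec.env.surface_tension_N_m / (
            spec.env.density_kg_m3 * spec.R0**3
        )
        assert tension_term == pytest.approx(143.04, rel=1e-3)
        assert tension_term < 1e-4 * minnaert_omega(spec) ** 2

    def test_omega0_squared_increases_with_gas_pressure(self, make_spec):
        spec = make_spec("cold_surface", "N2", 0.05)
        spec_hi = BubbleSpec(
            R0=0.05,
            env=replace(spec.env, pressure_Pa=2 * spec.env.pressure_Pa),
            gas=spec.gas,
        )
        w = TWO_PI * 100.0
        assert omega0_squared(spec_hi, w) > omega0_squared(spec, w)

    def test_small_epsilon_limit_is_omega0_squared(self, make_spec):
        spec = make_spec("cold_surface", "N2", 0.05)
        huge_c = BubbleSpec(
            R0=0.05, env=replace(spec.env, sound_speed_m_s=1e9), gas=spec.gas
        )
        w = TWO_PI * 65.0
        assert stiffness(huge_c, w) == pytest.approx(
            omega0_squared(huge_c, w), rel=1e-10
        )

    def test_large_omega_limit_tracks_omega_squared(self, make_spec):
        spec = make_spec("cold_surface", "N2", 0.05)
        w = 1e9
        assert stiffness(spec, w) == pytest.approx(w * w, rel=1e-3)

    def test_matches_arbitrary_precision_evaluation(self, make_spec):
        spec = make_spec("depth_2000m", "O2", 0.05)
        w = 7000.0
        got = stiffness(spec, w)
        with mpmath.workdps(50):
            R0 = mpmath.mpf("0.05")
            Dp = mpmath.mpf("92.64e-9")
            gam = mpmath.mpf("1.897")
            rho = mpmath.mpf(1036)
            tau = mpmath.mpf("0.07601")
            c = mpmath.mpf(1490)
            Pgas = mpmath.mpf("20.33e6") + 2 * tau / R0
            X = R0 / mpmath.sqrt(Dp / (2 * w))
            z = (1 + 1j) * X / 2
            G = gam / (1 - (z / mpmath.tanh(z) - 1) * 6j * (gam - 1) / X**2)
            w0sq = 3 * mpmath.re(G) * Pgas / (rho * R0**2) - 2 * tau / (rho * R0**3)
            eps = w * R0 / c
            want = float(w0sq + eps**2 / (1 + eps**2) * w**2)
        assert got == pytest.approx(want, rel=1e-12)


class TestDamping:
    def test_viscous_damping_hand_value_and_negligibility(self, make_spec):
        # 2 * 1.812e-3 / (1027 * 0.01) ~ 3.5e-4 s^-1
        spec = make_spec("cold_surface", "N2", 0.10)
        b = damping(spec, TWO_PI * 65.0)
        assert b.beta_vis == pytest.approx(3.529e-4, rel=1e-3)
        assert b.beta_vis < 1e-4 * TWO_PI * 65.0

    def test_acoustic_damping_small_epsilon_limit(self, make_spec):
        spec = make_spec("cold_surface", "N2", 0.05)
        w = 1.0  # eps ~ 3e-5
        b = damping(spec, w)
        eps = epsilon(spec, w)
        assert b.beta_ac == pytest.approx(0.5 * w * eps, rel=1e-8)

    @pytest.mark.parametrize("env_name", ENV_NAMES)
    @pytest.mark.parametrize("gas", ["N2", "O2"])
    def test_thermal_to_acoustic_crossover(self, make_spec, env_name, gas):
        """Thermal damping dominates at low frequency, acoustic at high."""
        spec = make_spec(env_name, gas, 0.10)
        w_und = TWO_PI * solve_undamped(spec)
        low, high = damping(spec, 1e-2 * w_und), damping(spec, 1e2 * w_und)
        assert low.beta_th > low.beta_ac
        assert high.beta_ac > high.beta_th

    def test_components_nonnegative_and_additive_over_frequency_sweep(self, make_spec):
        spec = make_spec("depth_3500m", "O2", 0.05)
        w_und = TWO_PI * solve_undamped(spec)
        for w in np.geomspace(1e-2 * w_und, 1e2 * w_und, 50):
            b = damping(spec, w)
            assert b.beta_th >= 0 and b.beta_vis >= 0 and b.beta_ac >= 0
            assert b.beta == b.beta_th + b.beta_vis + b.beta_ac  # exact
            assert b.beta0 == b.beta_th + b.beta_vis


class TestScattering:
    def test_normalization_identity_over_random_specs(self):
        for spec in perturbed_specs(seed=7, n=25):
            w = 1.3 * minnaert_omega(spec)
            pt = scattering_cross_section(spec, w)
            assert pt.sigma_s_norm * 4 * math.pi * spec.R0**2 == pytest.approx(
                pt.sigma_s, rel=1e-15
            )
            assert pt.epsilon > 0
            assert pt.K > 0

    def test_undamped_pole_diverges_at_resonance(self, make_spec):
        # kill thermal (X -> inf), viscous (eta -> 0) and radiation (c huge)
        # damping: sigma_s' blows up at omega0
        base = make_spec("warm_surface", "N2", 0.05)
        spec = BubbleSpec(
            R0=0.05,
            env=replace(
                base.env, surface_tension_N_m=0.0, sound_speed_m_s=1e10,
                viscosity_Pa_s=1e-30,
            ),
            gas=replace(base.gas, thermal_diffusivity_m2_s=1e-30),
        )
        w0 = math.sqrt(omega0_squared(spec, minnaert_omega(spec)))
        assert scattering_cross_section(spec, w0).sigma_s_norm > 1e12

    def test_high_frequency_limit_is_finite(self, make_spec):
        # as omega -> inf: s -> 0, beta0 -> beta_vis, so
        # sigma_s' -> 1 / (1 + 2 beta_vis R0 / c)^2
        spec = make_spec("cold_surface", "N2", 0.10)
        w = 1e9
        pt = scattering_cross_section(spec, w)
        b_vis = damping(spec, w).beta_vis
        want = 1.0 / (1.0 + 2 * b_vis * spec.R0 / spec.env.sound_speed_m_s) ** 2
        assert pt.sigma_s_norm == pytest.approx(want, rel=1e-4)

    def test_deep_peak_is_hundreds_of_times_below_surface_peak(self, make_spec):
        from deepbubble.resonance_solvers import solve_far_field

        _, cold = solve_far_field(make_spec("cold_surface", "N2", 0.10))
        _, deep = solve_far_field(make_spec("depth_3500m", "N2", 0.10))
        factor = cold.sigma_s_norm / deep.sigma_s_norm
        assert 200 < factor < 350

    @pytest.mark.parametrize("env_name", ENV_NAMES)
    def test_normalized_response_radius_invariance(self, make_spec, env_name):
        """Normalized peak locations collapse across radii in every
        environment; peak heights collapse within 1% in the deep environments
        (at the surface thermal damping keeps a mild radius dependence)."""
        from deepbubble.resonance_solvers import solve_far_field

        locations, heights = [], []
        for R0 in (0.01, 0.05, 0.10):
            spec = make_spec(env_name, "N2", R0)
            f_sigma, peak = solve_far_field(spec)
            locations.append(f_sigma / solve_undamped(spec))
            heights.append(peak.sigma_s_norm)
        assert max(locations) - min(locations) < 1e-4
        if env_name.startswith("depth"):
            assert max(heights) / min(heights) - 1 < 0.01
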