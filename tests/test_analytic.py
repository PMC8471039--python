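"""Closed-form transport estimates against independent numerical oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from wallswim.analytic import (
    RegimeError,
    boost,
    characteristic_speed,
    constant_control_x,
    constant_control_x_leading,
    flow_gain,
    min_time_estimate,
    optimal_distance,
    switch_time,
    transport_estimate,
)
from wallswim.dynamics import ModelParams


def params_at(omega, u_max=5.0):
    return ModelParams(v=1.0, k=1.0, omega=omega, u_max=u_max)


class TestCharacteristicSpeed:
    @pytest.mark.parametrize(
        "z0, k, expected",
        [(0.0, 1.0, 1.0), (1.0, 1.0, 0.0), (2.0, 1.0, -math.exp(-2)),
         (0.5, 2.0, 0.0)],
    )
    def test_values(self, z0, k, expected):
        assert characteristic_speed(z0, 1.0, k) == pytest.approx(expected)

    def test_unimodal_magnitude_above_null_height(self):
        z = np.linspace(1.01, 12.0, 500)
        mag = np.abs([characteristic_speed(zz, 1.0, 1.0) for zz in z])
        imax = np.argmax(mag)
        assert np.all(np.diff(mag[: imax + 1]) > 0)
        assert np.all(np.diff(mag[imax:]) < 0)
        assert mag[imax] == pytest.approx(math.exp(-2), rel=1e-3)


class TestOptimalDistance:
    def test_closed_form_and_scaling(self):
        assert optimal_distance(1.0) == 2.0
        assert optimal_distance(2.0) == optimal_distance(1.0) / 2

    def test_matches_numeric_maximisation(self):
        for k in (0.7, 1.0, 1.9):
            res = minimize_scalar(
                lambda z: -abs(characteristic_speed(z, 1.0, k)),
                bounds=(1.0 / k + 1e-9, 10.0 / k), method="bounded",
                options={"xatol": 1e-10},
            )
            assert res.x == pytest.approx(optimal_distance(k), abs=1e-6)


class TestBoost:
    def test_leading_order_values(self):
        assert 100 * boost(1.0, 1.0) == pytest.approx(8.5, abs=0.2)
        assert 100 * boost(5.0, 1.0) == pytest.approx(43.0, abs=1.0)
        assert boost(0.0, 1.0) == 0.0

    def test_linear_in_amplitude_ratio(self):
        assert boost(3.0, 1.0) == pytest.approx(3 * boost(1.0, 1.0))
        assert boost(1.0, 2.0) == pytest.approx(boost(1.0, 1.0) / 2)

    def test_passive_particle_rejected(self):
        with pytest.raises(ValueError):
            boost(1.0, 0.0)


class TestFlowGain:
    def test_zero_flow_zero_gain(self):
        assert flow_gain(1.0, -math.pi / 2, params_at(4.0)) == 0.0

    def test_fast_wave_limit_is_rectified_mean(self):
        z0 = 2.5
        V0 = abs(characteristic_speed(z0, 5.0, 1.0))
        fg = flow_gain(z0, -math.pi / 2, params_at(4000.0))
        assert fg == pytest.approx(2 * V0 / math.pi, rel=1e-3)

    def test_self_consistency_residual_is_second_order(self):
        # substituting v_flow into (per-cell displacement)/(switch time)
        # leaves a residual that shrinks ~4x when omega doubles
        z0, th0 = 2.4785, -math.pi / 2

        def residual(omega):
            p = params_at(omega)
            V0 = abs(characteristic_speed(z0, p.u_max, p.k))
            vfl = flow_gain(z0, th0, p)
            tsw = switch_time(z0, th0, p)
            return abs(vfl - (2 * V0 / omega) / tsw)

        r1, r2 = residual(8.0), residual(16.0)
        assert r2 < r1 / 2.5

    def test_slow_wave_regime_warns(self):
        with pytest.warns(UserWarning, match="wave speed"):
            flow_gain(2.0, -math.pi / 2, params_at(1.5))


class TestSwitchTime:
    def test_no_gain_limit(self):
        # v_flow = 0 at z0 = 1/k: denominator is omega - k v sin(theta0)
        p = params_at(4.0)
        assert switch_time(1.0, -math.pi / 2, p) == pytest.approx(
            math.pi / (4.0 - 1.0))

    def test_monotone_decreasing_in_omega(self):
        ts = [switch_time(2.4785, -math.pi / 2, params_at(w))
              for w in (4.0, 6.0, 8.0, 12.0)]
        assert all(a > b for a, b in zip(ts, ts[1:]))

    def test_inverse_is_affine_in_omega_with_slope_inv_pi(self):
        z0 = 3.0
        omegas = np.array([20.0, 30.0, 40.0, 60.0])
        inv = np.array([1.0 / switch_time(z0, -math.pi / 2, params_at(w))
                        for w in omegas])
        slope = np.polyfit(omegas, inv, 1)[0]
        assert slope == pytest.approx(1 / math.pi, rel=2e-2)

    def test_wave_slower_than_swimmer_rejected(self):
        p = ModelParams(v=10.0, k=1.0, omega=0.4, u_max=0.1)
        with pytest.warns(UserWarning):
            with pytest.raises(RegimeError):
                switch_time(2.0, -math.pi / 2, p)


class TestMinTime:
    def test_free_swimming_limit(self):
        p = ModelParams(v=1.0, k=1.0, omega=4.0, u_max=0.0)
        assert min_time_estimate(0.0, 3.0, 2.0, -math.pi / 2, p) == pytest.approx(3.0)

    def test_minimised_at_optimal_distance(self):
        p = params_at(8.0)
        zs = np.linspace(1.2, 6.0, 200)
        ts = [min_time_estimate(0, 2 * math.pi, z, -math.pi / 2, p) for z in zs]
        assert zs[int(np.argmin(ts))] == pytest.approx(2.0, abs=0.05)

    def test_backward_target_rejected(self):
        with pytest.raises(ValueError):
            min_time_estimate(1.0, 0.0, 2.0, -math.pi / 2, params_at(4.0))


class TestConstantControlX:
    def test_exact_solution_of_frozen_dynamics(self):
        # frozen z, theta: x' = -v sin(theta0) + V0 sin(k x - omega t)
        p = params_at(4.0)
        z0, th0, T0 = 2.4785, -math.pi / 2, 0.3
        V0 = characteristic_speed(z0, p.u_max, p.k)
        x0 = constant_control_x(0.0, T0, th0, z0, p)
        ode = lambda t, x: -math.sin(th0) + V0 * np.sin(x[0] - 4.0 * t)
        ts = np.linspace(0, 2.5, 400)
        sol = solve_ivp(ode, (0, ts[-1]), [x0], t_eval=ts,
                        rtol=1e-12, atol=1e-12)
        err = np.max(np.abs(sol.y[0] - constant_control_x(ts, T0, th0, z0, p)))
        assert err < 1e-6

    def test_zero_flow_reduces_to_uniform_drift(self):
        p = ModelParams(v=1.0, k=1.0, omega=4.0, u_max=0.0)
        ts = np.linspace(0, 3, 50)
        x = constant_control_x(ts, 0.0, -0.6, 2.0, p)
        np.testing.assert_allclose(np.diff(x, 2), 0.0, atol=1e-10)
        drift = (x[-1] - x[0]) / (ts[-1] - ts[0])
        assert drift == pytest.approx(-math.sin(-0.6))

    def test_continuity_across_half_periods(self):
        p = params_at(4.0)
        ts = np.linspace(0, 10, 20001)
        x = constant_control_x(ts, 0.1, -math.pi / 2, 2.4785, p)
        assert np.max(np.abs(np.diff(x))) < 0.01  # no branch jumps

    def test_flow_displacement_per_half_period(self):
        # between consecutive cell-border crossings the flow contributes
        # ~ 2 V0 / omega at leading order in V0 k / omega
        p = params_at(40.0)
        z0, th0 = 2.1, -math.pi / 2
        V0 = characteristic_speed(z0, p.u_max, p.k)
        from scipy.optimize import brentq

        psi = lambda t: constant_control_x(t, 0.0, th0, z0, p) - p.omega * t
        # psi decreases monotonically; find consecutive multiples of pi
        t_grid = np.linspace(0.02, 0.5, 4000)
        vals = np.array([psi(t) for t in t_grid])
        n0 = math.floor(vals[0] / math.pi)
        t_a = brentq(lambda t: psi(t) - n0 * math.pi, 0.02, 0.5)
        t_b = brentq(lambda t: psi(t) - (n0 - 1) * math.pi, t_a + 1e-6, 0.5)
        dx_total = (constant_control_x(t_b, 0.0, th0, z0, p)
                    - constant_control_x(t_a, 0.0, th0, z0, p))
        dx_flow = abs(dx_total - (-math.sin(th0)) * (t_b - t_a))
        assert dx_flow == pytest.approx(2 * abs(V0) / p.omega, rel=0.08)

    def test_wave_locked_regime_rejected(self):
        p = ModelParams(v=1.0, k=1.0, omega=1.2, u_max=20.0)
        with pytest.raises(RegimeError):
            constant_control_x(0.5, 0.0, -math.pi / 2, 0.2, p)

    def test_leading_form_tracks_exact_form(self):
        # the two closed forms fix the integration constant differently;
        # after removing that offset they agree to O(V0 k/omega)
        p = params_at(12.0)
        ts = np.linspace(0, 2, 400)
        xe = constant_control_x(ts, 0.2, -math.pi / 2, 2.4785, p)
        xl = constant_control_x_leading(ts, 0.2, -math.pi / 2, 2.4785, p)
        diff = xe - xl
        assert np.max(np.abs(diff - diff.mean())) < 0.15


class TestBundle:
    def test_transport_estimate_fields_consistent(self):
        p = params_at(4.0)
        est = transport_estimate(0.0, 2 * math.pi, 2.4785, -math.pi / 2, p)
        assert est.V0 == pytest.approx(
            characteristic_speed(2.4785, p.u_max, p.k))
        assert est.T_min == pytest.approx(2 * math.pi / (1 + est.v_flow))
        assert est.boost == pytest.approx(est.v_flow / p.v)
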