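"""Pontryagin machinery and solver plumbing (fast checks; full solver runs
are exercised through the shared session fixtures in test_acceptance)."""

import math
import warnings

import numpy as np
import pytest

import wallswim.optimal_control as oc
from wallswim.dynamics import ModelParams, SwimmerState, Trajectory
from wallswim.optimal_control import (
    AdjointState,
    OptimalControlProblem,
    SolverOptions,
    adjoint_derivative,
    bang_bang,
    extract_switch_times,
    hamiltonian,
    mean_switch_spacing,
    solve_time_optimal,
    switching_function,
)

P = ModelParams(v=1.0, k=1.0, omega=4.0, u_max=5.0)


class TestHamiltonian:
    def test_abnormal_only(self):
        adj = AdjointState(0, 0, 0, p0=-1.0)
        assert hamiltonian([0.3, 2.0, 0.4], adj, 1.0, 0.2, P) == -1.0

    def test_drift_part_closed_form(self):
        adj = AdjointState(0.7, -0.3, 0.2, p0=-1.0)
        s = [0.0, 2.0, 0.9]
        H0 = hamiltonian(s, adj, 0.0, 0.0, P)
        expected = (P.v * (-0.3 * math.cos(0.9) - 0.7 * -math.sin(0.9) * -1)
                    - 1.0)
        # H(u=0) = v (pz cos(theta) - px sin(theta)) + p0
        expected = P.v * (-0.3 * math.cos(0.9) - 0.7 * math.sin(0.9)) - 1.0
        assert H0 == pytest.approx(expected, rel=1e-12)

    def test_affine_in_control_with_switching_slope(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = rng.uniform([-3, 0.2, -3], [3, 4, 3])
            adj = AdjointState(*rng.normal(size=3), p0=-1.0)
            t = rng.uniform(0, 5)
            u = rng.uniform(-5, 5)
            h = switching_function(s, adj, t, P)
            dH = hamiltonian(s, adj, u, t, P) - hamiltonian(s, adj, 0.0, t, P)
            assert dH == pytest.approx(u * h, abs=1e-12)

    def test_abnormal_multiplier_sign_enforced(self):
        with pytest.raises(ValueError):
            AdjointState(1, 0, 0, p0=0.5)


class TestSwitchingFunction:
    def test_pure_rotation_costate_sign(self):
        adj = AdjointState(0, 0, 1.0, p0=0.0)
        # k x - w t in (0, pi): single positive term
        assert switching_function([0.5, 2.0, 0.0], adj, 0.0, P) > 0

    def test_decays_away_from_wall(self):
        adj = AdjointState(1.0, 1.0, 1.0, p0=0.0)
        h_far = switching_function([0.5, 30.0, 0.0], adj, 0.0, P)
        assert abs(h_far) < 1e-10


class TestBangBang:
    @pytest.mark.parametrize(
        "h, expected", [(-0.3, -5.0), (1e-9, 5.0), (0.0, 0.0)])
    def test_three_case_law(self, h, expected):
        assert bang_bang(h, -5.0, 5.0) == expected


class TestAdjoint:
    def test_matches_hamiltonian_gradient(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            s = rng.uniform([-2, 0.5, -2], [2, 3, 2])
            p_vec = rng.normal(size=3)
            adj = AdjointState(*p_vec, p0=-1.0)
            u, t = rng.uniform(-5, 5), rng.uniform(0, 3)
            dp = adjoint_derivative(s, adj, u, t, P)
            h = 1e-6
            grad = np.zeros(3)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for j in range(3):
                    ds = np.zeros(3)
                    ds[j] = h
                    grad[j] = (hamiltonian(s + ds, adj, u, t, P)
                               - hamiltonian(s - ds, adj, u, t, P)) / (2 * h)
            np.testing.assert_allclose(dp, -grad, atol=1e-6)

    def test_linear_in_costate(self):
        s = [0.4, 1.8, -0.7]
        z = adjoint_derivative(s, AdjointState(0, 0, 0, p0=0.0), 1.0, 0.2, P)
        np.testing.assert_array_equal(z, np.zeros(3))
        d1 = adjoint_derivative(s, AdjointState(1, 2, -1, p0=0.0), 1.0, 0.2, P)
        d2 = adjoint_derivative(s, AdjointState(2, 4, -2, p0=0.0), 1.0, 0.2, P)
        np.testing.assert_allclose(d2, 2 * d1, rel_err := 1e-12)

    def test_free_swimming_costate_dynamics(self):
        # u=0: px, pz frozen; ptheta driven by the orientation coupling
        adj = AdjointState(0.7, 0.3, 0.0, p0=-1.0)
        dp = adjoint_derivative([0.1, 2.0, 0.9], adj, 0.0, 0.0, P)
        assert dp[0] == 0.0 and dp[1] == 0.0
        assert dp[2] == pytest.approx(
            P.v * (0.7 * math.cos(0.9) + 0.3 * math.sin(0.9)), rel=1e-12)


class TestDurationSensitivity:
    def test_terminal_and_path_gradients_match_finite_differences(self):
        X0 = SwimmerState(0, 2.2, -1.2)
        d = np.array([0.6, 0.8, 0.5])
        nsub = [60, 80, 50]
        y, G, sm, Gz = oc._propagate_bang_sens(d, nsub, 1, X0, P, z_floor=0.05)
        for j in range(3):
            dd = d.copy()
            dd[j] += 1e-6
            r2 = oc._propagate_bang_sens(dd, nsub, 1, X0, P, z_floor=0.05)
            dd[j] -= 2e-6
            r1 = oc._propagate_bang_sens(dd, nsub, 1, X0, P, z_floor=0.05)
            np.testing.assert_allclose(
                G[:, j], (r2[0] - r1[0]) / 2e-6, atol=2e-6)
            assert Gz[j] == pytest.approx((r2[2] - r1[2]) / 2e-6, abs=2e-6)


class TestMergeBang:
    def test_zero_segment_merges_neighbours(self):
        s0, d = oc._merge_bang(1, np.array([0.5, 0.0, 0.7, 0.3]))
        np.testing.assert_allclose(d, [1.2, 0.3])
        assert s0 == 1

    def test_leading_zero_flips_sign(self):
        s0, d = oc._merge_bang(1, np.array([0.0, 0.7, 0.3]))
        assert s0 == -1
        np.testing.assert_allclose(d, [0.7, 0.3])


class TestSwitchExtraction:
    def _square_trajectory(self, tau, n_half=6):
        ts = np.linspace(0, n_half * tau, n_half * 50 + 1)
        u = 5.0 * np.sign(np.sin(np.pi * ts / tau + 1e-9))
        states = np.column_stack([ts, np.full_like(ts, 2.0), np.zeros_like(ts)])
        return Trajectory(ts, states, u)

    def test_square_wave_spacing(self):
        tau = 0.8
        traj = self._square_trajectory(tau)
        sw = extract_switch_times(traj)
        assert len(sw) >= 4
        assert mean_switch_spacing(sw) == pytest.approx(tau, rel=1e-2)

    def test_constant_control_has_no_switches(self):
        ts = np.linspace(0, 1, 50)
        states = np.column_stack([ts, np.full_like(ts, 2.0), np.zeros_like(ts)])
        traj = Trajectory(ts, states, np.full_like(ts, 5.0))
        assert extract_switch_times(traj).size == 0
        with pytest.warns(UserWarning):
            assert math.isnan(mean_switch_spacing(np.array([0.3])))


class TestProblemSetup:
    def test_targets(self):
        X0 = SwimmerState(0, 2, -math.pi / 2)
        p1 = OptimalControlProblem.parallel_displacement(P, X0, 5.0)
        assert p1.target == (5.0, 2.0, None) and p1.fixed_indices == [0, 1]
        p3 = OptimalControlProblem.wall_distance(P, X0, 1.0)
        assert p3.fixed_indices == [1]
        with pytest.raises(ValueError):
            OptimalControlProblem(X0, (None, None, None), P)

    def test_interaction_model_rejected(self):
        params = ModelParams(u_max=5.0, B2=10.0, a=0.5,
                             include_wall_interaction=True)
        with pytest.raises(ValueError, match="interaction"):
            OptimalControlProblem.parallel_displacement(
                params, SwimmerState(0, 2, 0), 5.0)


class TestSolvedTrajectoryInvariants:
    def test_switching_pattern_consistent_with_maximum_principle(
        self, fig3a_best
    ):
        # backward-integrated adjoint from a scanned terminal costate
        # reproduces the observed switching signs on >= 90% of samples
        sol, params, _ = fig3a_best
        match = oc.switching_sign_match(sol, params, fixed_indices=(0, 1))
        assert match >= 0.90

    def test_minimal_time_nearly_flat_in_frequency(self, fig3_solutions):
        for V0 in (0.62, 0.34):
            ts = [fig3_solutions[(V0, w)][0].T_min for w in (4.0, 8.0, 12.0)]
            assert (max(ts) - min(ts)) / min(ts) < 0.10

    def test_actuation_never_slows_transit(self, fig3a_best, fig3_solutions):
        # the admissible set grows with u_max, so every driven optimum
        # beats the free swimming time (the u_max = 0 optimum), and the
        # unrestricted optimum beats its height-restricted counterpart
        sol, params, _ = fig3a_best
        assert sol.T_min < 2 * math.pi / params.v
        assert sol.T_min <= fig3_solutions[(0.62, 4.0)][0].T_min + 1e-9

    def test_wall_approach_contained_in_reorientation(
        self, p3_solution, fig4_solutions
    ):
        # the minimum-time wall-distance solution retraces the approach
        # phase of the matching reorientation solution
        sol3, _ = p3_solution
        sol2, th0, _ = fig4_solutions["b"]
        tr2, tr3 = sol2.trajectory, sol3.trajectory
        i = np.argmax(tr2.z < 0.8)
        t_cross = tr2.times[i]
        assert sol3.T_min == pytest.approx(t_cross, rel=0.15)
        ts = np.linspace(0, min(t_cross, sol3.T_min), 100)
        z2 = np.interp(ts, tr2.times, tr2.z)
        z3 = np.interp(ts, tr3.times, tr3.z)
        assert np.mean(np.abs(z2 - z3)) < 0.1
        assert np.max(np.abs(z2 - z3)) < 0.25


class TestSolverNoActuation:
    def test_zero_amplitude_bound_gives_free_transit(self):
        # u_max = 0: the only admissible control is u = 0, so the minimum
        # time is the free swimming time (x1 - x0) / v
        params = ModelParams(v=1.0, k=1.0, omega=4.0, u_max=0.0)
        prob = OptimalControlProblem.parallel_displacement(
            params, SwimmerState(0.0, 2.0, -math.pi / 2), 3.0)
        sol = solve_time_optimal(prob, SolverOptions(refine_shooting=False))
        assert sol.T_min == pytest.approx(3.0, abs=1e-5)
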