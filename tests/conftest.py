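"""Shared fixtures: solved scenarios are expensive, so they are computed
once per session and reused across structural and quantitative tests."""

from __future__ import annotations

import math

import numpy as np
import pytest

from wallswim.dynamics import ModelParams, SwimmerState
from wallswim.io import back_solve_height, make_figure_fixtures
from wallswim.optimal_control import (
    OptimalControlProblem,
    SolverOptions,
    solve_time_optimal,
)

FIG3_GRID = [(0.62, 4.0), (0.62, 8.0), (0.62, 12.0),
             (0.34, 4.0), (0.34, 8.0), (0.34, 12.0)]
U_MAX = 5.0


def fig3_point(V0: float, omega: float):
    """Parameters and initial state of one minimum-time transport scenario."""
    z0 = back_solve_height(V0, U_MAX)
    params = ModelParams(v=1.0, k=1.0, omega=omega, u_max=U_MAX)
    X0 = SwimmerState(0.0, z0, -math.pi / 2)
    return params, X0, z0


@pytest.fixture(scope="session")
def fig3_solutions():
    """Minimum-time parallel-displacement solutions on the 6-point grid
    |V0| in {0.62, 0.34} x omega in {4, 8, 12}, x: 0 -> 2 pi, restricted to
    the cell-riding mechanism above the flow-null height (z >= 1/k) — the
    class described by the closed-form switch-time and transit estimates."""
    out = {}
    for V0, omega in FIG3_GRID:
        params, X0, z0 = fig3_point(V0, omega)
        prob = OptimalControlProblem.parallel_displacement(
            params, X0, 2 * math.pi)
        sol = solve_time_optimal(prob, SolverOptions(z_floor=1.0 / params.k))
        out[(V0, omega)] = (sol, params, z0)
    return out


@pytest.fixture(scope="session")
def fig3a_best():
    """Unrestricted minimum-time transport solution at the strongest
    operating point (|V0| = 0.62, omega = 4); the optimum is a dive
    strategy that rides the strong near-wall flow."""
    params, X0, z0 = fig3_point(0.62, 4.0)
    prob = OptimalControlProblem.parallel_displacement(params, X0, 2 * math.pi)
    return solve_time_optimal(prob), params, z0


@pytest.fixture(scope="session")
def fig4_solutions():
    """Minimum-time reorientation solutions for two representative
    orientation pairs at z0 = 2 (scaled-down selection)."""
    params = ModelParams(v=1.0, k=1.0, omega=4.0, u_max=U_MAX)
    pairs = {
        "a": (-math.pi / 4, -3 * math.pi / 4),
        "b": (-math.pi, 0.0),
    }
    out = {}
    for tag, (th0, th1) in pairs.items():
        prob = OptimalControlProblem.reorientation(
            params, SwimmerState(0.0, 2.0, th0), th1)
        out[tag] = (solve_time_optimal(prob), th0, th1)
    return out


@pytest.fixture(scope="session")
def p3_solution():
    """Minimum-time wall-approach solution z: 2 -> 0.8 for a swimmer
    pointing straight down (matches the approach phase of fig4b)."""
    params = ModelParams(v=1.0, k=1.0, omega=4.0, u_max=U_MAX)
    prob = OptimalControlProblem.wall_distance(
        params, SwimmerState(0.0, 2.0, -math.pi), 0.8)
    return solve_time_optimal(prob), params


@pytest.fixture(scope="session")
def figure_fixtures():
    return make_figure_fixtures()
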