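"""Equations of motion of a wall-driven spherical microswimmer.

The swimmer moves in the (x, z) plane above a wall at z = 0.  Its state is
X = (x, z, theta) with theta the orientation angle measured from the +z
axis, so the free-swimming velocity is U_free = (-v sin(theta), v cos(theta))
and free swimming produces no rotation.

The wall generates a travelling-wave flow of controllable amplitude u(t).
With phase phi = k x - omega t the flow felt by the swimmer is

    Ux_wall     =  u e^{-kz} (1 - kz) sin(phi)
    Uz_wall     = -u e^{-kz} k z      cos(phi)
    Omega_wall  =  (u/2) e^{-kz} k    sin(phi)

an incompressible field organised in counter-rotating cells of width pi/k
whose pattern travels at the wave speed omega/k.  Optionally, a far-field
squirmer-wall interaction (stresslet strength B2, swimmer radius a) is added.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "SwimmerState",
    "ModelParams",
    "Trajectory",
    "CrashError",
    "IntegrationError",
    "wall_flow",
    "free_velocity",
    "squirmer_wall_velocity",
    "state_derivative",
    "state_jacobian",
    "integrate",
]

# exp(-k z) guard: keeps exploratory evaluations below the wall finite
_EXP_CAP = 40.0


class CrashError(RuntimeError):
    """Swimmer reached the wall-crash threshold."""


class IntegrationError(RuntimeError):
    """ODE solver failed; carries the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class SwimmerState:
    """Planar state: horizontal position x, wall distance z, orientation theta.

    theta is stored unwrapped (no modular reduction) so that net rotation
    accumulated along a trajectory is measurable.
    """

    x: float
    z: float
    theta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.z, self.theta], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "SwimmerState":
        x, z, theta = arr
        return cls(float(x), float(z), float(theta))


@dataclass
class ModelParams:
    """Physical parameters of the wall-driven swimmer.

    Default nondimensionalisation: k = v = 1, so omega, times and speeds are
    the ratios omega/(k v), t k v and U/v.

    Parameters
    ----------
    v : free swimming speed (>= 0).
    a : swimmer radius; enters the squirmer-wall interaction and sets the
        crash threshold when positive.  a = 0 means point swimmer.
    B2 : squirmer stresslet coefficient; B2 > 0 puller (attracted to the
        wall), B2 < 0 pusher (repelled), B2 = 0 neutral (no leading-order
        wall interaction).
    k, omega : wave number and angular frequency of the wall wave.
    u_max, u_min : control amplitude bounds; u_min defaults to -u_max.
    include_wall_interaction : add the far-field squirmer-wall terms.
    squirmer_double_angle : the interaction formula is read with double
        angles sin(2 theta) / cos(2 theta) (default); set False for the
        squared-angle reading sin^2 / cos^2.
    """

    v: float = 1.0
    a: float = 0.0
    B2: float = 0.0
    k: float = 1.0
    omega: float = 4.0
    u_max: float = 1.0
    u_min: float | None = None
    include_wall_interaction: bool = False
    squirmer_double_angle: bool = True
    crash_fraction: float = 0.05  # point-swimmer crash height, units of 1/k

    def __post_init__(self) -> None:
        if self.u_min is None:
            self.u_min = -self.u_max
        if self.v < 0:
            raise ValueError("swimming speed v must be >= 0")
        if self.a < 0:
            raise ValueError("radius a must be >= 0")
        if self.k < 0:
            raise ValueError("wave number k must be >= 0")
        if self.u_min > self.u_max:
            raise ValueError("u_min must not exceed u_max")

    @property
    def crash_threshold(self) -> float:
        """Height below which the swimmer counts as crashed into the wall."""
        if self.a > 0:
            return self.a
        if self.k > 0:
            return self.crash_fraction / self.k
        return 0.0


@dataclass
class Trajectory:
    """Time-stamped states with the applied control trace.

    ``times`` is strictly increasing.  ``controls[i]`` is the control applied
    at (the left endpoint of) ``times[i]``; times, states and controls all
    have equal length (the final control sample repeats the last applied
    value so the arrays stay aligned).
    """

    times: np.ndarray
    states: np.ndarray  # (n, 3): columns x, z, theta
    controls: np.ndarray
    crashed: bool = False
    params: ModelParams | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.controls = np.asarray(self.controls, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (self.times.size, 3):
            raise ValueError("states must have shape (len(times), 3)")
        if self.controls.shape != self.times.shape:
            raise ValueError("controls must align with times")

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def theta(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def final_state(self) -> SwimmerState:
        return SwimmerState.from_array(self.states[-1])


def _exp_mkz(k: float, z: float) -> float:
    return math.exp(max(-_EXP_CAP, min(_EXP_CAP, -k * z)))


def wall_flow(
    x: float, z: float, t: float, u: float, params: ModelParams
) -> tuple[float, float, float]:
    """Wall-generated flow (Ux, Uz, Omega_y) at height z and phase k x - omega t.

    Only defined above the wall; raises for z < 0.
    """
    if z < 0:
        raise ValueError(f"wall flow undefined below the wall (z={z})")
    k, omega = params.k, params.omega
    phi = k * x - omega * t
    e = math.exp(-k * z)
    s, c = math.sin(phi), math.cos(phi)
    ux = u * e * (1.0 - k * z) * s
    uz = -u * e * k * z * c
    wy = 0.5 * u * e * k * s
    return ux, uz, wy


def free_velocity(theta: float, v: float) -> tuple[float, float]:
    """Self-propulsion velocity (-v sin(theta), v cos(theta)); no rotation."""
    if v < 0:
        raise ValueError("v must be >= 0")
    return -v * math.sin(theta), v * math.cos(theta)


def squirmer_wall_velocity(
    z: float,
    theta: float,
    a: float,
    B2: float,
    double_angle: bool = True,
) -> tuple[float, float, float]:
    """Leading-order far-field wall correction for a squirmer.

    Returns (Uxb, Uzb, Omega_yb):

        Uxb = -(3 a^2 B2 / 40 z^2) sin(2 theta)
        Uzb =  (9 a^2 B2 / 16 z^2) cos(2 theta)
        Oyb = -(3 a^2 B2 / 40 z^3) sin(2 theta)

    Vanishes identically for a neutral swimmer (B2 = 0).  With
    ``double_angle=False`` the trigonometric factors are read as sin^2 /
    cos^2 instead (an alternative reading of the same far-field result; the
    double-angle form is the one consistent with pullers tilting into and
    pushers away from the wall for a wall-parallel swimmer).
    """
    if z <= 0:
        raise ValueError(f"squirmer-wall interaction requires z > 0 (z={z})")
    if double_angle:
        strig = math.sin(2.0 * theta)
        ctrig = math.cos(2.0 * theta)
    else:
        strig = math.sin(theta) ** 2
        ctrig = math.cos(theta) ** 2
    pref = a * a * B2
    uxb = -3.0 * pref / (40.0 * z * z) * strig
    uzb = 9.0 * pref / (16.0 * z * z) * ctrig
    oyb = -3.0 * pref / (40.0 * z**3) * strig
    return uxb, uzb, oyb


def state_derivative(
    state: SwimmerState | Sequence[float],
    u: float,
    t: float,
    params: ModelParams,
    _warn: bool = True,
) -> np.ndarray:
    """Full right-hand side (dx, dz, dtheta): free + wall flow (+ squirmer).

    The three contributions are additive (the flow problem is linear).  The
    orientation rate has no free-swimming part.
    """
    if isinstance(state, SwimmerState):
        x, z, theta = state.x, state.z, state.theta
    else:
        x, z, theta = state
    if _warn and not (params.u_min - 1e-9 <= u <= params.u_max + 1e-9):
        warnings.warn(
            f"control u={u} outside [{params.u_min}, {params.u_max}]",
            stacklevel=2,
        )
    fx, fz = free_velocity(theta, params.v)
    wx, wz, wy = wall_flow(x, z, t, u, params)
    dx, dz, dth = fx + wx, fz + wz, wy
    if params.include_wall_interaction and params.B2 != 0.0:
        bx, bz, by = squirmer_wall_velocity(
            z, theta, params.a, params.B2, params.squirmer_double_angle
        )
        dx, dz, dth = dx + bx, dz + bz, dth + by
    return np.array([dx, dz, dth])


def state_jacobian(
    state: Sequence[float], u: float, t: float, params: ModelParams
) -> np.ndarray:
    """Analytic Jacobian d(rhs)/d(x, z, theta) of :func:`state_derivative`."""
    x, z, theta = (state.x, state.z, state.theta) if isinstance(state, SwimmerState) else state
    k, omega, v = params.k, params.omega, params.v
    phi = k * x - omega * t
    e = _exp_mkz(k, z)
    s, c = math.sin(phi), math.cos(phi)
    st, ct = math.sin(theta), math.cos(theta)
    J = np.array(
        [
            [u * e * (1 - k * z) * c * k, u * e * (k * k * z - 2 * k) * s, -v * ct],
            [u * e * k * z * s * k, -u * e * k * (1 - k * z) * c, -v * st],
            [0.5 * u * e * k * c * k, -0.5 * u * e * k * k * s, 0.0],
        ]
    )
    if params.include_wall_interaction and params.B2 != 0.0:
        pref = params.a**2 * params.B2
        if params.squirmer_double_angle:
            s2, c2 = math.sin(2 * theta), math.cos(2 * theta)
            ds, dc = 2 * c2, -2 * s2
        else:
            s2, c2 = st * st, ct * ct
            ds, dc = 2 * st * ct, -2 * st * ct
        J[0, 1] += 6.0 * pref / (40.0 * z**3) * s2
        J[0, 2] += -3.0 * pref / (40.0 * z * z) * ds
        J[1, 1] += -18.0 * pref / (16.0 * z**3) * c2
        J[1, 2] += 9.0 * pref / (16.0 * z * z) * dc
        J[2, 1] += 9.0 * pref / (40.0 * z**4) * s2
        J[2, 2] += -3.0 * pref / (40.0 * z**3) * ds
    return J


def integrate(
    params: ModelParams,
    control: Callable[[float, np.ndarray], float] | float,
    X0: SwimmerState | Sequence[float],
    T: float,
    *,
    t0: float = 0.0,
    switch_times: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step: float = np.inf,
    n_samples: int = 500,
    stop_on_crash: bool = True,
) -> Trajectory:
    """Integrate the swimmer dynamics on [t0, t0 + T].

    ``control`` is either a constant or a callable ``u(t, state)``.  When the
    control is discontinuous at known instants, pass them via
    ``switch_times``: integration then restarts at each switch so the
    adaptive stepper never straddles a discontinuity.  Integration stops
    early (``crashed`` flag) if z falls below the crash threshold.
    """
    if T <= 0:
        raise ValueError("horizon T must be positive")
    ufun = (lambda t, y, _u=float(control): _u) if not callable(control) else control
    y0 = X0.as_array() if isinstance(X0, SwimmerState) else np.asarray(X0, dtype=float)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        # adaptive steppers probe trial stages slightly past the crash
        # event; clamp those evaluations just above the wall (the accepted
        # trajectory itself is truncated by the event)
        if y[1] <= 1e-9:
            y = np.array([y[0], 1e-9, y[2]])
        return state_derivative(y, ufun(t, y), t, params, _warn=False)

    z_crash = params.crash_threshold
    events = []
    if stop_on_crash and z_crash > 0:
        def crash_event(t: float, y: np.ndarray) -> float:
            return y[1] - z_crash
        crash_event.terminal = True  # type: ignore[attr-defined]
        crash_event.direction = -1  # type: ignore[attr-defined]
        events.append(crash_event)

    edges = [t0, t0 + T]
    if switch_times is not None:
        edges = sorted({t0, t0 + T, *(ts for ts in switch_times if t0 < ts < t0 + T)})

    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    crashed = False
    y_cur = y0
    for lo, hi in zip(edges[:-1], edges[1:]):
        n_seg = max(2, int(round(n_samples * (hi - lo) / T)))
        t_eval = np.linspace(lo, hi, n_seg)
        sol = solve_ivp(
            rhs, (lo, hi), y_cur, method="DOP853", rtol=rtol, atol=atol,
            t_eval=t_eval, max_step=max_step, events=events or None,
            dense_output=True,
        )
        if sol.status == -1:
            raise IntegrationError(sol.message, float(sol.t[-1]))
        all_t.append(sol.t)
        all_y.append(sol.y.T)
        if sol.status == 1:  # crash event
            t_c = float(sol.t_events[0][0])
            if all_t[-1][-1] < t_c:
                all_t.append(np.array([t_c]))
                all_y.append(sol.y_events[0][:1])
            crashed = True
            break
        y_cur = sol.y[:, -1]

    times = np.concatenate(all_t)
    states = np.concatenate(all_y, axis=0)
    keep = np.concatenate(([True], np.diff(times) > 0))
    times, states = times[keep], states[keep]
    controls = np.array(
        [ufun(t, y) for t, y in zip(times, states)], dtype=float
    )
    return Trajectory(times, states, controls, crashed=crashed, params=params)
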