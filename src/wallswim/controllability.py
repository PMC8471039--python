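"""Local controllability around free-swimming reference trajectories.

With zero reference control the swimmer travels along the straight line

    X_ref(t) = (x0 - v t sin(theta0), z0 + v t cos(theta0), theta0),

and the linearised control system X' = A(t) X + B(t) u has

    A(t) = df/dX(X_ref, 0),   B(t) = df/du(X_ref, 0).

A time-varying Kalman-type test applies: with B1 = B' - A B and
B2 = B1' - A B1, the linearised system is controllable on [0, T] iff
[B | B1 | B2](t) is invertible for some t.  Its determinant has the closed
form

    Delta(t) = 1/2 e^{-3 k z_r(t)} k^3 v omega_c cos(theta0)
               * [omega_c z_r(t) cos(phi_r(t)) + v cos(theta0) sin(phi_r(t))]

with omega_c = omega + k v sin(theta0) (the rate at which the swimmer
crosses the wave phase: d(k x_ref - omega t)/dt = -omega_c),
z_r(t) = z0 + t v cos(theta0) and phi_r(t) = k x0 - omega_c t.

Delta factorises through k, v, omega_c and cos(theta0); each degenerate
case has a physical meaning:

* ``k = 0``   — uniform sliding wall, no rotational actuation at all;
* ``v = 0``   — passive particle, glued to a single flow line;
* ``omega_c = 0`` — the swimmer surfs the wave (horizontal speed
  -v sin(theta0) equals the wave speed omega/k) and never changes cell;
* ``cos(theta0) = 0`` — wall-parallel swimming at constant height, where
  the x- and theta-columns of the actuation are proportional for all time
  (both scale with sin(phi) at fixed z), so the three-state linearised
  system is singular even though planar transport itself still works.

Outside these cases Delta vanishes at most at isolated instants and the
nonlinear system is locally controllable around X_ref.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from wallswim.dynamics import ModelParams, SwimmerState

__all__ = [
    "LinearisedSystem",
    "ControllabilityReport",
    "reference_trajectory",
    "linearize",
    "kalman_blocks",
    "controllability_determinant",
    "classify_degeneracies",
]

_DEGENERACY_TOL = 1e-12


def _require_no_interaction(params: ModelParams) -> None:
    if params.include_wall_interaction and params.B2 != 0.0:
        raise ValueError(
            "the linearised controllability analysis is defined for the "
            "interaction-free model; disable include_wall_interaction and "
            "use simulation-based checks for the squirmer-wall variant"
        )


def reference_trajectory(params: ModelParams, X0: SwimmerState, t: float) -> SwimmerState:
    """Free-swimming (u = 0) reference state at time t."""
    s, c = math.sin(X0.theta), math.cos(X0.theta)
    return SwimmerState(
        X0.x - params.v * t * s, X0.z + params.v * t * c, X0.theta
    )


@dataclass
class LinearisedSystem:
    """Matrices A(t), B(t) of the linearisation around a free trajectory."""

    params: ModelParams
    X0: SwimmerState

    def A(self, t: float) -> np.ndarray:
        v, th = self.params.v, self.X0.theta
        return np.array(
            [[0.0, 0.0, -v * math.cos(th)],
             [0.0, 0.0, -v * math.sin(th)],
             [0.0, 0.0, 0.0]]
        )

    def B(self, t: float) -> np.ndarray:
        k, omega = self.params.k, self.params.omega
        ref = reference_trajectory(self.params, self.X0, t)
        e = math.exp(-k * ref.z)
        phi = k * ref.x - omega * t
        return np.array(
            [e * (1 - k * ref.z) * math.sin(phi),
             -e * k * ref.z * math.cos(phi),
             0.5 * e * k * math.sin(phi)]
        )


def linearize(
    params: ModelParams, X0: SwimmerState, t: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Jacobians (A, B) of the dynamics along the free reference."""
    _require_no_interaction(params)
    lin = LinearisedSystem(params, X0)
    return lin.A(t), lin.B(t)


_B_DERIV_CACHE: dict[str, object] = {}


def _b_deriv_fun():
    """Analytic B, B', B'' along the reference, generated symbolically once."""
    if "fun" not in _B_DERIV_CACHE:
        import sympy as sp

        t, k, v, w, x0, z0, th = sp.symbols("t k v w x0 z0 th", real=True)
        xr = x0 - v * t * sp.sin(th)
        zr = z0 + v * t * sp.cos(th)
        phi = k * xr - w * t
        e = sp.exp(-k * zr)
        B = sp.Matrix(
            [e * (1 - k * zr) * sp.sin(phi),
             -e * k * zr * sp.cos(phi),
             sp.Rational(1, 2) * k * e * sp.sin(phi)]
        )
        Bd = sp.diff(B, t)
        Bdd = sp.diff(Bd, t)
        _B_DERIV_CACHE["fun"] = sp.lambdify(
            (t, k, v, w, x0, z0, th), [B, Bd, Bdd], "numpy"
        )
    return _B_DERIV_CACHE["fun"]


def _B_derivatives(
    params: ModelParams, X0: SwimmerState, t: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """B and its first two total time derivatives along the reference."""
    fun = _b_deriv_fun()
    B, Bd, Bdd = fun(t, params.k, params.v, params.omega, X0.x, X0.z, X0.theta)
    return (
        np.asarray(B, dtype=float).ravel(),
        np.asarray(Bd, dtype=float).ravel(),
        np.asarray(Bdd, dtype=float).ravel(),
    )


def kalman_blocks(params: ModelParams, X0: SwimmerState, t: float) -> np.ndarray:
    """Concatenated test matrix [B | B1 | B2] with analytic time derivatives."""
    _require_no_interaction(params)
    A = LinearisedSystem(params, X0).A(t)
    B, Bd, Bdd = _B_derivatives(params, X0, t)
    B1 = Bd - A @ B
    # A is constant along the reference, so B1' = B'' - A B'
    B1d = Bdd - A @ Bd
    B2 = B1d - A @ B1
    return np.column_stack([B, B1, B2])


def controllability_determinant(
    params: ModelParams, X0: SwimmerState, t: float
) -> float:
    """Closed-form determinant Delta(t) of the Kalman test matrix.

    The closed form is stated in the angle-from-z-axis convention of the
    dynamics; it factorises through k^3, v, omega_c = omega + k v sin(theta0)
    and cos(theta0), with a decaying exponential in the reference height.
    It agrees with ``det(kalman_blocks(...))`` to round-off.
    """
    _require_no_interaction(params)
    k, omega, v = params.k, params.omega, params.v
    th = X0.theta
    omega_c = omega + k * v * math.sin(th)
    ct = math.cos(th)
    z_r = X0.z + t * v * ct
    phi_r = k * X0.x - omega_c * t
    return (
        0.5 * math.exp(-3.0 * k * z_r) * k**3 * v * omega_c * ct
        * (omega_c * z_r * math.cos(phi_r) + v * ct * math.sin(phi_r))
    )


@dataclass
class ControllabilityReport:
    """Verdict of the local controllability test around a free trajectory."""

    controllable: bool
    degeneracies: list[str]
    omega_c: float
    determinant: np.ndarray = field(default_factory=lambda: np.empty(0))
    times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "controllable": self.controllable,
            "degeneracies": list(self.degeneracies),
            "omega_c": self.omega_c,
            "times": self.times.tolist(),
            "determinant": self.determinant.tolist(),
        }


def classify_degeneracies(
    params: ModelParams,
    X0: SwimmerState,
    T: float = 5.0,
    grid: int = 1000,
) -> ControllabilityReport:
    """Flag structural degeneracies and evaluate Delta on a time grid.

    Flags (each annihilates Delta identically):

    * ``k_zero``          — no wave, orientation uncontrollable;
    * ``v_zero``          — passive particle;
    * ``omega_c_zero``    — swimmer locked to the wave phase
      (omega + k v sin(theta0) = 0);
    * ``cos_theta0_zero`` — wall-parallel reference orientation.

    The system is declared controllable iff no flag is set and Delta is
    nonzero somewhere on the grid (its zeros are then isolated).
    """
    _require_no_interaction(params)
    k, v, th = params.k, params.v, X0.theta
    omega_c = params.omega + k * v * math.sin(th)
    flags = []
    if abs(k) <= _DEGENERACY_TOL:
        flags.append("k_zero")
    if abs(v) <= _DEGENERACY_TOL:
        flags.append("v_zero")
    if abs(omega_c) <= _DEGENERACY_TOL:
        flags.append("omega_c_zero")
    if abs(math.cos(th)) <= _DEGENERACY_TOL:
        flags.append("cos_theta0_zero")

    ts = np.linspace(0.0, T, grid)
    dets = np.array([controllability_determinant(params, X0, t) for t in ts])
    scale = np.max(np.abs(dets)) if dets.size else 0.0
    nonzero_somewhere = scale > _DEGENERACY_TOL
    return ControllabilityReport(
        controllable=bool(not flags and nonzero_somewhere),
        degeneracies=flags,
        omega_c=omega_c,
        determinant=dets,
        times=ts,
    )
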