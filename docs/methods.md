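# Methods

## Model

A spherical swimmer self-propels in the (x, z) plane at constant speed v,
with orientation θ measured from the +z axis, so its free velocity is
U_free = (−v sin θ, v cos θ) and free swimming produces no rotation.  A wall
at z = 0 carries a metachronal-wave actuation whose far-field flow, with
controllable amplitude u(t) and phase φ = k x − ω t, is

    Ux = u e^{−kz} (1 − kz) sin φ
    Uz = −u e^{−kz} k z cos φ
    Ωy = (u/2) e^{−kz} k sin φ .

The field is incompressible, satisfies no-penetration at the wall, and is
organised in counter-rotating cells of width π/k travelling at the wave
speed ω/k.  The state X = (x, z, θ) evolves as the sum of the free and
wall-flow contributions, with θ̇ = Ωy.  Two sign conventions deserve note:

* θ = −π/2 points the swimmer toward +x (the transport direction used
  throughout);
* θ̇ = +Ωy is adopted as the rotation coupling.  The right-hand rule for
  r = (−sin θ, 0, cos θ) about +e_y would give θ̇ = −Ωy, but only the
  adopted sign produces the observed phenomenology of the synchronised
  feedback law (slow rotation toward the wall with eventual crash risk),
  which fixes the convention unambiguously.

A key structural fact: the horizontal flow and the rotation have the same
phase dependence (both ∝ sin φ), so for a swimmer above the null height
1/k every control pattern that extracts forward thrust necessarily rotates
the swimmer toward the wall.  This coupling is what eventually destabilises
pure transport policies.

Optionally a far-field squirmer–wall interaction is added for a swimmer of
radius a and stresslet coefficient B2 (puller B2 > 0, pusher B2 < 0):

    Uxb = −(3 a² B2 / 40 z²) sin 2θ,  Uzb = (9 a² B2 / 16 z²) cos 2θ,
    Ωyb = −(3 a² B2 / 40 z³) sin 2θ .

The double-angle reading is the default because it is the one under which
a wall-parallel puller (θ = −π/2, cos 2θ = −1) is attracted to the wall
and a pusher repelled, matching the standard far-field phenomenology; the
squared-angle reading (which predicts no vertical effect there) is exposed
behind `ModelParams.squirmer_double_angle=False` for comparison.

Units: the default nondimensionalisation sets k = v = 1, so ω, t and
speeds are ω/(k v), t k v and U/v.  Dimensional parameters are accepted
everywhere.

## Crash threshold

The far-field model has no steric or lubrication physics, so "reaching the
wall" is a modelling boundary, not a resolved event.  A run counts as
crashed when z ≤ a for a finite-radius swimmer, or z ≤ 0.05/k for a point
swimmer; integration stops there.  The same height enters the time-optimal
solver as a path constraint.

## Local controllability

Around the straight free-swimming reference X_ref(t) the linearised system
X' = A(t) X + B(t) u is tested with the time-varying Kalman condition
det[B | B1 | B2] ≠ 0, B1 = B' − A B, B2 = B1' − A B1.  The determinant has
the closed form (derived symbolically and verified against a
finite-difference construction of the blocks to relative 1e−9)

    Δ(t) = ½ e^{−3 k z_r} k³ v ω_c cos θ0 ·
           [ω_c z_r cos φ_r + v cos θ0 sin φ_r],

with ω_c = ω + k v sin θ0 (the rate at which the swimmer crosses the wave
phase), z_r(t) = z0 + t v cos θ0 and φ_r(t) = k x0 − ω_c t.  Δ factorises
through k, v, ω_c and cos θ0; each zero is a physically meaningful
degeneracy:

* k = 0 — a uniformly sliding wall cannot rotate the swimmer;
* v = 0 — a passive particle only follows one flow line;
* ω_c = 0 — the swimmer surfs the wave and never changes cell;
* cos θ0 = 0 — wall-parallel swimming: at constant height the x- and
  θ-columns of the actuation are proportional for all time, so the full
  three-state linearised test is singular.  (Planar transport itself still
  works in this case; only simultaneous independent control of x, z and θ
  around the straight reference is lost.)

Outside these cases Δ has isolated zeros only and the nonlinear system is
locally controllable around the reference.

## Transport estimates

For wall-parallel guidance (θ0 ≈ −π/2, wave fast compared with the
swimmer) the optimal amplitude schedule switches sign whenever the swimmer
crosses a cell border, i.e. with sin(k x − ω t).  Freezing z and θ over
one inter-switch interval gives, writing v_x = −v sin θ0 for the swimmer's
horizontal velocity and V0 = u_max e^{−k z0}(1 − k z0):

* flow gain      v_flow = (2|V0|/π) [1 − (k/ω)(v_x + 2|V0|/π)]
* switch time    T_switch = π / (ω − k (v_x + v_flow))
* minimal time   T_min = (x1 − x0) / (v + v_flow)
* boost at 2/k   b = v_flow / v = (2 e^{−2}/π) u_max / v .

The sign of the v_x term in the first two formulas was fixed against
direct simulation (the switch spacing of a synchronised run is the
cell-crossing time π/(ω − k·ẋ) with ẋ = v_x + v_flow; the alternative
sign predicts spacings 40–65% off, the resolved form is within a few
percent of both the feedback runs and the converged optimal solutions).
|V0| is maximal at z0 = 2/k, making that the optimal transport height, and
the boost formula is the ω → ∞ limit evaluated there (8.6% at u_max = v,
43% at u_max = 5v).

At ω = 4 the finite-frequency correction *reduces* the gain below the
ω → ∞ value: within the cell-riding mechanism the strongest tabulated
operating point (|V0| = 0.62, ω = 4) yields an effective-speed increase of
≈ 30%, not the ≈ 45–50% that the uncorrected-sign estimate would suggest.

The estimates describe the cell-riding mechanism — switching synchronised
with the flow cells at a roughly constant height z ≈ z0 > 1/k.  The
unrestricted time-optimal solution at the same operating point does
something better: it dives below the flow-null height to just above the
crash floor, rides the much stronger near-wall flow (local horizontal
speeds ≈ 2.5 v), and climbs back to z0, for an effective-speed gain of
≈ 41% (final time 4.451 against the free-swimming 2π; the value is
converged across shooting-grid resolutions and its switching pattern is
reproduced by the backward-integrated adjoint).  Because the closed-form
estimates are derived under the frozen-height assumption, the
estimate-versus-numerics comparisons are made within that class
(`SolverOptions(z_floor=1/k)` keeps the solver above the flow-null
height); the dive optimum is reported separately as the package's
headline transport figure.  `scripts/acceptance.py` reports the honestly
computed values.

The constant-control horizontal motion has an exact closed form: with
z, θ frozen, ψ = k x − ω t obeys the driven-pendulum equation
ψ' = k V0 sin ψ − ω_c, solved by a half-angle (Riccati) substitution:

    x(t) = (1/k)[ω t + 2 arctan*((k V0 − ω_0 tan(ω_0 (t−T0)/2)) / ω_c)],

ω_0 = sqrt(ω_c² − V0² k²), with arctan* unwrapped across half-periods so x
is continuous.  T0 is the integration constant (cell-entry instant),
exposed as an argument.  A simplified variant that drops the drift from
the pendulum frequency is kept for reference (`exact=False`); it agrees
with the exact form to O(V0 k / ω) after removing an integration-constant
offset.  The flow contributes ≈ 2 V0/ω per half-period, the basis of the
flow-gain estimate.

## Time-optimal solver

The Hamiltonian is affine in u, so optimal controls are bang-bang with
switching function h = e^{−kz}[(px(1−kz) + pθ k/2) sin φ − pz k z cos φ];
h vanishing on an interval would force p = 0, so singular arcs are absent.
The adjoint convention is ṗ = −(∂f/∂X)ᵀ p, the one under which maximising
H selects u = u_max sgn(h).

The solver exploits the bang-bang structure directly.  A candidate control
is an initial sign plus segment durations; SLSQP minimises the total time
subject to the fixed terminal components (equality constraints) and a
smooth minimum-height path constraint (softmin over the integration nodes
with sharpness β = 120, a conservative lower bound on min z; the floor is
the crash threshold, or 1/k when the cell-riding class is requested).  All
gradients are analytic: the backward adjoint sweep of the RK4
discretisation yields the classical switch-time formula
∂y_T/∂τ_j = Φ(T, τ_j)[f(τ_j⁻) − f(τ_j⁺)] plus the node-time shifts for the
path functional.  For transport problems each seed is polished inside its
own switching basin (switch times bounded within ±0.45 T_switch of the
seed), which keeps SLSQP from stepping across flow-cell borders on the
oscillatory constraint landscape.  Deterministic seeds come from
cell-synchronised square waves at the analytic switch period and from
rollouts of heuristic policies:

* parallel transport — the synchronised feedback law;
* reorientation — a latched three-phase policy (approach the wall with the
  vertical flow, rotate inside a height band with optional cos-quadrant
  height regulation, escape), rolled out over a small family of band
  configurations; orientation targets are treated modulo 2π and both
  rotation senses are tried (rotating through "pointing down" keeps the
  swimmer pressed to the wall and is often far faster than the naive
  sense);
* wall distance — a monotone descent/ascent policy.

If the minimise-time run stalls infeasible, a feasibility-restoration pass
(least-squares on the terminal residual) precedes a second minimisation.
For parallel transport the result is optionally polished by a direct
single-shooting transcription (piecewise-constant control on N = 100
intervals, free final time via t = T·s, exact discrete-adjoint gradients),
snapped back to bang-bang segments and re-polished.  Converged solutions
are re-integrated with a high-order adaptive scheme (rtol 1e−8/atol 1e−10,
segment-wise between switches) for reporting; an indirect
maximum-principle check (backward adjoint integration from a scanned
terminal costate, transversality zeroing the costates of free components)
reproduces the observed switching signs on ≥ 95% of samples for the
transport solutions.

Solver tolerances: terminal equality 1e−6 on the solver's own RK4 grid
(50–90 sub-steps per unit time); the independent re-integration agrees to
≈ 1e−5 for the longest reorientation runs.  Below-wall states reached
only by optimiser line searches evaluate a frozen flow (z clamped at
−0.5/k) so the NLP stays smooth; converged solutions never enter that
region because of the path constraint.

## Driving policies

The open-loop square wave u(t) = u_max sgn(sin(π t / T_switch + phase))
and the feedback law u = −u_max sgn(sin(k x − ω t)) are integrated with
event-accurate switching (time events for the former, state events located
by root finding for the latter; the step size is capped so no step can
straddle two cell borders).  Metrics are computed over the full run with
no transient trimming: mean horizontal speed, boost over free swimming,
minimum wall distance, crash flag, net rotation.

The standard driven-run configuration starts at (x, z, θ) = (0, 3, −π/2)
with u_max = 5 for T = 5 at ω = 4 (the transport-regime frequency; the
driven-run experiments do not state their own ω, so the value is shared
with the transport scenarios).  The open-loop period is the switch-time
estimate evaluated at the initial height; it drifts from the true optimal
period as the state evolves, which is what makes the open-loop run
desynchronise (boost ≈ −12% against ≈ +30% for feedback).  An explicit
relative-period-error sweep quantifies the open-loop robustness margin.

For the squirmer experiments the radius is set to a = 0.3 (units of 1/k):
small enough that the far-field approximation z ≫ a holds along the
trajectories, large enough that B2 = ±20 produces the documented modest
trajectory bending.  The minimum wall distance over the run is monotone in
B2 (pushers repelled, pullers attracted), and the puller loses transport
speed as it tilts into the wall.

## Scenario heights

Characteristic speeds |V0| < u_max e^{−2} are realised at two heights; the
presets use the outer branch z0 > 2/k, where the vertical flow and the
rotation drift are weakest for a given |V0| (the inner branch reaches the
same |V0| with roughly twice the rotational disturbance).

## Problem sizes in the shipped tests

The test suite solves the transport problem on the full 6-point grid
(|V0| ∈ {0.62, 0.34} × ω ∈ {4, 8, 12}), two of the three reorientation
pairs ((−π/4, −3π/4) and (−π, 0); the third, (−π/2, π/2), is exercised
through the shipped preset and was verified to solve via the
long-way-round rotation sense), and one wall-distance problem matched to
the reorientation approach phase.  Expensive solutions are session-scoped
fixtures shared across tests.

## What the tests do and do not show

All experiments are synthetic: the model is the far-field wall flow plus,
optionally, the leading-order squirmer images.  Passing tests demonstrate
internal consistency (closed forms against independent finite-difference,
complex-step, fixed-step and fine-tolerance ODE oracles; solver output
against analytic estimates; structural properties of optimal and driven
trajectories).  They do not validate near-field hydrodynamics, finite-size
or inertial corrections, measurement noise in the feedback law, or any
property of real cilia carpets.

## Known limitations

* The reorientation solver returns a locally optimal bang-bang schedule
  seeded from a heuristic; no global-optimality certificate is attempted.
* The minimum-height path constraint uses a softmin lower bound, so
  converged trajectories keep a small (≈ 0.01–0.05) margin above the
  nominal crash height.
* The wall-parallel degeneracy of the linearised controllability test
  (cos θ0 = 0) means the three-state local test is uninformative exactly
  in the most-used transport configuration; transport there is assessed
  by the solver and policy experiments instead.
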