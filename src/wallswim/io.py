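"""Scenario configuration, named presets and trajectory writers.

A scenario bundles the physical parameters, the initial state and either a
driving policy with a horizon or a minimum-time problem specification.
Scenarios round-trip losslessly through YAML (numbers are serialised at
full double precision); unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.optimize import brentq

from wallswim.dynamics import ModelParams, SwimmerState, Trajectory
from wallswim.policies import PolicySpec

__all__ = [
    "Scenario",
    "ScenarioError",
    "load_scenario",
    "save_scenario",
    "write_trajectory",
    "read_trajectory",
    "make_figure_fixtures",
    "back_solve_height",
]


class ScenarioError(ValueError):
    """Configuration file is missing, malformed or schema-invalid."""


class _Params(BaseModel):
    model_config = ConfigDict(extra="forbid")
    v: float = 1.0
    a: float = 0.0
    B2: float = 0.0
    k: float = 1.0
    omega: float = 4.0
    u_max: float
    u_min: Optional[float] = None
    include_wall_interaction: bool = False
    squirmer_double_angle: bool = True


class _Policy(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["none", "open_loop", "feedback"]
    T_switch: Optional[float] = None
    phase: float = 0.0


class _Problem(BaseModel):
    model_config = ConfigDict(extra="forbid")
    id: Literal[1, 2, 3]
    x1: Optional[float] = None
    z1: Optional[float] = None
    theta1: Optional[float] = None


class Scenario(BaseModel):
    """Validated scenario: parameters + initial state + task."""

    model_config = ConfigDict(extra="forbid")

    name: str = "scenario"
    params: _Params
    x0: float = 0.0
    z0: float
    theta0: float
    T: Optional[float] = None          # horizon for policy runs
    policy: Optional[_Policy] = None
    problem: Optional[_Problem] = None
    notes: str = ""

    @model_validator(mode="after")
    def _check_task(self) -> "Scenario":
        if self.policy is not None and self.T is None:
            raise ValueError("policy scenarios need a horizon T")
        if self.policy is not None and self.policy.kind == "open_loop" and (
            self.policy.T_switch is None or self.policy.T_switch <= 0
        ):
            raise ValueError("open_loop policy requires T_switch > 0")
        return self

    # -- conversions -------------------------------------------------------
    def model_params(self) -> ModelParams:
        return ModelParams(**self.params.model_dump())

    def initial_state(self) -> SwimmerState:
        return SwimmerState(self.x0, self.z0, self.theta0)

    def policy_spec(self) -> PolicySpec:
        if self.policy is None:
            raise ScenarioError(f"scenario {self.name!r} has no policy")
        return PolicySpec(
            kind=self.policy.kind,
            u_max=self.params.u_max,
            T_switch=self.policy.T_switch,
            phase=self.policy.phase,
        )


def load_scenario(path: str | Path) -> Scenario:
    """Read and validate a YAML (or JSON) scenario file."""
    path = Path(path)
    if not path.exists():
        raise ScenarioError(f"scenario file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ScenarioError(f"cannot parse {path}: {exc}") from exc
    try:
        return Scenario.model_validate(data)
    except Exception as exc:
        raise ScenarioError(f"invalid scenario {path}: {exc}") from exc


def save_scenario(scenario: Scenario, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = scenario.model_dump(exclude_none=True)
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    metrics: dict | None = None,
) -> Path:
    """CSV with header t,x,z,theta,u at full precision, plus a JSON sidecar
    echoing the model parameters (and optional metrics)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["t,x,z,theta,u"]
    for t, (x, z, th), u in zip(traj.times, traj.states, traj.controls):
        lines.append(
            f"{float(t)!r},{float(x)!r},{float(z)!r},{float(th)!r},{float(u)!r}"
        )
    path.write_text("\n".join(lines) + "\n")
    sidecar = {
        "crashed": traj.crashed,
        "params": asdict(traj.params) if traj.params is not None else None,
        "metrics": metrics,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    """Inverse of :func:`write_trajectory` (CSV part)."""
    rows = Path(path).read_text().strip().splitlines()
    if rows[0] != "t,x,z,theta,u":
        raise ScenarioError(f"{path} is not a trajectory file")
    if len(rows) == 1:
        raise ScenarioError(f"{path} contains no samples")
    data = np.array([[float(v) for v in r.split(",")] for r in rows[1:]])
    return Trajectory(data[:, 0], data[:, 1:4], data[:, 4])


def back_solve_height(V0_mag: float, u_max: float, k: float = 1.0) -> float:
    """Wall distance z0 > 2/k at which |V0(z0)| equals ``V0_mag``.

    Inverts |V0| = u_max e^{-k z0}(k z0 - 1) on the outer branch (beyond
    the optimum 2/k), where the vertical flow is weakest for a given
    characteristic speed.
    """
    if not 0 < V0_mag < u_max * math.exp(-2.0):
        raise ValueError(
            "V0 magnitude must lie in (0, u_max e^-2) for the outer branch"
        )
    f = lambda z: u_max * math.exp(-k * z) * (k * z - 1.0) - V0_mag
    return brentq(f, 2.0 / k, 50.0 / k)


def make_figure_fixtures(out_dir: str | Path | None = None) -> dict[str, Scenario]:
    """Named preset scenarios for the standard numerical experiments.

    * ``fig3a_w{4,8,12}`` / ``fig3b_w{4,8,12}`` — minimum-time parallel
      displacement from x = 0 to 2 pi/k at characteristic speeds
      |V0| = 0.62 and 0.34 (heights back-solved at u_max = 5).
    * ``fig4a/b/c`` — reorientation (theta0, theta1) in
      {(-pi/4, -3pi/4), (-pi, 0), (-pi/2, pi/2)} at z0 = 2.
    * ``fig5a/b/c/d/e`` — driven runs from (0, 3, -pi/2) until T = 5 with
      u_max = 5: desynchronised open loop, feedback, and feedback with
      squirmer-wall interaction B2 in {-20, -100, +20}.

    If ``out_dir`` is given the scenarios are also written as YAML files.
    """
    fixtures: dict[str, Scenario] = {}
    umax = 5.0

    for tag, V0 in (("a", 0.62), ("b", 0.34)):
        z0 = back_solve_height(V0, umax)
        for w in (4.0, 8.0, 12.0):
            name = f"fig3{tag}_w{int(w)}"
            fixtures[name] = Scenario(
                name=name,
                params=_Params(u_max=umax, omega=w),
                x0=0.0, z0=z0, theta0=-math.pi / 2,
                problem=_Problem(id=1, x1=2 * math.pi),
                notes=(
                    f"|V0|={V0} realised with u_max={umax} at the outer-branch "
                    f"height z0={z0!r}"
                ),
            )

    pairs = {
        "a": (-math.pi / 4, -3 * math.pi / 4),
        "b": (-math.pi, 0.0),
        "c": (-math.pi / 2, math.pi / 2),
    }
    for tag, (th0, th1) in pairs.items():
        name = f"fig4{tag}"
        fixtures[name] = Scenario(
            name=name,
            params=_Params(u_max=umax, omega=4.0),
            x0=0.0, z0=2.0, theta0=th0,
            problem=_Problem(id=2, theta1=th1),
            notes="reorientation at fixed return height z0=2",
        )

    from wallswim.analytic import switch_time

    Tsw5 = switch_time(3.0, -math.pi / 2, ModelParams(u_max=umax, omega=4.0))
    fig5 = {
        "a": dict(policy=_Policy(kind="open_loop", T_switch=Tsw5)),
        "b": dict(policy=_Policy(kind="feedback")),
        "c": dict(policy=_Policy(kind="feedback"), B2=-20.0),
        "d": dict(policy=_Policy(kind="feedback"), B2=-100.0),
        "e": dict(policy=_Policy(kind="feedback"), B2=20.0),
    }
    for tag, cfg in fig5.items():
        B2 = cfg.get("B2", 0.0)
        name = f"fig5{tag}"
        fixtures[name] = Scenario(
            name=name,
            params=_Params(
                u_max=umax, omega=4.0, B2=B2, a=0.3 if B2 else 0.0,
                include_wall_interaction=bool(B2),
            ),
            x0=0.0, z0=3.0, theta0=-math.pi / 2,
            T=5.0,
            policy=cfg["policy"],
            notes=(
                "open-loop period from the switch-time estimate at z0"
                if tag == "a" else ""
            ),
        )

    if out_dir is not None:
        out = Path(out_dir)
        for name, sc in fixtures.items():
            save_scenario(sc, out / f"{name}.yaml")
    return fixtures
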