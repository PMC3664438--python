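"""Closed-loop integration of the coupled agent-environment system.

A trial couples the ring world to the CTRNN controller: the agent's motion
generates the sensor derivative that drives the network that sets the
velocity that moves the agent.  Integration is forward Euler on a uniform
grid; the sensor derivative is computed analytically as ``v * ds/dp``
(exact for a static field), with a backward-difference mode available as a
cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.special import expit as _sigma

from .agent import AgentParams, AgentState, motor_velocity
from .world import World, sense, sense_gradient, wrap, wrapped_distance

__all__ = [
    "SimState",
    "Trajectory",
    "Outcome",
    "OutcomeThresholds",
    "run_trial",
    "behavior_outcome",
    "DEFAULT_T",
    "DEFAULT_DT",
    "DEFAULT_START_OFFSET",
]

DEFAULT_T = 100.0
DEFAULT_DT = 0.01
#: Canonical trial protocol: the agent starts this many world units from the
#: shape center (wrapped), network state at rest.
DEFAULT_START_OFFSET = 8.0


@dataclass
class SimState:
    """Full system state: time, body position, network state."""

    t: float = 0.0
    p: float = 0.0
    agent: AgentState = field(default_factory=AgentState)


@dataclass
class Trajectory:
    """Uniformly sampled record of a closed-loop trial.

    Series: position ``p``, sensor ``s``, sensor derivative ``ds``,
    network activations ``y1``/``y2`` and velocity ``v``; the invariant
    ``ds[k] == v[k] * ds/dp(p[k])`` holds at every stored sample (analytic
    mode).
    """

    t: np.ndarray
    p: np.ndarray
    s: np.ndarray
    ds: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    v: np.ndarray
    world: World
    params: AgentParams
    init: SimState
    dt: float
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.t)

    def to_csv(self, path, metadata_path=None) -> None:
        """Write ``t,p,s,ds,y1,y2,v`` rows plus a JSON metadata sidecar."""
        path = Path(path)
        data = np.column_stack([self.t, self.p, self.s, self.ds,
                                self.y1, self.y2, self.v])
        header = "t,p,s,ds,y1,y2,v"
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt="%.17g")
        meta = {
            "world": self.world.to_dict(),
            "params": self.params.to_dict(),
            "init": {"t": self.init.t, "p": self.init.p,
                     "y1": self.init.agent.y1, "y2": self.init.agent.y2},
            "dt": self.dt,
            "seed": self.seed,
        }
        mpath = Path(metadata_path) if metadata_path else path.with_suffix(".meta.json")
        mpath.write_text(json.dumps(meta, indent=2))


@dataclass(frozen=True)
class OutcomeThresholds:
    """Decision constants for labelling a trial.

    approach: mean wrapped distance over the final ``tail_frac`` of the
    trial below ``approach_factor * w``; avoid: final distance exceeds both
    the initial distance and ``avoid_factor * w``; otherwise undecided.
    First contact (for the oscillation flag) is the first sample with
    ``s > contact_level``.
    """

    approach_factor: float = 2.0
    avoid_factor: float = 4.0
    tail_frac: float = 0.2
    contact_level: float = 0.05
    min_sign_changes: int = 3


@dataclass(frozen=True)
class Outcome:
    """Behavioral verdict of one trial against one target shape."""

    final_distance: float
    tail_mean_distance: float
    initial_distance: float
    label: Literal["approach", "avoid", "undecided"]
    oscillation: bool
    n_sign_changes: int
    dwell_side: float  # sign of mean signed offset from the peak over the tail


def run_trial(
    world: World,
    params: AgentParams,
    init: SimState | None = None,
    T: float = DEFAULT_T,
    dt: float = DEFAULT_DT,
    ds_mode: Literal["analytic", "finite"] = "analytic",
    velocity_override: float | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Integrate the closed loop for duration ``T`` with Euler step ``dt``.

    Per step: read ``s`` and the field gradient at ``p``; form the sensor
    derivative from the current velocity; advance the network; recompute
    the velocity; move and wrap the body.  Deterministic: identical inputs
    give bit-identical trajectories.

    ``velocity_override`` clamps the velocity to a constant (open-loop test
    hook).  ``ds_mode="finite"`` feeds the network a backward difference of
    ``s`` instead of the analytic rate (zero at the first step).
    """
    if not T > 0:
        raise ValueError(f"duration must be positive, got T={T}")
    if not (0 < dt <= 0.05):
        raise ValueError(f"step must satisfy 0 < dt <= 0.05, got dt={dt}")
    if init is None:
        init = SimState()
    n = int(round(T / dt))
    L = world.circumference

    t_arr = np.empty(n + 1)
    p_arr = np.empty(n + 1)
    s_arr = np.empty(n + 1)
    ds_arr = np.empty(n + 1)
    y1_arr = np.empty(n + 1)
    y2_arr = np.empty(n + 1)
    v_arr = np.empty(n + 1)

    w11, w21 = params.w11, params.w21
    th1, th2 = params.theta1, params.theta2
    tau1, tau2 = params.tau1, params.tau2
    g_s, vmax = params.g_s, params.v_max

    t = float(init.t)
    p = wrap(float(init.p), L)
    y1 = float(init.agent.y1)
    y2 = float(init.agent.y2)
    v = (velocity_override if velocity_override is not None
         else vmax * (2.0 * _sigma(y2 + th2) - 1.0))
    s_prev = None

    for k in range(n + 1):
        s = sense(world, p)
        if ds_mode == "analytic":
            ds = v * sense_gradient(world, p)
        else:
            ds = 0.0 if s_prev is None else (s - s_prev) / dt
            s_prev = s
        t_arr[k] = t
        p_arr[k] = p
        s_arr[k] = s
        ds_arr[k] = ds
        y1_arr[k] = y1
        y2_arr[k] = y2
        v_arr[k] = v
        if k == n:
            break
        act = _sigma(y1 + th1)
        y1 = y1 + dt * (-y1 + w11 * act + g_s * ds) / tau1
        y2 = y2 + dt * (-y2 + w21 * act) / tau2
        if not (np.isfinite(y1) and np.isfinite(y2)):
            raise RuntimeError(
                f"non-finite network state at step {k + 1} (t={t + dt:.4f})"
            )
        if velocity_override is None:
            v = vmax * (2.0 * _sigma(y2 + th2) - 1.0)
        p = wrap(p + dt * v, L)
        t = init.t + (k + 1) * dt

    return Trajectory(t_arr, p_arr, s_arr, ds_arr, y1_arr, y2_arr, v_arr,
                      world=world, params=params, init=init, dt=dt, seed=seed)


def _sign_changes(v: np.ndarray) -> int:
    """Number of strict sign alternations, ignoring exact zeros."""
    signs = np.sign(v)
    signs = signs[signs != 0]
    if len(signs) < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs)))


def behavior_outcome(
    traj: Trajectory,
    target,
    thresholds: OutcomeThresholds = OutcomeThresholds(),
) -> Outcome:
    """Label a trial as approach / avoid / undecided w.r.t. a target shape."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    L = traj.world.circumference
    offs = wrapped_distance(traj.p, target.center, L)
    dist = np.abs(offs)
    d0 = float(dist[0])
    d_final = float(dist[-1])
    k_tail = int(np.floor((1.0 - thresholds.tail_frac) * len(traj)))
    tail_mean = float(np.mean(dist[k_tail:]))
    w = target.width

    if tail_mean < thresholds.approach_factor * w:
        label = "approach"
    elif d_final > d0 and d_final > thresholds.avoid_factor * w:
        label = "avoid"
    else:
        label = "undecided"

    contact = np.nonzero(traj.s > thresholds.contact_level)[0]
    if len(contact):
        nsc = _sign_changes(traj.v[contact[0]:])
    else:
        nsc = 0
    dwell = float(np.sign(np.mean(offs[k_tail:])))
    return Outcome(
        final_distance=d_final,
        tail_mean_distance=tail_mean,
        initial_distance=d0,
        label=label,
        oscillation=nsc >= thresholds.min_sign_changes,
        n_sign_changes=nsc,
        dwell_side=dwell,
    )
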