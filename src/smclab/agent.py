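"""Two-neuron continuous-time recurrent neural network (CTRNN) controller.

The controller is the smallest Beer-style network that supports the task:
the sensor derivative drives a self-recurrent interneuron, which drives a
motor neuron; the motor neuron's activation sets the agent's velocity
through a symmetric squashing map.  With a self-weight above 4 the
interneuron is bistable over a range of inputs, which is the dynamical
substrate of the approach/avoid decision.

    tau1 * dy1/dt = -y1 + w11 * sigma(y1 + theta1) + g_s * ds
    tau2 * dy2/dt = -y2 + w21 * sigma(y1 + theta1)
    v             = v_max * (2 * sigma(y2 + theta2) - 1)

with ``sigma`` the logistic function and ``ds`` the sensor time-derivative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import expit as sigma

__all__ = [
    "AgentParams",
    "AgentState",
    "internal_derivatives",
    "motor_velocity",
    "PARAM_RANGES",
    "load_agent",
    "save_agent",
]

#: Genome box: the admissible range of each evolvable parameter.  These are
#: conventional CTRNN-evolution ranges; v_max is fixed at 1 to remove the
#: speed/time-constant scaling degeneracy.
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "w11": (-16.0, 16.0),
    "w21": (-16.0, 16.0),
    "theta1": (-16.0, 16.0),
    "theta2": (-16.0, 16.0),
    "tau1": (0.1, 10.0),
    "tau2": (0.1, 10.0),
    "g_s": (-50.0, 50.0),
}


@dataclass(frozen=True)
class AgentParams:
    """Controller parameters.

    w11
        interneuron self-weight (dimensionless).
    w21
        interneuron-to-motor weight.
    theta1, theta2
        neuron biases.
    tau1, tau2
        time constants, in time units.
    g_s
        sensor-input gain applied to the sensor derivative.
    v_max
        speed scale, world units per time unit.
    """

    w11: float
    w21: float
    theta1: float
    theta2: float
    tau1: float
    tau2: float
    g_s: float
    v_max: float = 1.0

    def __post_init__(self):
        for name, (lo, hi) in PARAM_RANGES.items():
            val = getattr(self, name)
            if not (lo <= val <= hi):
                raise ValueError(
                    f"{name}={val} outside admissible range [{lo}, {hi}]"
                )
        if not self.v_max > 0:
            raise ValueError(f"v_max must be positive, got {self.v_max}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AgentParams":
        d = dict(d)
        d.setdefault("v_max", 1.0)  # legacy files may omit the fixed scale
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown agent parameter key(s): {sorted(extra)}")
        missing = known - set(d)
        if missing:
            raise ValueError(f"agent document missing key(s): {sorted(missing)}")
        return cls(**d)


@dataclass
class AgentState:
    """Instantaneous network state: interneuron y1 and motor neuron y2."""

    y1: float = 0.0
    y2: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.y1) and np.isfinite(self.y2)):
            raise ValueError("agent state must be finite")

    def copy(self) -> "AgentState":
        return AgentState(self.y1, self.y2)


def internal_derivatives(params: AgentParams, state: AgentState, inp: float):
    """Time derivatives (dy1/dt, dy2/dt) given sensor-derivative input."""
    act = sigma(state.y1 + params.theta1)
    dy1 = (-state.y1 + params.w11 * act + params.g_s * inp) / params.tau1
    dy2 = (-state.y2 + params.w21 * act) / params.tau2
    return float(dy1), float(dy2)


def motor_velocity(params: AgentParams, state: AgentState) -> float:
    """Velocity from the motor activation: v_max * (2*sigma(y2+theta2) - 1).

    Odd in (y2 + theta2), strictly increasing, bounded in (-v_max, v_max).
    """
    return float(params.v_max * (2.0 * sigma(state.y2 + params.theta2) - 1.0))


# -- file I/O ----------------------------------------------------------

def save_agent(params: AgentParams, path, extra: dict | None = None) -> None:
    """Write parameters as a flat JSON document (optionally with provenance)."""
    doc = params.to_dict()
    if extra:
        doc = {**doc, "provenance": extra}
    Path(path).write_text(json.dumps(doc, indent=2))


def load_agent(path) -> AgentParams:
    doc = json.loads(Path(path).read_text())
    doc.pop("provenance", None)
    return AgentParams.from_dict(doc)
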