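"""Closed-loop sensorimotor habitat: trajectory ensembles and quasi-static structure.

The quasi-static analysis clamps the network's sensory drive ``I = g_s * ds``
as a fixed parameter and asks where the internal dynamics would settle.  For
the two-neuron chain only the interneuron equation matters:

    F(y1) = -y1 + w11 * sigma(y1 + theta1) + I = 0,

the motor neuron and velocity being slaved to ``y1`` at steady state.  Roots
of ``F`` are fixed points, stable iff ``F'(y1) < 0``.  Writing
``G(y1) = y1 - w11 * sigma(y1 + theta1)``, fixed points are preimages of
``I`` under ``G``; for ``w11 > 4`` the logistic slope makes ``G`` fold back
on itself, producing a bistable input window bounded by two saddle-node
(fold) inputs that are available in closed form.  Sweeping ``I`` yields the
bifurcation diagram; evaluating the clamped input cell-by-cell over a
(position, velocity) grid yields the attractor landscape that explains which
way the agent tends to move at each point of its sensorimotor environment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import label as _cc_label
from scipy.optimize import brentq
from scipy.special import expit as sigma, logit

from .agent import AgentParams, AgentState, motor_velocity
from .simulate import Trajectory, run_trial, SimState, DEFAULT_T, DEFAULT_DT
from .world import World, sense_gradient, wrap

__all__ = [
    "FixedPoint",
    "Folds",
    "BifurcationDiagram",
    "AttractorLandscape",
    "SamplingSpec",
    "HabitatEnsemble",
    "solve_fixed_points",
    "fold_inputs",
    "bifurcation_diagram",
    "attractor_landscape",
    "tendency",
    "sample_habitat",
    "clamped_relaxation",
]

_TANGENT_TOL = 1e-8


@dataclass(frozen=True)
class FixedPoint:
    """Steady state of the clamped network at drive ``I``."""

    I: float
    y1: float
    y2: float
    v: float
    stable: bool


def _motor_of_y1(params: AgentParams, y1):
    """Slaved steady-state motor activation and velocity for a given y1."""
    y2 = params.w21 * sigma(np.asarray(y1) + params.theta1)
    v = params.v_max * (2.0 * sigma(y2 + params.theta2) - 1.0)
    return y2, v


def _make_fp(params: AgentParams, I: float, y1: float, stable: bool) -> FixedPoint:
    y2, v = _motor_of_y1(params, y1)
    return FixedPoint(I=float(I), y1=float(y1), y2=float(y2), v=float(v),
                      stable=bool(stable))


def solve_fixed_points(params: AgentParams, I: float,
                       scan_step: float = 1e-3) -> list[FixedPoint]:
    """All fixed points of the clamped interneuron at drive ``I``.

    Dense sign-change scan over ``y1`` (the root magnitude is bounded by
    ``|I| + |w11|``, padded to +20) followed by bisection to 1e-12.
    Stability from the sign of ``F'``; near-tangent points
    (``|F'| < 1e-8``) are flagged non-stable.
    """
    if not np.isfinite(I):
        raise ValueError("clamped input must be finite")
    w11, th1 = params.w11, params.theta1
    lo, hi = -abs(I) - 20.0, abs(I) + 20.0
    y = np.arange(lo, hi + scan_step, scan_step)
    F = -y + w11 * sigma(y + th1) + I

    def f(x):
        return -x + w11 * sigma(x + th1) + I

    roots: list[float] = []
    exact = np.nonzero(F == 0.0)[0]
    roots.extend(float(y[i]) for i in exact)
    sign_change = np.nonzero(F[:-1] * F[1:] < 0)[0]
    for i in sign_change:
        roots.append(brentq(f, y[i], y[i + 1], xtol=1e-12))
    roots.sort()

    out = []
    for r in roots:
        fprime = -1.0 + w11 * _dsigma(r + th1)
        stable = fprime < 0 and abs(fprime) >= _TANGENT_TOL
        out.append(_make_fp(params, I, r, stable))
    return out


def _dsigma(x):
    s = sigma(x)
    return s * (1.0 - s)


@dataclass(frozen=True)
class Folds:
    """Saddle-node structure of the clamped interneuron (``w11 > 4`` only).

    ``I_low < I_high`` bound the bistable input window; ``y_low_branch_max``
    and ``y_high_branch_min`` are the critical activations where the folds
    occur (lower fold at the larger input, by the shape of ``G``).
    """

    I_low: float
    I_high: float
    y_crit_low: float   # smaller critical y1 (local max of G -> I_high)
    y_crit_high: float  # larger critical y1 (local min of G -> I_low)


def fold_inputs(params: AgentParams) -> Folds | None:
    """Closed-form fold (saddle-node) inputs, or None if monostable.

    Critical points solve ``w11 * sigma'(y1 + theta1) = 1``, i.e.
    ``sigma = (1 +/- sqrt(1 - 4/w11)) / 2``, which requires ``w11 > 4``.
    """
    w11, th1 = params.w11, params.theta1
    if w11 <= 4.0:
        return None
    disc = np.sqrt(1.0 - 4.0 / w11)
    s_lo = (1.0 - disc) / 2.0
    s_hi = (1.0 + disc) / 2.0
    y_a = float(logit(s_lo) - th1)
    y_b = float(logit(s_hi) - th1)
    G = lambda y1: y1 - w11 * sigma(y1 + th1)
    return Folds(I_low=float(G(y_b)), I_high=float(G(y_a)),
                 y_crit_low=y_a, y_crit_high=y_b)


@dataclass
class BifurcationDiagram:
    """Fixed-point branches over an input sweep.

    ``branches`` is a list of dicts with arrays ``I``, ``y1`` and a boolean
    ``stable`` array; ``bifurcation_points`` holds the fold inputs located
    within the sweep.  Branch count per input is 1 or 3 for this
    architecture; folds come in pairs or are absent.
    """

    I_values: np.ndarray
    branches: list[dict]
    bifurcation_points: list[float]

    def branch_count(self, I: float) -> int:
        n = 0
        for b in self.branches:
            if b["I"][0] - 1e-12 <= I <= b["I"][-1] + 1e-12:
                n += 1
        return n

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bid, b in enumerate(self.branches):
            for I, y1, st in zip(b["I"], b["y1"], b["stable"]):
                rows.append((I, y1, bool(st), bid))
        return pd.DataFrame(rows, columns=["I", "y1", "stable", "branch_id"])


def bifurcation_diagram(params: AgentParams, I_range=(-5.0, 5.0),
                        I_step: float = 0.01) -> BifurcationDiagram:
    """Sweep the clamped input and assemble branches by y1-continuity.

    Fold inputs are refined by bisection on the root count and reported
    where the branch count changes inside the sweep.
    """
    lo, hi = I_range
    if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
        raise ValueError("invalid input range")
    if not I_step > 0:
        raise ValueError("I_step must be positive")
    I_values = np.arange(lo, hi + 0.5 * I_step, I_step)

    open_branches: list[dict] = []
    closed: list[dict] = []
    counts = np.empty(len(I_values), dtype=int)
    for k, I in enumerate(I_values):
        fps = solve_fixed_points(params, float(I))
        counts[k] = len(fps)
        assigned = [False] * len(open_branches)
        next_open: list[dict] = []
        # greedy nearest-neighbor matching of roots to branch tips
        for fp in fps:
            best, best_d = None, np.inf
            for bi, b in enumerate(open_branches):
                if assigned[bi]:
                    continue
                d = abs(b["y1"][-1] - fp.y1)
                if d < best_d:
                    best, best_d = bi, d
            if best is not None and best_d < 1.0:
                assigned[best] = True
                b = open_branches[best]
                b["I"].append(float(I))
                b["y1"].append(fp.y1)
                b["stable"].append(fp.stable)
                next_open.append(b)
            else:
                next_open.append({"I": [float(I)], "y1": [fp.y1],
                                  "stable": [fp.stable]})
        for bi, b in enumerate(open_branches):
            if not assigned[bi]:
                closed.append(b)
        open_branches = next_open
    closed.extend(open_branches)
    branches = [{"I": np.array(b["I"]), "y1": np.array(b["y1"]),
                 "stable": np.array(b["stable"], dtype=bool)} for b in closed]

    bif_points: list[float] = []
    for k in range(len(I_values) - 1):
        if counts[k] != counts[k + 1]:
            a, b = float(I_values[k]), float(I_values[k + 1])
            na = counts[k]
            for _ in range(60):  # bisection on root count
                mid = 0.5 * (a + b)
                if len(solve_fixed_points(params, mid)) == na:
                    a = mid
                else:
                    b = mid
            bif_points.append(0.5 * (a + b))
    return BifurcationDiagram(I_values, branches, sorted(bif_points))


# -- vectorized stable-root machinery ---------------------------------

def _bisect_vec(gfun, lo, hi, iters: int = 80):
    """Vectorized bisection for an increasing function on [lo, hi]."""
    lo = np.array(lo, dtype=float, copy=True)
    hi = np.array(hi, dtype=float, copy=True)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        neg = gfun(mid) < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    return 0.5 * (lo + hi)


def stable_y1_branches(params: AgentParams, I):
    """Stable steady-state y1 values for an array of clamped inputs.

    Returns ``(y_low, y_high)`` arrays: NaN where the branch does not exist.
    For a monostable network the unique root is reported in ``y_low``.
    """
    I = np.asarray(I, dtype=float)
    w11, th1 = params.w11, params.theta1
    G = lambda y: y - w11 * sigma(y + th1)
    pad = abs(w11) + 1.0
    folds = fold_inputs(params)
    y_low = np.full(I.shape, np.nan)
    y_high = np.full(I.shape, np.nan)
    if folds is None:
        y_low[...] = _bisect_vec(lambda y: G(y) - I, I - pad, I + pad)
        return y_low, y_high
    m_low = I <= folds.I_high  # lower branch exists up to the upper fold
    m_high = I >= folds.I_low
    if np.any(m_low):
        Im = I[m_low]
        y_low[m_low] = _bisect_vec(lambda y: G(y) - Im,
                                   Im - pad,
                                   np.full(Im.shape, folds.y_crit_low))
    if np.any(m_high):
        Im = I[m_high]
        y_high[m_high] = _bisect_vec(lambda y: G(y) - Im,
                                     np.full(Im.shape, folds.y_crit_high),
                                     Im + pad)
    return y_low, y_high


#: Landscape class codes.
CLASS_POSITIVE = 1
CLASS_NEGATIVE = -1
CLASS_BISTABLE = 0
_CLASS_NAMES = {CLASS_POSITIVE: "positive", CLASS_NEGATIVE: "negative",
                CLASS_BISTABLE: "bistable"}


@dataclass
class AttractorLandscape:
    """Per-cell steady-state velocity structure over (position, velocity).

    ``classes[i, j]`` is +1 (all stable attractors move positively), -1
    (negatively) or 0 (bistable with opposite signs); ``v_low``/``v_high``
    hold the stable steady-state velocities (NaN where a branch is absent).
    """

    p_grid: np.ndarray
    v_grid: np.ndarray
    classes: np.ndarray
    v_low: np.ndarray
    v_high: np.ndarray
    params: AgentParams
    world: World

    def class_name(self, i: int, j: int) -> str:
        return _CLASS_NAMES[int(self.classes[i, j])]

    def monostable_region_counts(self) -> dict:
        """Connected monostable regions (4-connectivity) by velocity sign."""
        _, n_pos = _cc_label(self.classes == CLASS_POSITIVE)
        _, n_neg = _cc_label(self.classes == CLASS_NEGATIVE)
        return {"positive": int(n_pos), "negative": int(n_neg),
                "total": int(n_pos + n_neg)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, p in enumerate(self.p_grid):
            for j, v in enumerate(self.v_grid):
                vs = [x for x in (self.v_low[i, j], self.v_high[i, j])
                      if np.isfinite(x)]
                rows.append((p, v, _CLASS_NAMES[int(self.classes[i, j])],
                             ";".join(f"{x:.17g}" for x in vs)))
        return pd.DataFrame(rows, columns=["p", "v", "class", "v_stable_list"])


def attractor_landscape(world: World, params: AgentParams,
                        p_grid, v_grid) -> AttractorLandscape:
    """Classify every (p, v) cell by the sign set of its stable attractors.

    The cell's clamped drive is ``I = g_s * v * ds/dp(p)`` — the sensory
    rate the agent would experience there, held fixed.  Cells whose stable
    steady-state velocities all share a sign are monostable of that sign;
    cells with both signs present are bistable.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    v_grid = np.asarray(v_grid, dtype=float)
    if p_grid.size == 0 or v_grid.size == 0:
        raise ValueError("grids must be nonempty")
    grad = np.atleast_1d(sense_gradient(world, p_grid))
    I = params.g_s * np.outer(grad, v_grid)
    y_low, y_high = stable_y1_branches(params, I)
    _, v_low = _motor_of_y1(params, y_low)
    _, v_high = _motor_of_y1(params, y_high)
    v_low = np.where(np.isfinite(y_low), v_low, np.nan)
    v_high = np.where(np.isfinite(y_high), v_high, np.nan)

    classes = np.empty(I.shape, dtype=np.int8)
    has_low = np.isfinite(v_low)
    has_high = np.isfinite(v_high)
    s_low = np.where(v_low >= 0, CLASS_POSITIVE, CLASS_NEGATIVE)
    s_high = np.where(v_high >= 0, CLASS_POSITIVE, CLASS_NEGATIVE)
    only_low = has_low & ~has_high
    only_high = has_high & ~has_low
    both = has_low & has_high
    classes[only_low] = s_low[only_low]
    classes[only_high] = s_high[only_high]
    same = both & (s_low == s_high)
    classes[same] = s_low[same]
    classes[both & ~same] = CLASS_BISTABLE
    return AttractorLandscape(p_grid, v_grid, classes, v_low, v_high,
                              params, world)


def clamped_relaxation(params: AgentParams, I, y1_0, T: float = 500.0,
                       dt: float = 0.01):
    """Integrate the clamped interneuron from y1_0 for T time units (Euler).

    Vectorized over matching arrays of inputs and initial conditions;
    serves as the dynamical oracle for the algebraic fixed points.
    """
    I = np.asarray(I, dtype=float)
    y1 = np.array(np.broadcast_to(np.asarray(y1_0, dtype=float), I.shape),
                  copy=True)
    n = int(round(T / dt))
    w11, th1, tau1 = params.w11, params.theta1, params.tau1
    for _ in range(n):
        y1 += dt * (-y1 + w11 * sigma(y1 + th1) + I) / tau1
    return y1


def tendency(params: AgentParams, state: AgentState, I: float,
             T_max: float = 200.0, dt: float = 0.01,
             tol: float = 1e-3) -> FixedPoint | None:
    """Attractor the clamped system converges to from ``state``.

    Integrates the clamped dynamics for up to ``T_max`` time units and
    matches the endpoint to a stable fixed point within ``tol`` in y1.
    Returns None (with a warning) when the endpoint matches none — e.g.
    when started exactly on the basin boundary (the unstable point).
    """
    fps = solve_fixed_points(params, I)
    stable = [fp for fp in fps if fp.stable]
    if not stable:
        raise ValueError(f"no stable fixed point at I={I}")
    y1_end = float(clamped_relaxation(params, np.array([I]),
                                      np.array([state.y1]), T=T_max, dt=dt)[0])
    for fp in stable:
        if abs(fp.y1 - y1_end) <= tol:
            return fp
    warnings.warn(
        f"clamped relaxation did not reach a stable fixed point "
        f"(endpoint y1={y1_end:.6g}); state may sit on a basin boundary",
        stacklevel=2,
    )
    return None


# -- trajectory ensembles ---------------------------------------------

@dataclass(frozen=True)
class SamplingSpec:
    """Battery of closed-loop trials spanning the habitat's parameter ranges.

    Each trial places a single shape at mid-ring with width drawn from
    ``widths``, height uniform in ``height_range``, start offset uniform in
    ``offset_range`` with a random sign, and initial network state uniform
    in the given boxes.
    """

    n: int
    widths: tuple[float, ...] = (1.0, 3.0)
    height_range: tuple[float, float] = (0.5, 1.0)
    offset_range: tuple[float, float] = (6.0, 10.0)
    y1_range: tuple[float, float] = (0.0, 0.0)
    y2_range: tuple[float, float] = (0.0, 0.0)
    circumference: float = 40.0
    T: float = DEFAULT_T
    dt: float = DEFAULT_DT


@dataclass
class HabitatEnsemble:
    """Trajectories plus the sampling specification that produced them."""

    members: list[Trajectory]
    spec: SamplingSpec
    seed: int

    def __len__(self) -> int:
        return len(self.members)

    def save(self, directory) -> None:
        """Write one trajectory CSV per member plus a manifest JSON."""
        import json
        from dataclasses import asdict
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        names = []
        for i, traj in enumerate(self.members):
            name = f"trajectory_{i:04d}.csv"
            traj.to_csv(directory / name)
            names.append(name)
        manifest = {"seed": self.seed, "spec": asdict(self.spec),
                    "members": names}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def sample_habitat(params: AgentParams, spec: SamplingSpec,
                   seed: int) -> HabitatEnsemble:
    """Draw and run ``spec.n`` trials; deterministic under ``seed``."""
    if spec.n <= 0:
        raise ValueError("sampling spec must request at least one trial")
    if not spec.widths:
        raise ValueError("sampling spec must list at least one width")
    rng = np.random.default_rng(seed)
    L = spec.circumference
    c = 0.5 * L
    members = []
    for _ in range(spec.n):
        w = float(rng.choice(spec.widths))
        h = float(rng.uniform(*spec.height_range))
        off = float(rng.uniform(*spec.offset_range))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        y1 = float(rng.uniform(*spec.y1_range))
        y2 = float(rng.uniform(*spec.y2_range))
        world = World.single(width=w, height=h, L=L)
        init = SimState(t=0.0, p=wrap(c - sign * off, L),
                        agent=AgentState(y1=y1, y2=y2))
        members.append(run_trial(world, params, init, T=spec.T, dt=spec.dt,
                                 seed=seed))
    return HabitatEnsemble(members, spec, seed)
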