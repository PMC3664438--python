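"""Sensorimotor coordination: reliable (meta)stable patterns tied to function.

The habitat's trajectories are projected into the plane of sensory and motor
*rates of change* (ds/dt against dm/dt, with m the motor neuron activation).
A sustained closed orbit there is a limit cycle of the coupled
agent-environment system — notably not of the clamped internal dynamics,
which only has fixed points.  A pattern (cycle or reliable transient) counts
as a sensorimotor coordination when it recurs across a battery of trials and
co-occurs with task success.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agent import AgentParams, AgentState
from .simulate import (DEFAULT_DT, DEFAULT_START_OFFSET, DEFAULT_T, Outcome,
                       OutcomeThresholds, SimState, Trajectory,
                       _sign_changes, behavior_outcome, run_trial)
from .world import World, wrap

__all__ = [
    "RatesPortrait",
    "CycleDetection",
    "CoordinationReport",
    "CategoryMap",
    "TrialProtocol",
    "rates_portrait",
    "detect_limit_cycle",
    "avoidance_transient_signature",
    "classify_coordination",
    "category_map",
]


@dataclass
class RatesPortrait:
    """Time-aligned (ds/dt, dm/dt) series from a trajectory.

    Central differences of ``s`` and ``y2`` over the stored grid (the two
    endpoint samples are dropped).  ``transient_end`` marks the first
    post-transient index: 30% of the trial or first contact with the shape,
    whichever is later.
    """

    t: np.ndarray
    ds_dt: np.ndarray
    dm_dt: np.ndarray
    transient_end: int

    def post_transient(self):
        k = self.transient_end
        return self.t[k:], self.ds_dt[k:], self.dm_dt[k:]

    def ds_over_dm(self) -> np.ndarray:
        """Local habitat descriptor ds/dm; NaN where dm/dt vanishes."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.ds_dt / self.dm_dt
        return np.where(np.abs(self.dm_dt) > 1e-12, r, np.nan)


@dataclass(frozen=True)
class CycleDetection:
    """Outcome of the recurrence test on one portrait."""

    cycle_detected: bool
    period: float | None
    amplitude: float
    n_returns: int


@dataclass(frozen=True)
class CoordinationReport:
    """Aggregated verdict over a trial battery.

    ``reliability`` is the fraction of trials exhibiting the pattern;
    ``functional`` requires the pattern-bearing trials to succeed at the
    task; the pattern is a sensorimotor coordination iff both hold.
    """

    cycle_detected: bool
    period: float | None
    amplitude: float
    reliability: float
    functional: bool
    is_sm_coordination: bool
    n_trials: int


def rates_portrait(traj: Trajectory,
                   contact_level: float = 0.05) -> RatesPortrait:
    """Project a trajectory into the sensorimotor-rates plane."""
    if len(traj) < 3:
        raise ValueError("trajectory too short for central differences")
    dt = traj.dt
    ds_dt = (traj.s[2:] - traj.s[:-2]) / (2.0 * dt)
    dm_dt = (traj.y2[2:] - traj.y2[:-2]) / (2.0 * dt)
    t = traj.t[1:-1]
    n = len(t)
    k30 = int(np.floor(0.3 * n))
    contact = np.nonzero(traj.s[1:-1] > contact_level)[0]
    k_contact = int(contact[0]) if len(contact) else 0
    transient_end = min(max(k30, k_contact), n - 1)
    return RatesPortrait(t=t, ds_dt=ds_dt, dm_dt=dm_dt,
                         transient_end=transient_end)


def detect_limit_cycle(portrait: RatesPortrait,
                       tol: float | None = None) -> CycleDetection:
    """Recurrence test for a sustained orbit in the rates plane.

    The reference point is the farthest-from-origin point within the final
    30% of the post-transient segment (the asymptotic regime, so that a
    settling prefix cannot hijack the anchor); returns are entries into its
    tolerance ball (default 5% of the maximum radius) passing with the same
    tangent direction.  A cycle requires at least 3 trailing returns with
    inter-return times within 10% of each other and no outward drift of the
    return points; the period is the median inter-return time.
    """
    t, x, y = portrait.post_transient()
    if len(t) == 0:
        raise ValueError("post-transient segment is empty")
    pts = np.column_stack([x, y])
    radius = np.hypot(x, y)
    amplitude = float(radius.max())
    if amplitude <= 0:
        return CycleDetection(False, None, 0.0, 0)
    k_tail = int(np.floor(0.7 * len(t)))
    if tol is None:
        tol = 0.05 * amplitude
        # the ball must be resolvable at the sampling rate: near the
        # fastest orbit segment consecutive samples can jump further than
        # a purely geometric tolerance, letting passes skip over the ball
        if len(pts) > k_tail + 1:
            spacing = np.linalg.norm(np.diff(pts[k_tail:], axis=0), axis=1)
            tol = max(tol, 2.0 * float(spacing.max()))
    if len(pts) >= 3:
        tangent = np.gradient(pts, axis=0)
    else:
        tangent = np.zeros_like(pts)

    # candidate anchors: high-radius points of the asymptotic tail, thinned
    # so a once-in-several-cycles outlier cannot monopolize the test
    tail_idx = np.arange(k_tail, len(pts))
    order = tail_idx[np.argsort(radius[tail_idx])[::-1]]
    keep = order[: max(1, len(order) // 5)]
    candidates = [int(keep[0])]
    for k in keep[1:]:
        if all(abs(int(k) - c) > 25 for c in candidates):
            candidates.append(int(k))
        if len(candidates) >= 6:
            break

    best = CycleDetection(False, None, amplitude, 0)
    for k0 in candidates:
        ref = pts[k0]
        ref_dir = tangent[k0]
        d = np.linalg.norm(pts - ref, axis=1)
        inside = d < tol
        # entry events into the tolerance ball, same tangent direction
        entries = []
        for i in range(1, len(pts)):
            if inside[i] and not inside[i - 1]:
                if np.dot(tangent[i], ref_dir) > 0:
                    entries.append(i)
        # local minimum of d within each visit approximates the return;
        # a visit truncated by the end of the record is discarded
        returns = []
        for i in entries:
            j = i
            while j + 1 < len(pts) and inside[j + 1] and d[j + 1] <= d[j]:
                j += 1
            if j + 1 < len(pts):
                returns.append(j)
        n_ret = len(returns)
        if n_ret > best.n_returns:
            best = CycleDetection(False, None, amplitude, n_ret)
        if n_ret < 3:
            continue
        # judge the trailing (asymptotic) run of returns
        trail = np.array(returns[-8:])
        intervals = np.diff(t[trail])
        intervals = intervals[intervals > 0]
        if len(intervals) < 2:
            continue
        med = float(np.median(intervals))
        if med <= 0 or (intervals.max() - intervals.min()) > 0.1 * med:
            continue
        # orbit must not spiral outward: later returns stay as close to ref
        if np.any(np.diff(d[trail]) > 0.25 * tol):
            continue
        return CycleDetection(True, med, amplitude, n_ret)
    return best


def avoidance_transient_signature(traj: Trajectory,
                                  contact_level: float = 0.05) -> bool:
    """Reliable-transient signature of avoidance: one decisive act, no dithering.

    After first contact the velocity changes sign at most once — the agent
    either sweeps straight through the shape, or reverses once at the
    encounter and departs.  Any subsequent alternation (scanning) breaks
    the signature.
    """
    contact = np.nonzero(traj.s > contact_level)[0]
    if len(contact) == 0:
        return False
    v_post = traj.v[contact[0]:]
    signs = np.sign(v_post)
    signs = signs[signs != 0]
    if len(signs) == 0:
        return False
    return _sign_changes(v_post) <= 1


def classify_coordination(detections: list[CycleDetection | bool],
                          outcomes: list[Outcome],
                          expected_label: str,
                          r_min: float = 0.9) -> CoordinationReport:
    """Aggregate per-trial pattern detections into a coordination verdict.

    ``detections`` holds either ``CycleDetection`` results or plain booleans
    (for transient signatures).  The pattern is reliable when present in at
    least ``r_min`` of trials, and functional when at least ``r_min`` of the
    pattern-bearing trials carry the expected behavioral label.
    """
    if len(detections) == 0:
        raise ValueError("empty trial battery")
    if len(detections) != len(outcomes):
        raise ValueError("detections and outcomes are misaligned")
    present = np.array([
        d.cycle_detected if isinstance(d, CycleDetection) else bool(d)
        for d in detections
    ])
    success = np.array([o.label == expected_label for o in outcomes])
    reliability = float(np.mean(present))
    n_pat = int(np.count_nonzero(present))
    functional = bool(n_pat > 0
                      and np.count_nonzero(present & success) >= r_min * n_pat)
    periods = [d.period for d in detections
               if isinstance(d, CycleDetection) and d.cycle_detected]
    amplitudes = [d.amplitude for d in detections
                  if isinstance(d, CycleDetection)]
    any_cycle = any(isinstance(d, CycleDetection) and d.cycle_detected
                    for d in detections)
    return CoordinationReport(
        cycle_detected=any_cycle,
        period=float(np.median(periods)) if periods else None,
        amplitude=float(np.median(amplitudes)) if amplitudes else 0.0,
        reliability=reliability,
        functional=functional,
        is_sm_coordination=bool(reliability >= r_min and functional),
        n_trials=len(detections),
    )


@dataclass(frozen=True)
class TrialProtocol:
    """Canonical single-shape trial used for mapping behavior over shapes."""

    circumference: float = 40.0
    start_offset: float = DEFAULT_START_OFFSET
    T: float = DEFAULT_T
    dt: float = DEFAULT_DT
    thresholds: OutcomeThresholds = OutcomeThresholds()


@dataclass
class CategoryMap:
    """Behavior labels over a (width, height) grid of shapes.

    ``labels[i, j]`` is the outcome for ``height_grid[i]`` x
    ``width_grid[j]``; per height row, ``boundaries[i]`` is the midpoint
    between the last approached and first avoided width (NaN when the row
    never flips), and ``multi_flip[i]`` flags rows whose approach/avoid
    pattern is not a single monotone transition.
    """

    width_grid: np.ndarray
    height_grid: np.ndarray
    labels: np.ndarray
    boundaries: np.ndarray
    multi_flip: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, h in enumerate(self.height_grid):
            for j, w in enumerate(self.width_grid):
                rows.append((w, h, self.labels[i, j]))
        return pd.DataFrame(rows, columns=["width", "height", "label"])


def category_map(params: AgentParams, width_grid, height_grid,
                 protocol: TrialProtocol = TrialProtocol()) -> CategoryMap:
    """One canonical trial per (width, height) cell, labelled by outcome."""
    width_grid = np.asarray(width_grid, dtype=float)
    height_grid = np.asarray(height_grid, dtype=float)
    L = protocol.circumference
    labels = np.empty((len(height_grid), len(width_grid)), dtype=object)
    for i, h in enumerate(height_grid):
        for j, w in enumerate(width_grid):
            world = World.single(width=float(w), height=float(h), L=L)
            c = world.objects[0].center
            init = SimState(p=wrap(c - protocol.start_offset, L),
                            agent=AgentState())
            traj = run_trial(world, params, init, T=protocol.T, dt=protocol.dt)
            labels[i, j] = behavior_outcome(traj, world.objects[0],
                                            protocol.thresholds).label

    boundaries = np.full(len(height_grid), np.nan)
    multi = np.zeros(len(height_grid), dtype=bool)
    for i in range(len(height_grid)):
        row = labels[i]
        app = [j for j in range(len(row)) if row[j] == "approach"]
        avd = [j for j in range(len(row)) if row[j] == "avoid"]
        if app and avd:
            boundaries[i] = 0.5 * (width_grid[max(app)] + width_grid[min(avd)])
            # monotone: every approach width below every avoid width
            multi[i] = max(app) > min(avd)
    return CategoryMap(width_grid, height_grid, labels, boundaries, multi)
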