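"""Combined SMC report: one agent, all four sensorimotor analyses.

Bundles the open-loop surface extrema, the quasi-static landscape region
counts, and the coordination verdicts for approach and avoidance into one
JSON-serializable document.  The sensorimotor-strategy slot is present but
never filled by an analysis: assessing a strategy requires comparing
repertoires of coordinations across task variants, which this minimal task
does not support.
"""

from __future__ import annotations

import numpy as np

from .agent import AgentParams, AgentState
from .coordination import (classify_coordination, detect_limit_cycle,
                           rates_portrait, avoidance_transient_signature)
from .environment import check_symmetry, compute_surface, default_grids, find_extrema
from .habitat import attractor_landscape, fold_inputs, solve_fixed_points
from .simulate import SimState, behavior_outcome, run_trial
from .world import World, wrap

__all__ = ["build_smc_report", "coordination_battery"]


def coordination_battery(params: AgentParams, width: float, expected: str,
                         n: int = 10, seed: int = 0, L: float = 40.0,
                         offset_range=(6.0, 10.0), T: float = 100.0,
                         dt: float = 0.01, r_min: float = 0.9):
    """Run n single-shape trials and aggregate the coordination verdict.

    For an expected "approach" the pattern sought is a limit cycle in the
    rates plane; for "avoid", the single-pass transient signature.
    """
    rng = np.random.default_rng(seed)
    c = 0.5 * L
    detections, outcomes = [], []
    for _ in range(n):
        h = float(rng.uniform(0.5, 1.0))
        off = float(rng.uniform(*offset_range))
        side = 1.0 if rng.random() < 0.5 else -1.0
        world = World.single(width=width, height=h, L=L)
        init = SimState(p=wrap(c - side * off, L), agent=AgentState())
        traj = run_trial(world, params, init, T=T, dt=dt)
        outcomes.append(behavior_outcome(traj, world.objects[0]))
        if expected == "approach":
            detections.append(detect_limit_cycle(rates_portrait(traj)))
        else:
            detections.append(avoidance_transient_signature(traj))
    return classify_coordination(detections, outcomes, expected, r_min=r_min)


def build_smc_report(params: AgentParams, seed: int = 0,
                     narrow_width: float = 1.0, wide_width: float = 3.0,
                     height: float = 0.75, L: float = 40.0,
                     n_coord_trials: int = 10,
                     landscape_p_step: float = 0.05,
                     landscape_v_step: float = 0.025) -> dict:
    """All analyses for one agent on canonical narrow and wide shapes."""
    report: dict = {"environment": {}, "habitat": {}, "coordination": {},
                    "sm_strategy": None}

    for name, w in (("narrow", narrow_width), ("wide", wide_width)):
        world = World.single(width=w, height=height, L=L)
        c = world.objects[0].center
        p_grid, v_grid = default_grids(world)
        surface = compute_surface(world, p_grid, v_grid)
        extrema = find_extrema(surface)
        report["environment"][name] = {
            "n_extrema": len(extrema),
            "n_peaks": sum(e["kind"] == "peak" for e in extrema),
            "n_troughs": sum(e["kind"] == "trough" for e in extrema),
            "extrema": extrema,
            "symmetry_residual": check_symmetry(surface, c),
            "max_abs_value": float(np.max(np.abs(surface.values))),
        }

        pg = c + np.arange(-3.0 * w, 3.0 * w + 1e-9, landscape_p_step)
        vg = np.arange(-1.0, 1.0 + 1e-9, landscape_v_step)
        scape = attractor_landscape(world, params, pg, vg)
        report["habitat"][name] = {
            "monostable_regions": scape.monostable_region_counts(),
        }

    folds = fold_inputs(params)
    report["habitat"]["folds"] = (
        None if folds is None else {"I_low": folds.I_low, "I_high": folds.I_high}
    )
    fps0 = solve_fixed_points(params, 0.0)
    report["habitat"]["stable_velocities_at_zero_input"] = [
        fp.v for fp in fps0 if fp.stable
    ]

    report["coordination"]["approach"] = _report_dict(
        coordination_battery(params, narrow_width, "approach",
                             n=n_coord_trials, seed=seed, L=L))
    report["coordination"]["avoid"] = _report_dict(
        coordination_battery(params, wide_width, "avoid",
                             n=n_coord_trials, seed=seed + 1, L=L))
    return report


def _report_dict(r) -> dict:
    return {
        "cycle_detected": r.cycle_detected,
        "period": r.period,
        "amplitude": r.amplitude,
        "reliability": r.reliability,
        "functional": r.functional,
        "is_sm_coordination": r.is_sm_coordination,
        "n_trials": r.n_trials,
    }
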