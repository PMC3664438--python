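# Methods

## The model

A point agent moves on a ring of circumference `L = 40` world units.  The
ring carries a static scalar field built from bell-shaped objects: an object
with center `c`, height `h ∈ (0, 1]` and width `w > 0` contributes
`h · exp(−d(p, c)² / 2w²)`, with `d` the signed minimal wrapped distance.
Contributions sum and the field is clipped at 1 ("normalized proximity");
all analyses place objects far enough apart (centers ≥ 6·max w) that the
clip never operates away from a lone peak with `h = 1`.

The agent's only receptor reads the field height at its own position, and
the *time-derivative* of that reading, `Δs = v · ds/dp`, is the sole input
to its controller — a two-neuron continuous-time recurrent neural network
(CTRNN):

    τ₁ ẏ₁ = −y₁ + w₁₁ σ(y₁ + θ₁) + g_s Δs
    τ₂ ẏ₂ = −y₂ + w₂₁ σ(y₁ + θ₁)
    v     = v_max (2 σ(y₂ + θ₂) − 1)

with `σ` the logistic function.  The interneuron `y₁` is self-recurrent and
drives the motor neuron `y₂`; the motor activation sets the velocity through
a symmetric squashing map so both travel directions are reachable.  There is
no sensor→motor shortcut and no motor self-loop.  The body closes the loop:
`ṗ = v`, wrapped onto the ring.

The task is active categorical perception: approach the peak of narrow
shapes (`w = 1`) and move away from wide ones (`w = 3`), with heights drawn
per trial from `[0.5, 1.0]` so that no instantaneous reading identifies the
category — only the sensorimotor dynamics of self-motion can.

### Parameters

| parameter | meaning | range / default |
|---|---|---|
| `w₁₁` | interneuron self-weight | [−16, 16], evolved |
| `w₂₁` | interneuron→motor weight | [−16, 16], evolved |
| `θ₁, θ₂` | biases | [−16, 16], evolved |
| `τ₁, τ₂` | time constants (time units) | [0.1, 10], evolved |
| `g_s` | sensor gain on Δs | [−50, 50], evolved |
| `v_max` | speed scale (world units / time unit) | fixed 1 |
| `L` | ring circumference | 40 |
| `dt` | Euler step | 0.01 |
| `T` | trial duration | 100 time units |
| start offset | wrapped distance from shape center at t = 0 | 8 (protocol), {6, 8, 10} (battery) |

`v_max` is fixed because rescaling it is equivalent to rescaling time
constants and the ring: evolving it would add a pure degeneracy.  The box
bounds are conventional CTRNN-evolution ranges; forward Euler at
`dt = 0.01` is empirically stable over the whole box (checked over 1,000
random draws for 100 time units).

## The four sensorimotor analyses

**SM environment** (open loop).  Cutting the motor equation makes velocity a
free command; the sensory consequence of issuing `v` at `p` is
`S(p, v) = v · ds/dp(p)`.  The surface is a body+world property — no
controller parameter enters.  For one symmetric object it obeys
`S(c+δ, v) = S(c−δ, −v)` exactly and has two peaks and two troughs at the
flanks of greatest slope (`p = c ∓ w` at the velocity bounds).  Extrema are
found by strict 8-neighbor comparison with the zero plateau excluded, so the
flat background never yields spurious extrema.

**SM habitat** (closed loop).  Trajectory ensembles are sampled over start
offsets, shape parameters and initial states (deterministic per seed).  The
quasi-static analysis clamps the network drive `I = g_s Δs` as a parameter.
Only the interneuron equation matters at steady state; fixed points are the
roots of `F(y₁) = −y₁ + w₁₁ σ(y₁+θ₁) + I`, stable iff `F′ < 0`.  Because
`σ′ ≤ 1/4`, any `w₁₁ ≤ 4` is monostable for every input; for `w₁₁ > 4` the
map folds, producing a bistable window bounded by two saddle-node inputs
that are available in closed form (critical activations solve
`w₁₁ σ′ = 1`).  The scalar solver follows the stated contract (dense
sign-change scan at step 1e−3, bisection to 1e−12, tangent tolerance 1e−8);
the landscape uses an algebraically equivalent vectorized bisection per
monotone branch, cross-checked against the scalar solver in the tests.
Landscape cells are classified by the sign set of their stable steady-state
velocities (positive / negative / bistable); connected monostable regions
are counted with 4-connectivity.

**SM coordination.**  Trajectories are projected into the plane of sensory
and motor *rates* (central differences of `s` and of the motor activation
`y₂`; `y₂` rather than `v` because the two are monotonically related and
`y₂` is the network's own motor coordinate).  The transient prefix is
`max(30% of the trial, first contact)`, with contact at `s > 0.05`.  Cycle
detection is a recurrence test anchored in the asymptotic regime (the
settling phase of an approach has a larger radius and would otherwise
hijack the anchor): candidate reference points are high-radius samples from
the final 30% of the post-transient segment, thinned so a
once-per-several-cycles outlier cannot monopolize the test, and returns are
entries into the tolerance ball of a candidate with matching tangent
direction.  The ball is 5% of the maximum radius, widened to twice the
largest consecutive-sample spacing so a fast orbit segment cannot step over
it at dt = 0.01.  A cycle needs ≥ 3 trailing returns with inter-return
times within 10% and no outward drift; the period is the median
inter-return time.  A pattern is a sensorimotor coordination iff it
appears in ≥ r_min = 0.9 of battery trials *and* the trials bearing it
succeed at the task (we require ≥ r_min of them to carry the expected
label).  Avoidance has no cycle; its reliable-transient signature is a
single decisive act — at most one post-contact velocity sign change,
covering both a straight sweep-through and a one-time reversal at the
encounter.

**SM strategy.**  The combined report contains a `sm_strategy` slot that is
always null: judging strategies requires comparing repertoires of
coordinations under normative pressure (efficiency, robustness), which this
single-task setup cannot exhibit.  The slot documents the scope boundary.

## Evolution

Genomes are 7 reals in `[0, 1]` mapped affinely onto the parameter box
(`v_max` excluded).  Fitness over a 12-trial battery (2 widths × 6 signed
offsets, heights drawn per trial): narrow trials score
`1 − min(1, d_final/d_start)`, wide trials `min(1, d_final/(L/2 −
d_start))`; fitness is the mean.  The optimizer is a generational GA:
rank-proportional selection, elitism of one, uniform crossover at rate 0.5,
per-gene Gaussian mutation (σ = 0.05) reflected into the unit cube.  During
search the battery heights are redrawn each generation so solutions cannot
overfit particular heights; the best-so-far fitness is always re-measured on
the run's fixed canonical battery, so reported values are reproducible and
never ride a lucky draw.

The shipped reference agent was produced by a warm-started run of this GA
(seed and fitness recorded in the fixture's provenance block) and selected
among successful evolved agents for the qualitative solution class analysed
throughout: oscillatory approach to narrow shapes, single-reversal
avoidance of wide ones, a four-region attractor landscape, and no stable
fixed point with `|v*| < 0.05` anywhere in the swept input range (so
dwelling near a peak is only possible by oscillating between attractors).
Its two attractor velocities are markedly asymmetric (≈ +0.86 fast
approach, ≈ −0.28 slow retreat); this asymmetry is what lets one and the
same controller oscillate on steep flanks yet retreat for good from
shallow ones: the drive needed to knock the state across the bistable band
scales with the current speed times the local slope, and only narrow-shape
slopes can do it at retreat speed.

## Numerical choices and degenerate cases

- Euler update order per step: read `s` and `ds/dp` at `p`; form
  `Δs = v · ds/dp`; update `y₁, y₂`; recompute `v`; move and wrap `p`.
  `Δs` is analytic (exact for a static field); a backward-difference mode
  exists for cross-checking and agrees to O(dt).
- Wrapped distance lives in `(−L/2, L/2]`; the sign at the exact antipode is
  positive by convention.  Exact periodicity of the field holds whenever
  `p` and `p + L` are both exactly representable.
- Outcome labels: approach iff the mean distance over the final 20% of the
  trial is `< 2w`; avoid iff the final distance exceeds both the initial
  distance and `4w`; else undecided.  The oscillation flag needs ≥ 3
  post-contact velocity sign changes.  These thresholds are package
  decisions; the task itself only defines qualitative goals.
- Bifurcation branches are assembled by nearest-`y₁` continuity across the
  sweep; fold locations are refined by bisection on the root count.
  Tangent (fold-touching) fixed points are flagged non-stable.
- `tendency` integrates the clamped system for up to 200 time units and
  matches the endpoint to a stable fixed point within 1e−3 in `y₁`; a state
  exactly on the basin boundary matches nothing and returns None with a
  warning.

## What the synthetic conditions do and do not show

All inputs are generated: Gaussian worlds, seeded trial batteries, and the
GA's own populations.  The generator mirrors the study conditions (ring 40,
widths 1 vs 3, heights 0.5–1.0, offsets 6–10, T = 100, dt = 0.01) — where
the underlying account leaves a value unstated these were fixed once as
conventional choices and not tuned afterwards.  Passing tests therefore
demonstrate properties of this idealized coupled system: a noiseless sensor,
a static environment, a single shape per trial, and first-order integration.
They do not speak to sensor noise, non-stationary worlds, or multi-object
scenes; the oscillation period in particular is a property of this agent on
this field shape, not a universal constant.

## Problem sizes

Default analysis grids: surface at steps (0.01, 0.01) over ±3 widths and
|v| ≤ 1; landscapes at (0.05, 0.025); bifurcation sweeps at ΔI = 0.01.  The
acceptance script uses a 40-trial held-out discrimination battery, 10
approach starts for period stability, 201 swept inputs for the fixed-point
scan, 1,000 random draws for the monostability check, and a GA run at the
default configuration (population 60, up to 300 generations, early stop at
fitness 0.9).  These sizes are the package's reporting defaults; all are
configurable.

## Known limitations

- The exact evolved parameters of the historical "best agent" for this task
  are not public; the shipped reference agent reproduces the solution class
  (counts, signs, cycle structure), not any particular printed velocity
  values.
- Forward Euler is first order; the dt-halving test bounds the endpoint
  drift on the reference approach trial to < 0.05 world units, but stiff
  parameter corners of the box would need smaller steps.
- Cycle detection assumes a roughly stationary asymptotic orbit; slowly
  drifting orbits (period drift > 10% per window) are reported as
  non-cycles by design.
- On a ring of 40 units a trial of 100 time units lets a fast agent lap the
  ring; avoidance scoring therefore rewards solutions that leave the shape
  and park far away, which the selected reference agent does by reversing
  into its slow attractor.
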