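# Methods

## Model

A growth cone is idealized as a semi-circle of radius R (default 10 μm),
decomposed into independent 1-D radial slices indexed by the angle
θ ∈ [0°, 180°]. Each slice holds a fixed ensemble of N microtubules whose
tips undergo dynamic instability: a growing tip switches to shrinking at the
catastrophe frequency f_cat and back at the rescue frequency f_res. A
microtubule couples to actin retrograde flow with probability
p_r(θ) = p_r0 (1 − A cos θ); a coupled tip is dragged rearward at the flow
speed v_r, so the effective tip speeds are

    v_g = v_plus − p_r v_r   (growing, toward the leading edge)
    v_s = v_minus + p_r v_r  (shrinking, away from it)

The leading-edge MT fraction p — tips strictly past the 75% line,
r > 0.75 R — feeds back on the flow through the adhesion force balance
v_r = v0 / (1 + β p), and local protrusion is v_cell = v_p − v_r. The net
protrusion angle θ_p is the polar angle of Σ_θ v_cell(θ) (cos θ, sin θ)
with equal angular weights; it is reported as undefined when the resultant
magnitude is below 1e-9·v0·n_angles.

Model assumptions worth keeping in mind: coupling depends only on θ, never
on the tip's radial position; the force balance is algebraic, so v_r tracks
p instantaneously (no adhesion kinetics); slices do not exchange MTs; and
there are no molecular motors, MT mechanics, or explicit actin filaments.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| f_cat | catastrophe frequency | 0.61 | 1/min |
| f_res | rescue frequency | 1.79 | 1/min |
| v_plus | MT polymerization speed | 6.0 | μm/min |
| v_minus | MT depolymerization speed | 9.6 | μm/min |
| v0 | maximum retrograde flow speed | 5.0 | μm/min |
| v_p | actin polymerization speed | 5.0 | μm/min |
| p_r0 | coupling probability at θ = 90° | 0.5 | — |
| A | gradient steepness, in [0, 1] | 0.0 | — |
| β | adhesion sensitivity to leading-edge MTs | 0.1 | — |
| R | growth cone radius | 10 | μm |

The rates and speeds are literature estimates from fluorescent imaging of
*Aplysia* bag cell growth cones; v_p = v0 puts the uncoupled system exactly
at treadmilling (zero protrusion), so any protrusion is clutch-driven.
Validity requires p_r0(1+A) ≤ 1 so that p_r is a probability at every
angle. R only sets absolute excursion lengths — the gradient enters purely
through the dimensionless A — so its value is a convention, not a fit.

The sign of v_g f_res − v_s f_cat classifies each slice: positive mean tip
drift ("unbounded" growth, tips persistently reach the leading edge),
negative drift ("bounded", exponential steady-state length distribution
with constant λ = 1/(f_cat/v_g − f_res/v_s)), and an explicitly flagged
marginal case. With the defaults and A = 0.9 the θ = 0 side is unbounded
(criterion +4.28) and the θ = 180 side bounded (−6.52), which is the
asymmetry the turning response rests on.

## Stochastic simulation scheme

Time is discretized with step dt (default 0.005 min). Per step and MT:
phase switches are Bernoulli with probability f·dt; the tip then moves with
its phase's effective speed for the full step; boundary rules are applied;
finally p is recounted and v_r updated from the force balance. Coupling
enters either as its mean (`coupling_mode="mean"`, drift v± ∓ p_r v_r,
the literal reading of the density equations) or as a fresh Bernoulli(p_r)
draw per MT per step (`"bernoulli"`); the two give statistically
indistinguishable steady states because the extra coupling noise adds a
diffusion term orders of magnitude below the switching-driven one.

Boundaries: a growing tip reaching R is clamped to the membrane and forced
into catastrophe; a shrinking tip reaching 0 is clamped and rescued,
modeling continual regrowth from the C domain. N is conserved. All MTs
start growing at r = 0, and v_r starts at v0.

Config invariants bound the discretization error: dt·max(f_cat, f_res) ≤
0.05 and dt·(v_plus+v_minus+v0) ≤ 0.1 R. Each angle runs on an RNG
substream keyed on (master seed, angle value in millidegrees), so results
are independent of grid order and fully reproducible from (config, seed).
Parameter sweeps give grid point k the seed `master+k`.

Steady-state averages use t > burn_in (defaults: t_total = 100 min,
burn_in = 50 min, N = 1000 per angle, 19 angles at 10° spacing). Standard
errors use batch means with 10 blocks (5-min blocks, longer than the
measured correlation time of p); calibration against 20 independent seeds
at (A=0.9, β=0.1, θ=0) gave run-to-run scatter 0.0016 vs mean estimated SE
0.0015.

## Mean-field oracle

The deterministic companion solves the two-state tip-density
advection–reaction equations on [0, R] with the same boundary conversions
(growing flux at R re-enters the shrinking density; shrinking flux at 0
re-enters the growing density), using first-order upwind finite volumes —
chosen for positivity and exact mass conservation over order of accuracy.
Steady states come either from a direct sparse solve of the stationary
system (one redundant row replaced by the mass-normalization constraint) or
by marching in time until the leading-edge mass fraction moves < 1e-8 per
check interval; the two paths agree to ~1e-11. The self-consistent fixed
point iterates p ← (1−ω) p + ω M(v_r(p)) with damping ω = 0.5 (the positive
feedback overshoots for large β; β = 0 short-circuits to a single map
evaluation). Default grid Δr = R/400; a refinement test (halving Δr changes
the leading-edge fraction by < 1%) backs the choice.

Two numerical caveats shape how the oracle is used in tests. First-order
upwinding smears the advective front, so transient agreement with the agent
ensemble is asserted only after the front has passed the 75% line (t ≥ 5 min
at p_r = 0.5). Second, the stochastic stepper's per-step Bernoulli switching
carries an O(f·dt) bias in the stationary leading-edge fraction — measured
at ~0.6% relative at dt = 0.005 — so the steady-state equivalence check runs
the agent at dt = 0.0025 and the PDE at Δr = R/1600, pooling three
replicates per parameter point; at that accuracy the residual bias is well
inside the 3-SE statistical tolerance at all five points spanning both
growth regimes.

## What the simulations do and do not emulate

All inputs are generated internally from the model; there is no external
data. The simulated conditions are the study conditions: the reference rate
table, p_r0 = 0.5, and sweeps over A and β. Passing tests therefore show
internal consistency (stochastic model vs mean-field limit vs closed
forms) and reproduction of the model's qualitative predictions — monotone
angular profiles, symmetry at A = 0, strongest turning at small nonzero β —
not agreement with live-cell imaging. Real growth cones have finite MT
number fluctuations shared across angles, adhesion kinetics with memory,
filopodia, and MT–MT interactions, none of which are represented.

## Degenerate inputs and tie-breaks

Ties at exactly r = 0.75 R do not count as leading-edge (strict
inequality; a measure-zero event). The marginal growth regime is its own
label rather than being binned. θ_p is `None` (CSV: NaN) for a zero net
protrusion vector, e.g. β = 0 with v_p = v0, where every local protrusion
vanishes identically. Parameter validation aggregates all violations into
one report.

## Problem sizes

Default runs (19 angles × 1000 MTs × 20 000 steps) take ~6 s per growth
cone on one CPU; the five-seed symmetry computation ~35 s; the full test
suite under two minutes. These sizes give θ_p estimates with ≲0.2°
scatter at A = 0 and leading-edge fractions with SE ≈ 0.0015 per angle.
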