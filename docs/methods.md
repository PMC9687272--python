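# Methods

## The model

`ulkswitch` implements a minimal mechanistic model of autophagy induction
control by the mTORC1–ULK1–PP2A regulatory triangle.  Each protein exists
in an active and an inactive (phosphorylated or otherwise silenced) form
inside a conserved total pool, and all conversions follow mass-action
kinetics.  Writing `m`, `u`, `p` for the active concentrations of mTORC1,
ULK1 and PP2A and `MT`, `UT`, `PT` for their totals:

    dm/dt = ka_m·(MT − m) − (ki_m + k_b·u + k_e·p)·m
    du/dt = (ka_u + k_c·p)·(UT − u) − (ki_u + k_a·m)·u
    dp/dt = (ka_p + k_d·u)·(PT − p) − (ki_p + k_f·m)·p

Activation always acts on the inactive pool and inhibition on the active
pool, so each variable is confined to `[0, XT]` (the box is forward
invariant).  The six interaction constants encode the network's three
positive circuits — two double-negative loops (mTORC1 ⊣ ULK1 ⊣ mTORC1 via
`k_a`/`k_b`, mTORC1 ⊣ PP2A ⊣ mTORC1 via `k_f`/`k_e`) and one positive loop
(ULK1 → PP2A → ULK1 via `k_d`/`k_c`).  Because every feedback circuit is
positive, the system is monotone after flipping the sign of `m`; it can be
bistable but cannot sustain a limit cycle.  That structural fact is what
the oscillation screen in the acceptance suite verifies numerically: the
experimentally observed slow periodicity of autophagy markers under
prolonged phosphatase inhibition is *outside* the scope of this core
model and would require at least one negative loop (e.g. an AMPK arm).

Units: time in minutes, concentrations dimensionless with every total
equal to 1 in the untreated cell.  Treatments are levers on the totals:

- rapamycin (100 nM) ↦ `MT = 0.1`, applied as a step at t = 0;
- okadaic acid ↦ `PT = 0.1` (100 nM) or `PT = 0.3` (the partial-inhibition
  phase-plane condition);
- siRNA silencing ↦ a reduced total applied *before* equilibration
  (cells are transfected ~24 h before treatment, so the silenced system
  is assumed fully relaxed at its reduced total when t = 0 arrives);
  `UT ∈ {0.01, 0.3}` for ULK1, `PT = 0.01` (full) or `0.25` (measured
  residual) for PP2A.

When a step reduces a total below the current active amount, the excess
active material is removed (clipped) at t = 0; the remainder is left to
the dynamics.  This is the natural reading of an inhibitor that acts on
the active complex, and it reproduces the immediate collapse of the
phospho-p70S6K readout after rapamycin.

## Observable mapping

The immunoblot readouts map onto the state as: `ulk1_757P = UT − u`
(Ser757-phosphorylated ULK1 is the inactive form), `pp2a_P = PT − p`, and
phospho-p70S6K ∝ `m` (p70S6K is a direct mTORC1 substrate, so its
phosphorylation tracks absolute kinase activity).  Densitometry ratios
divide the ULK1 and PP2A phospho bands by their total-protein bands
(`(XT − x)/XT`); the p70S6K readout is deliberately *not* divided by
`MT` — total p70S6K is a downstream substrate, not a model pool, and a
fraction-based readout would be blind to the rapamycin-induced collapse
of mTORC1 activity.  Every series is finally normalized to its own
untreated control (the replicate mean of the t = 0 sample), which is
therefore 1 by construction.

## Reference parameter set

No rate constants are tabulated for this network; they must be inferred
from time-course data.  The shipped reference set
(`data/reference_params.yaml`) was designed once, by a seeded stochastic
search scored purely on the qualitative behaviour the switch must show,
and then frozen:

1. bistability at physiological totals (two stable states separated by a
   saddle), with the mTORC1-dominant resting state selected from
   high-mTORC1 initial conditions;
2. collapse to a single autophagy state under rapamycin (`MT = 0.1`);
3. retention of both stable states under partial PP2A loss (`PT = 0.3`),
   with the resting cell staying non-autophagic;
4. monostable non-autophagy under acute okadaic acid (`PT = 0.1`);
5. the four combined-perturbation outcomes (ULK1 silencing blocks PP2A
   activation under rapamycin; okadaic acid plus rapamycin still
   activates ULK1; full PP2A silencing keeps ULK1 off);
6. a global time scale (all constants share a factor, which moves no
   equilibrium) chosen so the rapamycin-induced ULK1/PP2A activation
   develops after ~30 min while the p70S6K readout collapses within the
   first sampling interval — the kinetics the blots show.

The basal PP2A inactivation rate (`ki_p = 0.12/min`) is deliberately much
larger than its basal activation (`ka_p = 0.0003/min`): PP2A stays
phosphorylated unless ULK1 drives it, which is what makes ULK1 silencing
block PP2A activation even when mTORC1 is gone.

## Parameter estimation

The cost function simulates each measured condition from its
pre-treatment state, passes the trajectory through the identical
observable/normalization chain, and accumulates squared residuals against
replicate means, scaling each series by the inverse of its mean level so
the three readouts contribute comparably.  Candidates whose simulation
fails receive a large finite penalty (1e6) so optimizers keep moving.

The optimizer works in log10-space over default bounds `[1e-4, 1e2]`
(sub-minute to multi-day kinetics around the 60–180 min data window).
The global stage is a seeded Sobol multi-start (16 starts) of a bounded
trust-region least-squares solver; the three best starts are then run to
convergence within the evaluation budget.  A population-based global
search was tried first and rejected: within a 5 000-evaluation budget,
differential evolution repeatedly stalled in "switch-flipped" basins
(parameterizations that activate ULK1 under the wrong treatment) at
several times the noise-floor cost, while the multi-start least-squares
scheme reaches the noise floor on every tested seed.  The whole fit is
deterministic given its seed and never returns rates outside bounds.

### Identifiability, and why the default set is not a fit

Twelve rate constants against two 60-min, 7-point, self-normalized
triplicate series are heavily under-determined.  Fits routinely reach the
measurement-noise floor with rate vectors far from the generating truth,
sometimes pinned at the search bounds, and — decisively — sometimes with
a *different equilibrium landscape* (e.g. monostable at physiological
totals), because the acute time courses never visit the second branch of
the switch.  For this reason the shipped default parameter set used by
the catalog experiments is the curated reference set itself, not a fit
output; `run_pipeline` still performs the fit and writes the fitted
config plus diagnostics alongside, and the fit stage is validated by what
the data *do* constrain: the predicted treatment endpoints (steady-state
activities under rapamycin and okadaic acid) are recovered within 15%.
The `identifiability_report` profiles the cost one constant at a time
(±1 decade around the optimum, clipped to bounds) and flags directions
whose cost spread stays below 5% of the fitted cost, with a floor
corresponding to 1%-level residuals per point, below which cost
differences carry no information about data of this precision.

## Phase-plane reduction

Active PP2A enters its own balance linearly, so its nullcline solves in
closed form, `p_qss = (ka_p + k_d·u)·PT / (ka_p + k_d·u + ki_p + k_f·m)`,
and substituting it projects the 3-D system onto the (m, u) plane without
approximating equilibria: roots of the reduced 2-D system are exactly the
equilibria of the full system.  Balance curves are traced by bracketing
sign changes on a grid (≥100 points per axis) and polishing each point
with Brent's method.  Equilibria are enumerated by multi-start Newton
refinement seeded from a regular grid (default 30×30; the count is
verified stable up to 200×200 seeding in the test suite, and against an
exhaustive 400×400 sign-change-cell oracle in the acceptance suite),
merged at Euclidean tolerance 1e-6, accepted at residual < 1e-9, and
classified by the eigenvalues of the analytic 3×3 Jacobian with a ±1e-8
margin; a leading real part inside the margin sets an explicit `marginal`
flag rather than a silent call.  An equilibrium is labelled `autophagy`
iff its ULK1 active fraction exceeds its mTORC1 active fraction (ties go
to `non-autophagy`).

## Synthetic densitometry

The generator emulates the study's immunoblot design: triplicate
sampling every 10 min for 60 min (acute rapamycin / okadaic acid),
every 30 min for 180 min (prolonged okadaic acid), and 2-h endpoint
series for the combined perturbations.  Noise is multiplicative Gaussian
per band with cv = 0.10 (a typical replicate scatter for quantified
blots; the real experiments report mean ± SD of three measurements but
no noise magnitude), truncated positive, applied to the raw signals
before control normalization.  What it does *not* emulate: band
saturation and background subtraction artefacts, loading-control error,
correlated noise between proteins on one membrane, and biological
(as opposed to measurement) variability.  Passing the recovery tests
therefore shows the estimation machinery works at realistic noise
levels, not that the wet-lab series would identify the constants.

## Numerical choices

- Integrator: LSODA with analytic Jacobian, rtol 1e-8, atol 1e-10.
- Steady states: relaxation in doubling time chunks until ‖rhs‖ < 1e-8
  (horizon 1e5 min), then one Newton polish to round-off.
- Curve-point polish: Brent to xtol 1e-12; curve resolution floor 100.
- Cost evaluations share one physiological steady state per candidate.
- The densitometry CSV dialect writes `%.17g` and reads with pandas'
  round-trip parser, so files reproduce binary64 values exactly.

## Problem sizes

Default analysis sizes are desk scale: 30×30 equilibrium seeding,
15-value lever scans, 5 000-evaluation fits, 400×400 oracle grids, and
20 random parameter sets for the enumeration cross-check.

## Known limitations

- The model deliberately omits AMPK, LC3/p62 dynamics and autophagic
  flux; it describes induction signalling only.
- Sustained oscillations seen under intermediate phosphatase inhibition
  are out of reach of this wiring (no negative loop), by design.
- "Totals" conflate expression level and drug-accessible activity; a
  lever value such as `MT = 0.1` is a phenomenological inhibition depth,
  not a measured occupancy.
- Individual rate constants should not be interpreted from fits to
  acute time courses (see identifiability above).
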