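# Methods

## The model

Myonuclei in *Drosophila* larval ventral longitudinal (VL) muscles are
modelled as N interacting particles in a 2D rectangle `[-b, b] x [-l, l]`
(x across the cell, y along it; all lengths in um).  The regime is
overdamped (low Reynolds number): velocity equals net force, with the drag
coefficient normalised to 1, so one model time unit is the time a nucleus
under unit force needs to move 1 um.  The net force on nucleus i is the sum
of pairwise internuclear forces from all other nuclei, plus forces from the
normal projections of the nucleus onto the two cell sides and the two cell
poles, plus short-range size exclusion.

Every smooth interaction is a signed power law of separation,

    F(d) = sigma * M * (d / d_ref)^alpha * H(c - d),

with `sigma = +1` repulsive / `-1` attractive, relative amplitude `M >= 0`
(the internuclear amplitude is fixed to 1 and defines the force unit),
exponent `alpha` (falling / constant / growing with distance), finite reach
`c`, and `d_ref = 40 um`, the typical internuclear spacing.  Nuclear
overlap is prevented by the size exclusion `Q (1/d^2 - 1/D^2) H(D - d)`
with `Q = 2000`, `D = 2r` between nuclei and `D = r` against the boundary,
where `r = 7 um` is the nuclear radius.

A *model* fixes (sigma, alpha) of all three laws — 2^3 x 3^3 = 216
combinations; a *model class* fixes only the internuclear and side laws —
36 combinations (the pole-law form matters little for the pattern).

## Equilibria and the integrator

Equilibria are found by integrating the flow until every nucleus's velocity
2-norm falls below 1e-4 (in force units).  The integrator is an adaptive
embedded Euler/Heun pair with per-step error control (default step error
1e-4 um; the screens use 1e-3 um — path accuracy is irrelevant for
equilibria, whose accuracy is set by the residual rule) and step rejection
whenever a trial step leaves the open rectangle; positions are never
clamped.

Two numerical measures deal with the discontinuous Heaviside cut-offs:

* **Cut-off smoothing.**  Inside the dynamics each finite cut-off is closed
  by a C1 smoothstep ramp of width 0.5 um.  Without it, equilibria that sit
  *on* a cut-off surface (sliding states in the Filippov sense — e.g. a
  zigzag whose neighbour distance equals the internuclear reach) make the
  integrator chatter indefinitely with a residual that never settles.  The
  ramp turns these into ordinary equilibria displaced by less than the ramp
  width, far below the micrometre scales of all pattern criteria.  The
  `ForceLaw` evaluation API keeps the exact Heaviside (zero at and beyond
  the cut-off).

* **Newton polish.**  Runs that stop moving (largest displacement below
  0.01-0.02 um over 5000-20000 steps) or stay stiffness-pinned (step size
  persistently below the smooth scale) hand their quasi-stationary state to
  a root-finder (`hybr`, falling back to Levenberg-Marquardt) on the
  velocity field.  The root is accepted only if it meets the 1e-4 residual
  rule, stays inside the cell, and lies within 10 um of the flow state, so
  the flow — not the root-finder — selects the equilibrium.  This matters
  because the slow collective modes of a 15-nucleus chain otherwise need
  millions of explicit steps to satisfy the residual rule.

When boundary forces are orders of magnitude stronger than the
internuclear unit — as with the second filter's fixed pole law (amplitude
200 on a 25-um reach), whose equilibria sit on the steep pole ramp — the
explicit step size stays pinned at the stiff scale while the chain's soft
modes still evolve, and no polish can certify a mid-transient state.  Those
relaxations use a stiff path instead: LSODA (via `scipy`) on the same
compiled force kernel, integrated in growing time chunks (rtol = atol =
1e-5) until the 1e-4 residual rule is met, with out-of-rectangle trial
evaluations mapped back to the open interior where the boundary exclusion
restores.  Tightening the tolerances to 1e-6 changes no screening
outcome.

Runs that converge neither way are reported as non-convergent and count as
invalid patterns in the screens.

The x = 0 axis is invariant under the dynamics, so the "equally spaced on
the midline" initial condition carries a small alternating x-offset
(0.5 um by default) that seeds the zigzag mode; otherwise even unstable
single files would persist exactly.

## The screen

**Filter 1** asks whether a model class can produce the observed patterns
at all, in two reference geometries: narrow (2b = 50, N = 9; single file
expected) and wide (2b = 80, N = 15; double file expected), both 2l = 500.
Validity criteria on the equilibrium: K1 all centroids at least r from the
boundary; K2 all pairs at least 2r apart; K3 the correct SF/DF
classification; K4 axial spread above 2/3 of the cell length; K5 mean
nearest-neighbour distance above 30 um (wide) / 45 um (narrow).  A class
survives if *some* parameter combination yields a valid pattern in each
geometry (not necessarily the same one), which makes the survivor set
monotone under grid refinement.

Two implementation details:

* The default ("reduced") grid uses cut-offs {25, 50, inf} um and three
  log-spaced amplitudes in [0.1, 10] for the side and pole forces, with the
  pole law fixed to repulsive-falling (its amplitude and reach still vary);
  both initial-condition modes and fixed per-run seeds.  The full published
  grid (four cut-offs, five amplitudes, 216 models; 1,382,400 runs) is
  available via `reduced=False`.

* A valid equilibrium is discarded as *inherited* when the initial
  condition already satisfied all criteria and no nucleus moved more than
  2 um: models whose forces are entirely out of range at the starting
  spacing freeze whatever arrangement they are given, and a frozen lattice
  or a lucky random draw is not a pattern the model formed.

**Filter 2** takes the survivors to 14 cells of representative width
(42-117 um, halved to b) and nucleus count (7-23), with the pole law fixed
to strong short-range repulsion (sigma_P=1, alpha_P=-1, c_P=25, M_P=200).
K3 is dropped; K5 becomes the pooled criterion K5*: the mean
nearest-neighbour distance over all nuclei of all 14 cells must be
40 +- 5 um.  Each (c_N, c_S) pair is scored 0-4 (per-criterion pass
fractions over the 14 cells, K5* contributing 0 or 1, maximised over M_S).
A class is then rejected if

* *trend*: at its best-scoring parameters the average |x| vs cell width
  curve initially decreases (its value at the smallest width exceeds the
  curve minimum by more than 2 um), the signature of side forces that
  decentre thin cells; or
* *robustness*: perturbing the internuclear reach by +-25% around its
  best-scoring value drops the score by more than one full
  criterion-equivalent across the cells (paired initial conditions isolate
  the parameter effect) — the signature of classes that only work with the
  reach tuned to the internuclear spacing.  A single marginal cell-criterion
  flip does not count as a defect.

**Calibration** fixes a surviving class's laws with infinite reach and
grids the side and pole amplitudes (13 log-spaced values in [0.1, 10]
each).  Every cell is relaxed *from its measured configuration*; the error
is the mean Euclidean deviation of the equilibrium from the measurement;
grid points with any non-convergent cell are excluded rather than silently
skipped, and the full error surface is returned.

## Strip-model analytics

Viewing the cell as an infinite strip with evenly spaced nuclei
(`lambda = 2l/(N+1)`) in a zigzag reduces the dynamics to one scalar offset
x with `dx/dt = 4 f(d(x)) x/d(x) + g_S(b+x) - g_S(b-x)`,
`d(x) = sqrt(4x^2 + lambda^2)`.  The single file x = 0 is stable iff
`2 f(lambda)/lambda < -g_S'(b)`.  All closed forms (the general inequality
`b^(1-aS) lambda^(aN-1) < -sS aS MS d_ref^(aN-aS)/2`, the Model-1 critical
spacing `lambda* = d_ref sqrt(2/M_S)`, the Model-2 critical ratio
`r* = sqrt(M_S/2)`, and the fork offsets
`x_bar = sqrt(lambda*^2 - lambda^2)/2` (M1) and
`x_bar = sqrt((b^2 - (r* lambda)^2)/(2 M_S + 1))` (M2)) are re-derived from
this stability condition rather than transcribed, and the tests verify
them against finite-difference slopes and numerical root-finding on the
strip ODE; cut-offs are ignored here (infinite reach, as in the
calibration laws).

The same reduction yields the nuclear-shape model: compressive forces
f_x (sides plus the lateral neighbour push) and f_y (axial neighbours;
optionally the second axial neighbours — the "long-range" variant) deform
an area-preserving elliptical nucleus of stiffness kappa into the oriented
aspect ratio `N_AR = (kappa - f_y)^2 / (kappa - f_x)^2`, defined > 1 for
elongation along the cell axis and < 1 across it (reciprocal branch when
the fitted ellipse's major axis lies within pi/4 of the x-axis).  kappa is
fitted by minimising the mean absolute aspect-ratio error on a coarse grid
refined by bounded scalar minimisation.

When the full 2D dynamics are compared against the strip prediction (the
pitchfork test), the simulation is set up under the strip model's own
assumptions: an internuclear reach covering the immediate zigzag
neighbours but not the second axial neighbours, weak distant poles, and
the prediction evaluated at the realized axial spacing of the interior
nuclei.

## Pattern statistics

* SF/DF classification: 7 equal bins of x/b over [-1, 1]; SF if the single
  highest bin holds >= 60% of nuclei; DF if the two highest bins are
  non-adjacent (one broad file must not count as two), jointly hold
  >= 60%, and differ by less than 50% (`|n1-n2|/max < 0.5`, the scale-free
  reading).
* Nearest-neighbour distances, with a Monte-Carlo baseline of x, y
  i.i.d. uniform in the rectangle (default 1000 realizations, 10-um bins
  over [0, 150]).
* Zigzag correlations: nuclei within 10% of the cell height of either pole
  are discarded; y-positions are rescaled so the mean spacing *within a
  file* is 1 — for DF cells a single scale (the mean of the two per-row
  factors `(n_r - 1)/range_r`) is applied to both rows so their relative
  alignment survives — shifted so the middle-most nucleus sits at 0,
  pooled, and histogrammed with bin 0.25.  A perfect zigzag puts the
  row-vs-other-row-midpoint cross-correlation mass on integers, perfectly
  paired rows on half-integers; whole-cell normalisation would blur this
  distinction, which is why the within-row scale is used.
* Pooled positional histograms of x/b and y/l (default 10 bins).

## Synthetic data

Cell geometries are drawn from truncated normals (at +-3 SD and
positivity) matching the measured morphometrics: length 499.2 +- 57.7 um
(VL3) / 491.8 +- 57.1 um (VL4), width 80.4 +- 17.5 um / 51.7 +- 11.3 um,
nucleus counts 15.3 +- 2.9 / 9.3 +- 1.6 (rounded, floored at 2), nuclear
radius 7 um.  Counts are independent of width by default; an optional
linear count-width coupling exists because counts correlate with cell area
in the real data.  Nuclear positions are either i.i.d. uniform (the null
model) or model equilibria from random starts plus Gaussian jitter
(default SD 2 um, clipped to the rectangle).  Ellipse tables invert the
shape model at a given kappa with multiplicative lognormal noise, fixed
area pi (7 um)^2, and orientation consistent with the oriented-aspect-ratio
branch.

Synthetic cells are exactly rectangular and noise-free apart from the
placement jitter; they carry none of the segmentation error, boundary
curvature, or count-width confounding of real microscopy data.  Passing
tests therefore demonstrate the *internal* soundness of the pipeline
(parameter recovery, pattern statistics, screen discrimination) — not that
the calibrated amplitudes of real muscles are reproduced, which would
require the imaging data.

## Problem sizes and defaults

The reduced Filter-1 screen runs ~26k relaxations (grid above, early exit
per geometry once a class is satisfied) in a few minutes on one CPU;
Filter 2 sweeps 3 cut-off values per law and 5 amplitudes over the 14
cells (~8k stiff relaxations); calibration/recovery tests use 30 synthetic
cells on the full 13 x 13 amplitude grid.  Budgets (20k adaptive explicit
steps per Filter-1 relaxation, model-time cap 1e6 everywhere) mark the
rare grinding run non-convergent, which the screens count as an invalid
pattern.  All stochastic stages take explicit seeds; screen runs derive
per-run seeds from (seed, class, combo, geometry), so reruns are
bit-identical.

## Known limitations

* The dynamics are 2D; real fibres are three-dimensional with peripheral
  nuclei.
* Equilibria reached through the smoothed cut-offs can differ from the
  hard-Heaviside idealisation by up to the ramp width near a cut-off
  surface.
* The screens' reduced grids are existence tests: enlarging the grid can
  only add survivor classes, and the reduced grid was chosen to contain
  the parameter regions the survivor classes need (a reach near 50 um for
  constant/growing internuclear repulsion, near 25 um for short-range side
  centring).
* Transient dynamics (trajectories, timing of file formation) are outside
  the model's validated scope; only equilibria are compared.
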