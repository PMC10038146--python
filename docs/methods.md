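# Methods

`coralflow` models the feeding structures of gorgonian soft corals (sea
fans) as infinite planar arrays of finite-height circular cylinders at three
nested scales — colony branches, polyp tentacles, and tentacle pinnules —
and asks two questions: how much of the oncoming water passes *between* the
structures rather than around them (the leakiness `Le`), and how that
leakiness shapes the capture of plankton swimming with Brownian-like motion.

## Model geometry

One cylinder of diameter `D` and height `H` sits in a periodic unit cell of
width `W = D + G`, where `G` is the surface-to-surface gap to its
neighbours.  Periodic side faces make the cell a motif of an infinite row
normal to the flow.  The scale levels are (all solved in cm internally):

| level    | D        | H       | domain (length x height) | inlet offset | G/D studied |
|----------|----------|---------|--------------------------|--------------|-------------|
| branch   | 0.1 cm   | 1 cm    | 10 x 4 cm                | 2 cm         | 0.5 - 8     |
| tentacle | 0.025 cm | 0.25 cm | 2.5 x 1 cm               | 0.5 cm       | 1.5 - 3     |
| pinnule  | 0.025 mm | 0.25 mm | 2.5 x 1 mm               | 0.5 mm       | 1.25 - 2.5  |

The cylinder is centred across the cell width and vertically in the domain.
Seawater is `rho = 1.025 g cm^-3`, `mu = 0.0108 P`.  Integer Reynolds
labels use the rounded kinematic viscosity `nu_nominal = 0.01 cm^2 s^-1`
(`Re = U D / nu_nominal`, so `Re = 2` at `U = 0.2 cm s^-1` for a branch);
the solver always uses the true viscosity.

An idealized feeding polyp decorates the branch cylinder for the decorated
runs: four polyps per face on the two faces normal to the flow, each a short
stalk (diameter 0.03 cm) carrying eight solid tentacle capsules (length
0.1 cm, diameter 0.0125 cm) splayed 45 degrees from the oral axis, the whole
polyp standing 0.09 cm proud of the cylinder surface.  Stalk and tentacle
thicknesses, the splay angle and the even vertical spacing (polyp centres at
H/8, 3H/8, 5H/8, 7H/8) are modelling choices — the literature gives only the
tentacle length, the total height and "evenly positioned" — and are exposed
as a tunable `PolypModel`, not constants.

## Flow solver

The steady incompressible Navier–Stokes equations are discretized with a
staggered (MAC) finite-volume scheme on a stretched rectilinear grid:
uniform spacing in the periodic `x` direction, geometrically graded spacing
(growth ratio 1.3, capped at 24x the fine spacing) in the streamwise `y` and
axial `z` directions away from a refined window around the obstacle.  The
fine spacing is `D/8` by default (`n_per_diameter`), additionally capped at
`G/5` in `x` so narrow gaps keep at least five cells across the jet.
Boundary conditions: uniform inflow, zero-pressure outlet (ghost-mirrored
pressure with an extrapolated outflow velocity), periodic sides, free-slip
(symmetry) top and bottom, and stair-step no-slip obstacles masked with the
analytic signed-distance query (`mask_inflate` dilates the mask for solids
thinner than the local grid, used for polyp tentacles).

Steady states are reached by artificial-compressibility pseudo-time
marching: velocities advance explicitly, then pressure relaxes
`dp/dtau = -rho * beta * div(u)`.  Updating pressure from the *new*
velocities makes the acoustic subsystem symplectic-Euler, which is neutrally
stable, so no artificial damping is needed.  Each face uses a local
pseudo-time step from the combined convective/acoustic/viscous stability
bound; `beta` is set to `max((2.5 U)^2, (3 nu / h)^2)` so pressure waves
outrun both the flow and the diffusive signal.  Convection is second-order
central differencing with the advective von-Neumann bound `dt <= 2 nu/|u|^2`
folded into the local step; the four cell rows before the outlet fall back
to first-order upwind to suppress open-boundary reflections, and a
first-order hybrid scheme is available as a robust fallback (it is also used
for the half-resolution initialization stage).  Two accelerations keep
desk-scale solves in the tens of seconds: cells whose obstacle set is
mirror-symmetric about mid-height (all plain and polyp-decorated cells) are
solved on the bottom half with the symmetry plane at mid-height and mirrored
on export, and every solve starts from a converged half-resolution solution
interpolated onto the fine grid.

Convergence is declared when the momentum residual
`||du/dtau||_rms * D / (U^2 + nu U / D)` — normalized by the dominant force
scale so Stokes-regime cases are judged fairly — falls below `tolerance`
(default 1e-3) with the size-scaled cell divergence below `div_tolerance`
(default 3e-4 relative to `U`).  On the default grids the residual stalls at
(1.5–2.5)e-4 (the stair-step noise floor), and measured leakiness drifts by
less than 0.005 once the residual is below ~5e-3, which is what the default
tolerance is calibrated to; both tolerances can be tightened through
`SolverSettings`.  A stalled-but-bounded residual within
`plateau_factor * tolerance` is accepted as a quasi-steady state with a
warning — this is the normal exit for the fastest flows (nominal `Re = 128`),
where the wake oscillates in a mild limit cycle and no discrete steady state
exists.

Time-resolved solves use dual time stepping: backward-Euler physical time
(default horizon eight domain flow-through times in 120 steps), each step
relaxed by the same pseudo-time iteration.  Starting from uniform inflow,
the final frame is compared against the steady solve; agreement within 1%
is itself one of the scientific claims checked by the test suite.

## Leakiness metrics

Two metric variants, both normalized by the inlet speed `U`:

* **gap flux** `Le = Q/(U A)`: the streamwise velocity integrated (midpoint
  quadrature, 96x96) over the rectangular window between neighbouring
  cylinder surfaces (width `G`, height `H`) in the cross-flow plane at the
  cylinder's streamwise position, divided by `U G H`.  Moving the plane
  within the cylinder's streamwise extent (+-D/2) changes `Le` by under ~6%
  (tested); a full diameter away the window no longer has a solid flank and
  reads up to ~15% lower, which is why the metric is pinned to the
  cylinder's centre plane.  `Le > 1` occurs when flow accelerates through
  the reduced cross-section.
* **line average**: the mean streamwise velocity along the lateral line from
  the cylinder axis to the periodic cell edge at a chosen height, divided by
  `U`.  Samples inside the solid contribute zero velocity but stay in the
  averaging length (the cylinder radius is 1/3 of the half-width line), which
  is why this metric reads systematically lower than the gap-flux metric.
  Both a fluid-only average and a surface-to-edge variant are available
  behind switches.  A streamwise (wake-line) reading of the same prose
  definition was evaluated and rejected: it produces leakiness *decreasing*
  with Reynolds number, the wrong physics.

Polyp-decorated cylinders are measured with the line metric — "between
polyps" at cylinder mid-height, "over the polyp" at the height of the second
polyp from the top — because the polyps sit on the upstream/downstream faces
and the centre-plane gap window passes between them without registering them
at all.  (The gap-flux routine does refuse, with a geometry error, any
window that a solid actually intrudes into.)

## Agent-based capture

Plankton are point agents advected by the solved flow field (tiled
periodically in `x` to ~3.6 cm) with unbiased Brownian motion representing
active swimming, integrated by Euler–Maruyama with per-axis displacement
variance rate `2.5e-3 cm^2 s^-1` — interpreted as variance accumulated per
unit time (increment s.d. `sqrt(v dt)`); a diffusivity convention
(`Var = 2 d t`) is switchable since the same number doubles as the plankton's
effective diffusivity.  1000 agents per replicate are released uniformly in
a sheet `x in [0.4, 3.2], y = 1.0, z in [0.6, 3.4]` cm, 1 cm upstream of the
cylinder row.  An agent is captured the moment its straight step segment
touches a cylinder surface — an analytic segment-versus-finite-cylinder test
(side and caps), not an endpoint test; the generic obstacle API uses the
convexity of each solid's signed distance along a segment (ternary search
plus bisection), so grazing contacts within tolerance are detected.

Boundary rules (not stated in the source study; recorded as configuration):
periodic in `x`; reflection at the inlet plane and at the free-slip
top/bottom faces; agents crossing the outlet are exited.  Defaults
`dt = 0.01 s` (per-step displacement is well under `D/2` at all simulated
speeds; a warning fires otherwise, and halving `dt` moves mean capture by
less than one replicate SD — tested) and `max_time = 3 L/U`, after which
surviving agents count as not captured.  As an exact optimization, agents
more than 1 cm downstream of the cylinders are retired early when the
advective Peclet number over that margin exceeds 50 (return probability
`~exp(-U margin/d) < 1e-30`); the optimization disables itself in
slow-drift regimes.  A single experiment seed deterministically spawns
per-replicate child generators, so results reproduce exactly at fixed dt
and field.

The paper-conditions experiment is 100 replicates; the shipped test suite
and acceptance script use 10 replicates (and 6 for auxiliary robustness
checks) to fit interactive runtimes — the argmax structure over G/D is
stable well within the replicate scatter at 10 replicates.

## Dimensionless reporting

`Re` is reported in both conventions (true viscosity and nominal), `Pe =
L U / d` per substance with `d_plankton = 2.5e-3`, `d_O2 = 1.97e-5`,
`d_CO2 = 1.60e-5 cm^2 s^-1`, and the porous-sheet coefficient as
`Lambda = Le F / U` with the force per area `F` supplied by the caller (the
solver's surface-stress drag can provide it).  Characteristic lengths and
speeds per structural level are inputs, not constants, since they vary by
colony and flow environment.

## Synthetic fixtures

Analytic, exactly divergence-free velocity fields (uniform stream, linear
shear, plane-channel parabola, extruded potential flow past a cylinder)
serve as oracles for the metrics, interpolation and transport: uniform
fields must give `Le = 1` exactly, the channel's line average is `(2/3) u0`
in closed form, trilinear interpolation is exact on linear fields, and
potential flow has exactly zero normal velocity on the cylinder surface.
The morphometric generator draws gap/diameter/height records uniformly from
the measured ranges of real gorgonians (branch `G/D` 1.3–4, `H/D` 4.5–30;
tentacle `G/D` 1.75–3; pinnule `G/D` 1.25–2.5); the uniform choice is a
synthetic stand-in for unpublished raw tables, not an inference about their
distribution.  What fixtures do *not* emulate: solver-produced boundary
layers, wake structure, or any correlation structure in real morphometric
data — tests against fixtures validate the metrics and transport machinery,
not the flow physics, which is validated by the solver's own convergence
and symmetry properties and by comparison against the study's reported
values.

## Numerical choices and known limitations

* Stair-step masking is first-order at the surface: the effective cylinder
  boundary sits within half a cell of the true surface.  Grid refinement
  from `D/8` to `D/12` at matched (deep) residual moves leakiness and
  surface-stress drag by ~3% each; the routinely tested `D/8`-vs-`D/10`
  pair at default settings agrees within 1% (the convergence properties
  bound Le at 5% and drag at 10%).
* At the default residual stopping point the artificial-compressibility
  field carries a small distributed divergence: streamwise section fluxes
  balance the inlet flux to within a few percent (worst ~7% for the slowest
  branch flows), tightening to ~1% at `tolerance = 3e-4`.  Leakiness values
  move by less than ~0.016 between those stopping points.
* The solver reproduces the study's leakiness transition at low and
  moderate Reynolds number (line-average 0.33–0.34 at `Re = 2`, 0.67 vs
  0.72 at `Re = 10`; gap-flux 0.36 vs ~0.3 at `Re = 1`, 0.91 vs >0.9 at
  `Re = 8`, all G/D = 2).  At strongly blocked or inertial configurations it
  predicts a *flatter* transition than the reference finite-element values:
  line-average 0.75–0.77 vs 0.97 at `Re = 128`; gap-flux 0.35–0.38 vs 0.55
  at `G/D = 0.5, Re ~ 9`; pinnule gap-flux up to 0.28 at `G/D = 2.5` vs a
  reported 10–20% band.  These differences are resolution-converged in our
  scheme.  Our fields satisfy continuity with a mid-height gap jet of
  ~1.2 U and a vertical bypass of ~1.05 U at `Re = 128`; the reference value
  0.97 implies a ~1.45 U jet, i.e. almost no vertical redistribution around
  the finite cylinder within 2 cm of a uniform inlet.  Which behaviour is
  closer to truth is left open; the downstream consequence is that the
  capture optimum at `Re = 8` lands at `G/D = 0.5` here rather than the
  reported `G/D = 1` (the `Re = 1` optimum at `G/D = 1.75` and the decline
  beyond `G/D = 3` reproduce exactly).
* The quasi-steady plateau exit means the reported residual, not the
  requested tolerance, is the convergence statement for the fastest flows;
  both are recorded in `FlowField.convergence`.
* Agents are point particles: no finite-size hydrodynamics, no behavioural
  taxis, and contact equals capture — no capture kinetics.
* Flexible structures, whole-colony porous-sheet modelling, and scanned
  colony meshes are out of scope.
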