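# Methods

`cryptmech` simulates a two-dimensional cross-section of a colonic crypt as
an off-lattice cell-centre model. This note records the model, its numerical
treatment, the package's own calibration choices, and what the synthetic
scenarios do and do not capture about real tissue.

## Model

**Cells and connectivity.** Every cell is a point (its centre) on a strip
that is periodic in x and unbounded in y. Connectivity is the Delaunay
triangulation of the periodically replicated point set, folded back onto the
canonical strip; cell shapes and areas are the dual Voronoi polygons. Edges
longer than an interaction cutoff (1.5 cell widths) carry no force and do
not count as contacts: this is the standard convention for cell-centre
models and prevents spurious long-range edges across the lumen. Lengths are
measured in cell widths, time in hours.

**Springs.** Neighbouring cells interact through linear springs along
Delaunay edges,

    F_i = sum_j mu_ij (|r_ij| - s_ij) rhat_ij,

with spring strength mu = 15 for every pairing by default (the
epithelial-epithelial strength can be raised independently to study the
E-E/S-S stiffness ratio) and mature rest length s = 1. Overdamped dynamics
eta dr_i/dt = F_i are integrated by forward Euler with eta = 1 and
dt = 0.0042 h.

**Basement membrane.** The membrane is the piecewise-linear curve through
the midpoints of every epithelial-stromal spring, traversed along the
epithelial layer with the stroma kept on the same side. At each midpoint the
signed discrete curvature kappa is evaluated from the parametric formula
kappa = (x'y'' - y'x'') / (x'^2 + y'^2)^(3/2), with derivatives taken by
central differences with respect to cumulative chord length; unequal chords
use the non-uniform three-point stencil, which is second-order accurate on
smooth curves (validated against circles of radius 1, 2 and 5). Each
epithelial cell i then receives, for each stromal neighbour j, a force

    F_ij = beta (kappa_ij - kappa_0(r_i)) uhat_ji,

along the stromal-to-epithelial direction. The sign convention is fixed by
two behaviours rather than by notation: a perturbed flat layer with
kappa_0 = 0 must relax back to flat, and a region with kappa_0 = kappa_c > 0
must bulge into the stroma with radius ~ 1/kappa_c. Both are covered by
tests. With the traversal convention above this means kappa > 0 where the
curve bows into the stroma (a crypt-base valley) and kappa < 0 where it bows
into the lumen (the collar shoulders).

**Spontaneous curvature field.** kappa_0 is kappa_c inside a designated
base region and zero elsewhere. In the flat scenarios the region is a
central x-band (half the domain width in the basic block; 20% of the width
in the flat-to-crypt deformation). In the crypt scenario it is the lowest
f_base fraction of the crypt height, where the height is recomputed every
step from the epithelial extent, so the region follows the tissue as it
deforms.

**Cell cycle.** Proliferative epithelial cells cycle through G1/S/G2/M with
G1 ~ Uniform(1, 3) h and fixed S = 5, G2 = 4, M = 1 h, so every total
duration lies in [11, 13] h. (The flat scenarios use the same phased model;
its total is exactly Uniform(11, 13).) With density-dependent inhibition
enabled, a cell whose Voronoi area is below the division threshold A_div
holds at the G1/S boundary — age frozen, phase G1 — until its area
recovers. At the end of M the parent is replaced by two daughters at
+/- epsilon along the division axis: the direction of the vector joining the
parent's two nearest epithelial neighbours (planar cell polarity). A parent
with fewer than two epithelial neighbours divides along a uniformly random
axis and the event is flagged in the log. The daughters' connecting spring
starts at rest length s0 = 0.3 and matures linearly to 1 over one hour.
The daughter separation (2 epsilon = 0.3, a standard choice in cell-centre
frameworks) matters:
with near-coincident daughters the newborn pair is geometrically unstable
and one daughter is almost always extruded and lost to anoikis within
minutes, which starves the tissue of net cell production.
Stromal cells are terminally differentiated and never cycle.

**Wnt gating (crypt only).** A linear Wnt field decays from 1 at the lowest
epithelial cell to 0 at the highest; cells at Wnt >= threshold are
proliferative, the rest are terminally differentiated. The flat scenarios
give every epithelial cell unlimited proliferative capacity instead.

**Death.** Two channels. *Anoikis*: an epithelial cell whose triangulation
neighbours (within the cutoff) include no stromal cell has detached from
the basement membrane and is removed immediately. *Sloughing*: inside a
prescribed region (top 10% of the crypt height; the outer quarters of the
width per side in the flat scenarios) each epithelial cell dies with
per-step probability p dt, a per-hour hazard of p. Removal is instantaneous
in both channels.

## Scenarios

* `rectangular` — 20 columns x 10 rows (200 cells) of hexagonally packed
  cells at unit spacing; the top row is epithelial, the bottom row pinned
  (the musculature beneath the mucosa), vertical walls periodic. The central
  half of the width carries kappa_c. Hexagonal packing (row pitch sqrt(3)/2,
  alternate rows offset half a width) is used because it is the mechanical
  equilibrium of the unit-rest-length spring network: the block is
  force-balanced at t = 0 and the equilibrium Voronoi area is
  A_eq = sqrt(3)/2.
* `deformation` — a wider (30 x 14) variant whose central band covers 20%
  of the width, deep enough for a full test-tube invagination to form.
* `crypt` — an epithelial chain at unit spacing tracing collar -> wall ->
  semicircular base -> wall -> collar, embedded in a hexagonally packed
  stromal block clipped away from the lumen, bottom row pinned. The chain is
  created in traversal order and the simulator maintains that order through
  divisions and deaths, which gives a stable membrane traversal without
  re-deriving the chain from geometry each step.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| mu | spring strength (all pairings) | 15 | eta cell-width / h |
| eta | drag coefficient | 1 | — |
| s | mature spring rest length | 1 | cell width |
| dt | timestep | 0.0042 | h |
| beta | membrane force strength | 10 (flat), 5 (crypt) | — |
| kappa_c | base spontaneous curvature | 0.4 | 1/cell-width |
| f_base | crypt-base fraction of height | 0.2 | — |
| A_div | division-area threshold | 0.7 A_eq (crypt), 0.8 A_eq (flat) | cell-width^2 |
| Wnt threshold | proliferative gate | 0.5 | — |
| p | sloughing hazard | 0.05 (crypt), 0.1 (flat) | 1/h |
| epsilon | daughter offset | 0.15 | cell width |
| s0 | newborn spring rest length | 0.3 | cell width |

mu, eta, s and dt are the baseline literature values. beta, kappa_c, A_div,
the Wnt threshold and p are not printed in the source material; the values
above are the package's calibration, chosen once so that (i) a flat layer
with kappa_0 = 0 stays flat at the default beta, (ii) the crypt keeps its
test-tube shape with the smallest effective beta (a larger beta flattens the
collar corners and squashes the crypt), and (iii) crypt turnover balances —
division at the Wnt-positive base matches anoikis plus collar sloughing —
with the hourly epithelial count fluctuating in the printed 50-60 band.
All are configurable.

## Numerical choices

* **Periodic triangulation.** Points within a margin (2 cell widths) of the
  vertical walls are replicated at +/- width and the Delaunay edges folded
  back; edges are kept only when at least one endpoint is canonical, which
  removes convex-hull artifacts of the truncated image band. At tissue
  density this reproduces the fully replicated construction exactly (tested
  property); the full construction is available via `margin=None`.
* **Rebuild cadence.** Connectivity is rebuilt every 3 steps by default; any
  birth or death forces an immediate rebuild, and positions (which enter all
  force evaluations) are always current. A dedicated test checks that
  rebuilding every step instead leaves steady-state statistics within the
  spread of independent seeds. Forward Euler consistency is checked by
  halving dt.
* **Voronoi areas.** Interior areas are exact dual-polygon areas of the
  periodic point set. Cells on the open boundaries (the lumen surface, the
  region below the pinned row) have unbounded dual regions; these are closed
  by ghost points mirrored one cell width along the outward surface normal
  (epithelium) or one row pitch downward (pinned row). Boundary areas are
  therefore convention-dependent; interior areas are exact. Arrested cells
  re-check their area every 10 steps (~2.5 min of cell time) rather than
  every step — their area evolves on the timescale of whole-tissue
  rearrangement, orders of magnitude slower than dt.
* **Step order.** Within a step: triangulate; remove anoikis cells (this
  reflects the movement of the previous step) and sample sloughing; advance
  cell cycles (areas on demand); divide; evaluate forces; move. The order
  within a step is a convention — a sensitivity test swaps the
  death/division order and finds steady-state statistics unchanged within
  seed-to-seed spread.
* **Degenerate geometry.** Coincident consecutive membrane midpoints (two
  springs sharing a midpoint) are collapsed for the curvature evaluation and
  both springs inherit the shared curvature; a fully degenerate curve raises
  a zero-arc-length error. Curve endpoints (open curves only) contribute no
  membrane force.
* **Curvature spikes are not regularised.** Where midpoints crowd together
  — a cell being squeezed radially out of the layer — the three-point
  curvature estimate becomes very large and the membrane force ejects the
  cell from the layer within a step or two, after which anoikis removes it.
  This instantaneous extrusion is part of the model's behaviour: clamping
  the curvature, or capping per-step displacements, leaves half-extruded
  cells lingering inside the tissue and measurably flattens the basal death
  peak while inflating the total death count. An optional displacement cap
  (`IntegratorParams.max_step`, off by default) exists for experiments that
  need bounded moves; an ejected cell's logged removal position can
  otherwise lie far from the layer.
* **Determinism.** One master seed spawns independent substreams for cycle
  sampling, division-axis fallback and sloughing, and cells are processed in
  id order, so runs are bit-reproducible and toggling one stochastic feature
  does not shift the draws of the others. Initial cycle ages are staggered
  uniformly over each cell's cycle to avoid artificial division synchrony.

## What the scenarios do and do not capture

The scenarios are the model's own study conditions, not data: they emulate
the mechanical embedding of a crypt cross-section (periodic neighbours,
pinned musculature, deformable stroma) and the known turnover processes
(Wnt-restricted proliferation, contact inhibition, anoikis, collar
shedding). They do not include lateral cell rearrangement out of the
cross-sectional plane, active migration forces, subcellular signalling
dynamics, or measured murine geometry; passing tests therefore demonstrate
the internal consistency and the qualitative emergent behaviours of the
model (shape maintenance, homeostatic counts, basal death peak,
death-driven migration), not agreement with any particular animal.

## Known limitations

* The epithelial monolayer is a 1D chain in the crypt scenario: a cell
  cannot move around a neighbour, so perturbations propagate along the
  chain more strongly than in 3D tissue.
* Homeostasis is sensitive to the balance between the sloughing hazard and
  the proliferative-compartment size; far outside the calibrated defaults
  the crypt either involutes (death-dominated) or grows without bound.
* Absolute Voronoi areas of boundary cells depend on the ghost-closure
  convention; only interior areas (and area *changes* at the arrest gate)
  are convention-free.
* Event positions are binned against the snapshot chain nearest in time
  (flat scenarios), so arc-length coordinates carry up to one snapshot
  interval of staleness.

## Problem sizes used by the test suite and acceptance script

The crypt homeostasis run uses the default geometry for 300 cell hours
(100 h equilibration + 200 h observation). The flat-layer death
distributions average 10 replicates of 200 cell hours. Property tests use
smaller blocks (8-12 columns) and tens of cell hours, which is past the
~60 h relaxation time of the flat scenarios.
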