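# Methods

This note documents the models implemented in `wolftracks`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
inputs do and do not emulate.

## Movement model

A 2-day wolf travel path is a sequence of 24 steps at the 2-hour GPS fix
interval. Each step is in one of two states:

- **moving** with probability `p_move = 0.57` (the observed fraction of
  active 2-h steps in winter). States are independent Bernoulli draws by
  default: only the marginal activity fraction is known, and independence
  is the minimal model consistent with it. A first-order Markov state
  process is available (`state_transitions=(p_move|moving,
  p_move|not_moving)`) but off by default.
- **not moving** otherwise: bed- and kill-site steps. These are given a
  uniform displacement on [0, 150) m with uniform heading — effectively no
  net displacement, while keeping every path vertex well defined.

Moving steps draw a step length from a log-normal distribution truncated
to `[150 m, observed maximum]` and a turning angle from a wrapped normal
added to the previous *travel* bearing (the bearing of the last moving
step; a bed-site stop does not reset the direction of travel). The first
moving step of a path has no travel history and takes a uniform heading.

Month-specific defaults (natural-scale moving-step statistics from 2-h
winter telemetry):

| month    | step mean (m) | step SD (m) | turn mean (°) | turn SD (°) | truncation (m) |
|----------|---------------|-------------|---------------|-------------|----------------|
| December | 3,013         | 2,657       | −2.46         | 103.85      | 150–12,283     |
| January  | 2,118         | 2,159       | 2.56          | 108.17      | 150–∞          |
| February | 1,488         | 1,606       | 0.48          | 105.12      | 150–11,843     |
| Dec–Feb  | 1,928         | 2,074       | 0.10          | 105.12      | 150–∞          |

December and February bracket the range of winter movement rates and are
the two months used in scenario sweeps. Turning angles are degrees,
counter-clockwise positive, wrapped to (−180°, 180°]; the sign convention
is immaterial because the monthly means are near zero.

**Truncation calibration.** Truncating a log-normal that was
moment-matched to the table above at the observed maximum would drop the
December mean by ~6%. The sampler therefore solves for the `(meanlog,
sdlog)` whose *truncated* distribution has exactly the tabulated mean and
SD (closed-form truncated log-normal moments, hybrid root-finding started
from the untruncated method-of-moments solution). Simulated moving steps
then reproduce the monthly means to well under 1%, and stay inside the
observed support.

**Habitat bias.** At each moving step, `K = 20` candidate (length,
bearing) pairs are drawn; each is scored by the habitat-quality weight at
its endpoint, candidates leaving the territory (pack paths only) score 0,
and one candidate is selected with probability proportional to its score
(roulette selection). With `K = 1` or a constant surface the scheme
reduces exactly to an unbiased correlated random walk — a useful
degeneracy check. Candidate-endpoint scoring is the standard biased-CRW
construction; whether the bias should act on endpoints, whole steps or by
step rejection is an open design choice, and endpoint scoring was chosen
as the simplest scheme with that graceful degeneracy.

**Confinement.** If all candidates of a step fall outside the territory,
the reference bearing is reflected toward the territory centre and the
candidates redrawn, up to 10 times; a path that still cannot proceed is
discarded and resimulated from a fresh start (logged). Reflection
preserves the step-length marginal far better than rejecting whole paths.
Confinement necessarily shortens *net displacement*; in small territories
(182 km² at the densest packing, where the territory diameter is about
the length of a long step) it also measurably shortens selected step
lengths, because long candidates are the ones that exit. This is a real
property of any confined walk, not an artifact.

## Territory packing

Territory area follows the reciprocal-density (exclusive-area) rule
`A = 1000/d` km², which reproduces the observed 182 km² home range at 5.5
packs/1,000 km². (The alternative endpoint sometimes quoted for the lowest
density, 1,800 km² at 0.5 packs/1,000 km², would instead require
`A = 0.9 × 1000/d`; no single rule reproduces both, and the 182-consistent
rule was kept.) Centres sit on a hexagonal lattice — the densest regular
circle packing — with a uniformly random phase offset and rotation per
seed so that survey grids are never aligned with the packing. Lattice
spacing is solved by root-finding on the circular-lens area formula so
that an interior territory shares 8% of its area with its six neighbours
combined (per-pair lens = 8%/6 of the circle area; the six lenses are
disjoint at this spacing). Two consequences worth noting:

- the hexagonal cell area at this spacing is within 0.5% of the circle
  area, so realized pack counts track `density × 14.4` over the
  14,400 km² extent; because the number of lattice points inside the
  square still fluctuates with the lattice phase (whole rows slip in or
  out at the boundary), a handful of candidate phases are drawn per seed
  and the one with the count closest to the density target is kept,
  pinning realized counts to within one pack of the target;
- `measured_overlap` verifies the 8% constraint numerically on
  high-resolution polygon circles, and a pairwise-8% spacing solver
  (`spacing_for_pairwise_overlap`) is exposed separately for two-circle
  constructions.

Territories whose centre falls inside the extent are kept; their circles
may protrude beyond it (paths stay in-circle; survey grids cover only the
extent).

## Virtual surveys

Square grids of 36, 144, 400 and 576 km² cells tile the extent exactly
(400, 100, 36 and 25 cells). A survey samples `round(0.2 × n_cells)` cells
uniformly without replacement (round-half-even; the 36-cell grid thus
surveys 7 cells). A cell is occupied if any path intersects its closed
square, computed with exact segment–box predicates on an STR-tree — a
segment crossing a cell corner-to-corner occupies it even without an
interior vertex, and a path touching only a shared boundary occupies both
adjacent cells (an observer seeing tracks on a cell edge would call both
occupied; the convention is measure-zero for the stochastic results).
Detection is perfect by assumption; a per-cell detection-probability hook
exists but defaults to 1 and stays there in all standard analyses. Each scenario runs 10 replicate surveys, redrawing both the
surveyed cells and the per-territory path selection (a flag switches to a
fixed cell sample across replicates). Ten replicates suffice because the
running mean of occupancy stabilizes well within ten iterations
(`stabilization_check` reports the stabilization point).

## Scenario engine

Scenarios cross movement month (December/February), pack cohesion (1, 2 or
4 independent hunting units, drawn without replacement from the
territory's 1,000-path library), and lone wolves. Loners are
`round(f/(1−f) × n_packs × 7.8)` unconstrained walkers, so that they form
`f = 13%` of the *total* wolf population when packs average 7.8 wolves;
the pack-size conversion is exposed in the configuration because no
canonical value is prescribed. Loner paths are resimulated fresh each
replicate. The density sweep is 0.0–5.5 packs/1,000 km² in steps of 0.5
(12 values).

A master seed spawns named substreams (habitat surface, layout, library,
path selection, surveyed cells, loners) keyed by density and grid but —
deliberately — not by month, cohesion or loner flag. Contrasts are
therefore paired: December and February scenarios share territory layouts
and surveyed cells; cohesion levels share everything but the number of
paths drawn; a cumulative assembly mode makes the 1-unit draw a subset of
the 2-unit draw (and so on) for per-replicate monotonicity checks.

## Synthetic landscape inputs

The empirical inputs behind the original analysis (a fitted resource
selection function, the GIS layers, the raw GPS collar data) are not
available, so the package generates synthetic stand-ins with the same
*roles*:

- **Habitat surface.** Gaussian-smoothed white noise with a configurable
  correlation length, z-scored against the smoothing filter's exact output
  SD (impulse response on the same grid) and mapped through the normal CDF
  into (0.05, 1]. The CDF mapping keeps the marginal weight distribution
  stable across correlation lengths: realistic roughness spans nearly the
  full range while extreme smoothing degenerates to a near-constant
  surface, rather than having residual micro-noise stretched to full
  range, as a realized min–max rescale would. The 0.05 floor avoids
  zero-weight traps. The raster is padded by one maximum territory
  diameter beyond the extent, and out-of-raster lookups clamp to the edge,
  so unconstrained paths always score. Default correlation length: 5 km,
  the scale of boreal upland/peatland mosaics. Sensitivity is mild: the
  density-1 occupancy results shift by well under the replicate SD across
  correlation lengths from 1 km to fully flat, so conclusions do not hinge
  on the surface's roughness.
- **Linear features.** Near-straight roads/pipelines and meandering rivers
  spanning the extent, for path-crossing statistics.
- **Ground-truth telemetry.** Fix series generated by the movement model
  itself on a flat surface, used to validate the fitting pipeline by
  parameter recovery. Timestamps are exact multiples of the 2-h interval;
  fix failures and GPS measurement error are not modelled.

Because these stand-ins are synthetic, passing tests demonstrate internal
consistency of the framework (simulation → survey → curve) and correct
recovery of *generating* parameters — not that the surface or features
match any particular landscape.

## Telemetry statistics

Steps are straight-line displacements between consecutive fixes; a step is
a travel ("moving") step iff its length strictly exceeds 150 m (the strict
inequality matches the simulator's truncation support; 150 m exactly has
probability zero). Steps spanning a flagged gap (interval off nominal by
more than 10%) are excluded, and the step after a gap has an undefined
turning angle. Parameter fitting uses the sample mean/SD of moving-step
lengths, the moving fraction for `p_move`, and the circular mean/angular
deviation of turning angles *between successive travel moves* — the
direction change across a bed-site stop carries no information about
travel persistence and would otherwise inflate the angular deviation.
Monthly comparisons use Welch t-tests on moving-step lengths (moving steps
only; whether all steps should enter is unstated, and travel steps are the
quantity the simulator consumes). Home ranges are 100% minimum convex
polygons (convex hulls); the step-length/home-range association uses
Spearman rank correlation with average ranks for ties.

The path-validation harness mirrors the observed-vs-simulated comparison
design: two sets of 22 two-day paths from identical parameters, paired by
start location, compared by paired t-tests on total length, per-grid cells
intersected, and river and road/pipeline crossings. One caveat is
inherent: with 7 characteristics tested at the 5% level, the chance that
*every* test is non-significant in a single healthy run is only about
0.95⁷ ≈ 0.7, so individual significant results are expected under the
null at that rate; the per-characteristic rejection rate, not the
all-clear, is the calibrated quantity.

## Problem sizes

The default configuration matches the survey protocol: 1,000 paths per
territory per month, 10 survey replicates, 12 densities, four grids. The
test suite exercises the same code paths at reduced sizes chosen for
turnaround — libraries of 4–8 paths for sweep properties, 100–150 for
distributional checks, the full 1,000-path library for the density-1
cohesion analysis — and states expected Monte-Carlo tolerances
accordingly.

## Known limitations

- Territory geometry is idealized (equal circles, regular packing, static
  over the survey); real territories are irregular and dynamic.
- The two-state classification is a fixed 150 m threshold, not a
  behavioural state model; no prey interaction, den attraction or
  multi-day patrolling structure.
- Detection is perfect and uniform across cell sizes; variable
  detectability (forest cover, weather, flight-path length) is exposed as
  a hook but not modelled.
- Occupancy is summarized as a proportion; the package does not invert
  curves into abundance estimates with uncertainty, nor fit
  detection-explicit occupancy likelihoods.
- The cohesion contrast at 1 pack/1,000 km² is sensitive at the few-percent
  level to draw noise between seeds; comparisons between scenarios should
  use the paired substreams rather than independent runs.
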