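# Methods

## Movement model

Movers perform a discrete-time correlated random walk (CRW) in unbounded
continuous 2-D space. Each mover starts at its release position with an
initial heading drawn independently and uniformly on [0°, 360°); the first
step follows that heading. Every subsequent step adds a turn drawn from
Normal(0, σ²), where σ is the circular standard deviation (c.s.d.) of turn
angles in degrees, then wraps the result into (−180°, 180°]. At σ = 0 every
turn is exactly zero (straight rays). Draws are unwrapped-Gaussian rather
than wrapped-normal by construction; for σ ≤ 80° the circular s.d. of the
wrapped and unwrapped laws differ by far less than the Monte-Carlo noise of
any experiment here (the turn-angle sample c.s.d. matches its nominal value
to <1% at n = 10⁶, which the suite checks), so the distinction is
immaterial over the working range. Step length is fixed (default 1 unit;
1 unit ≈ 1 m in the field mapping). There are no walls, no wind or plume
physics, no variable step lengths and no interaction between movers.

Kinematic correctness is tested against the closed-form CRW mean squared
displacement E|R_n|² = n(1+ρ)/(1−ρ) − 2ρ(1−ρⁿ)/(1−ρ)², ρ = exp(−σ²/2)
(σ in radians).

## Traps and capture

Traps are closed, axis-aligned squares (default side 2 units). A mover is
captured the first time its step *segment* intersects any trap square
(Liang–Barsky slab test), not merely when a step endpoint lands inside —
endpoint-only testing lets a step clip a trap corner and tunnel through.
The mover is frozen at the entry point, credited to that trap at that step
index, and never moves again. If one segment crosses two traps the nearer
entry wins (physical first contact); with the grids used here (gap ≥ 13
units between traps, step 1) that tie cannot actually occur mid-walk. An
`endpoint` capture mode is retained as a sensitivity knob; it can only
catch fewer movers (asserted in the suite).

For lattice grids the engine finds the single candidate trap for a step by
rounding coordinates to the nearest lattice node — exact whenever
step length < spacing/2 − side/2, since any segment touching a trap then
has both endpoints rounding to that trap's node; the suite verifies the
fast path equals the all-pairs test, and the σ = 0 limit is verified
trap-by-trap against an independently coded ray-casting oracle on identical
headings.

## Randomness and reproducibility

Every public operation takes an integer seed. One run uses
`numpy.random.SeedSequence(seed)` feeding a single `default_rng` stream
that draws release positions (when sampled), then initial headings, then
one turn vector per step. Multi-run drivers (sweeps, calibration, fixture
generation) spawn child `SeedSequence`s from the master seed in a fixed
(condition, replicate) order and reduce each child to a sub-2³¹ integer
run seed. Identical seed + identical parameters ⇒ bit-identical results.

## Scenario geometry

Coordinates are Cartesian; for lattice grids the origin is the centre of
trap (row 0, col 0), rows increase along +y and columns along +x.

* **corner5x5** — 5×5 grid of 2×2-unit traps, 15-unit spacing. Point
  release on the main grid diagonal, 10 units outward from the corner
  trap's centre. The diagonal is the lattice's mirror axis, which makes
  the two edge traps at each index exchangeable — the property the decay
  analysis uses when averaging pairs (checked as a binomial-split test on
  simulated pairs).
* **center7x7** — 7×7 grid, 20-unit spacing. Point release 0.1 spacing
  (2 units) along +x from the central trap's centre, i.e. one step length
  outside its edge: as near the grid centre as a mover can legally start.
  The offset is configurable (`release_rule`, in units of spacing, up to
  0.5 = midway to the neighbouring trap). We chose the near-trap value
  because "released near the centre" most plausibly means next to the
  central trap, and because larger offsets depress capture of
  high-meander movers, flattening the saturation that defines this
  scenario's purpose; the offset's effect on the capture curve is the
  main sensitivity worth probing when adapting the layout.
* **lowdensity** — a single 2×2 trap at the centre of a 1000×600-unit
  rectangle; movers are seeded uniformly in the rectangle (rejecting the
  trap interior). The rectangle bounds only the starting positions, not
  the walk. One trap per 600,000 square units, a 2000-fold dilution of the
  7×7 grid's ≈1/300 (tight-box convention).

Target density is reported under two box conventions, because "area per
target" depends on where the habitat boundary is drawn: the lattice-cell
convention (centre bounding box grown by half a spacing per side; 400 for
the 7×7 grid) and the tight centre-to-centre box (≈294). Both are exposed.

## Edge profile and decay constant

For a corner release, only the corner trap (T1) and the two edges adjacent
to the release corner are informative about outbound flux; interior traps
mostly screen returning movers and are excluded. Index t ≥ 2 averages its
two mirror-image traps. The decay constant k is the OLS slope of
ln(mean catch) on trap index over bins with positive mean catch. Choices:

* **Log-linear, not nonlinear, by default.** It reproduces the standard
  "exponential trendline" slope, is exact on exact exponentials (asserted
  to 1e−12), and has a closed-form SE. A nonlinear least-squares mode
  (a·exp(k·t) on raw means) exists for sensitivity analysis.
* **Zero bins are dropped, never imputed** (ln 0 undefined; +0.5-style
  imputation biases k). At least 3 positive bins are required; otherwise
  an `UnfittableError` carries the profile for inspection.
* **The distance axis is trap index, not metres.** k is per trap
  interval, matching how the standard curve is calibrated, so the unit
  cancels on inversion. k is invariant to index shifts and to rescaling
  all catches (both asserted).

## Standard curve and inversion

The curve regresses all retained replicate k values (default: 10
replicates × each c.s.d. in {15, 20, …, 50}°, corner5x5 runs of 400
movers × 400 steps) on c.s.d., via OLS with intercept. Fitting replicate
points rather than per-c.s.d. means leaves the slope unchanged in balanced
designs but keeps replicate scatter in the coefficient covariance, so
prediction intervals are honest. Two r² values are exposed: the
replicate-level `r_squared` (≈0.8; it conflates linearity with Poisson-like
counting noise in the small T4/T5 catches) and `r_squared_means` (≥0.95;
linearity of the mean relationship, which is what "the relationship is
linear" means here). Replicates whose decay fit fails are dropped with a
warning; more than 20% failing aborts calibration.

Inversion: σ̂ = (k − b)/m. The standard error propagates, to first order,
(i) the measurement SEM of k through 1/m and (ii) the curve coefficient
covariance through the gradient (−1/m, −(k−b)/m²); the two components are
reported separately and combined in quadrature. Estimates outside the
simulated c.s.d. range are flagged `extrapolated` rather than refused.
Curves serialise to JSON (slope, intercept, covariance, every replicate k,
seed, walk sizes) so a calibration can be reused bit-for-bit.

## Capture sweeps and the optimum rule

A sweep runs n independent populations per c.s.d. and records total
captures. The "optimal" c.s.d. is the smallest tested value whose mean
capture is within one *pooled SEM* — the RMS of the per-point SEMs, a
single sweep-level noise scale — of the maximum mean. A sweep whose whole
max−min spread is inside that band returns "no optimum"; an optimum at the
largest tested value is flagged as a boundary solution. This rule reads a
saturating curve as "the earliest point on the plateau" while remaining
well-defined for interior peaks.

## Synthetic field fixtures

`generate_field_fixture` emulates a mark–release–recapture replicate:
`release_size` (default 800) movers through the corner5x5 scenario for 400
steps (the same run length as the calibration, so fixture and curve are
consistent by construction), optional per-trap binomial thinning with a
single recapture probability (default 1.0 — no field recapture rate is
available to set it from), release corners cycling through NW/NE/SW/SE with
counts flipped to match. What the generator does **not** emulate: lure
attractiveness and plume overlap, trap saturation, weather, mortality,
between-night behavioural variation, and any mover-to-mover heterogeneity
in meander. Passing recovery tests on these fixtures therefore shows the
*estimator chain* is unbiased under the model's own assumptions — it does
not validate the model against real moths. The steps-per-trapping-period
equivalence (400 cyber steps ↔ one field replicate) is an assumption
inherited from the calibration design, not a derived quantity.

Field tables are long-form CSV (`replicate_id, row, col, catch,
release_corner[, release_size, label]`), row 0 = northernmost row, col 0 =
westernmost column; analysis first maps the release corner to the canonical
NW position by axis flips (each its own inverse), and k is invariant under
relabelling a replicate's corner together with its grid (asserted for all
four corners). The c.s.d. histogram uses 5°-wide bins from 10° to 65°.

## Problem sizes used by the tests and the acceptance script

The acceptance script runs the full published sizes: the default curve
(80 runs of 400×400), the centre-release sweep (8 c.s.d. × 12 runs × 1000
movers × 2000 steps) and the low-density sweep (6 c.s.d. × 3 runs × 5000
movers × 3000 steps) — a few minutes on one CPU in total. The test suite
uses the same pipelines at reduced sizes chosen so each check still
resolves the effect it asserts (e.g. 200-mover saturation sweeps,
1000-mover low-density sweeps, a session-wide default curve built once).

## Known limitations and departures

* **Complete capture does not literally occur.** With exact 2×2-unit traps
  and segment-exact collision, a small diffusive tail of the population
  (~0.2–1%) leaves the 7×7 grid uncaptured within 2000 steps at every
  meander level; mean capture saturates near 99.5–99.8% and keeps creeping
  upward with c.s.d. rather than pinning at 100% from 50° as the original
  proprietary simulator reported. Consequently the measured saturation
  onset lands one to two 10° grid steps above the original report (and,
  because the plateau is flat to within its own SEM, jitters between 60°
  and 70° across master seeds). The direction
  of the discrepancy is consistent with the original software having a
  larger effective collision footprint (e.g. icon-sized movers/traps on a
  pixel display) — which would also pull the low-density optimum slightly
  upward — but its collision rule is not recoverable from the published
  description, and we do not inflate the stated geometry to compensate.
* **The low-density optimum is broad.** Catch differs only mildly between
  20° and 40° c.s.d. (a few tens of captures out of 5000), so the
  smallest-tied-with-max rule can land on 20° where the original analysis
  read "about 30°" off a flatter peak.
* The decay-constant distribution at a fixed c.s.d. is left-skewed (driven
  by ln of small T4/T5 counts), so per-replicate k values scatter more
  than the original report's "invisibly small" error bars suggest;
  averaging 10 replicates per c.s.d. in the curve absorbs this.
* Two-dimensional movement, constant step length, memoryless Gaussian
  turning and permanent traps are modelling assumptions inherited from the
  original design; none are relaxed here.
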