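# Methods

## Model

The simulator evolves two coupled fields on a 2D substrate: the cell
concentration C̃ and the secreted-EPS concentration S̃, both in units of
the mobility saturation depth σ. The assumptions are deliberately minimal:

- cells perform a random walk whose effective diffusion coefficient
  (mobility) depends only on the local EPS depth, M̃ = S̃/(1+S̃);
- a directional light source adds a constant drift β·M̃·C̃·b̂ — the drift is
  proportional to the same mobility, so cells on bare substrate neither
  diffuse nor drift;
- cells secrete EPS at a constant specific rate (∂S̃/∂t̃ gains a term C̃);
  EPS does not diffuse and, in the base model, does not degrade;
- optionally EPS decays with time constant τ̃ (∂S̃/∂t̃ loses S̃/τ̃), which
  caps the attainable EPS level at C̃τ̃ and makes motility contingent on
  group size rather than on waiting time;
- cell division is ignored: total cell mass is an invariant of every run,
  which is also the main numerical diagnostic.

All quantities are dimensionless; physical output uses λ = √(m₀/k_s),
T = 1/k_s and σ via `PhysicalScales`. The normalization constants are not
shipped with numeric values: the mapping T = 2000 s (so that 300 natural
time units correspond to one 600,000 s experiment) is provided as the
reference convention, but converting to physical units always requires a
user-supplied (m₀, k_s, σ).

## Discretization

Finite-volume on a square grid (default 360×720, dx = 0.25), forward Euler
in time (default dt = 0.01):

- Diffusive flux on cell faces with the face mobility taken as the
  arithmetic mean of the two adjacent mobilities.
- Advective flux β·M̃·C̃ by first-order upwind along the current bias
  direction. Upwinding adds numerical diffusion ~β·M̃·dx/2 along the bias
  axis only; a central-difference variant was compared during development
  and produced the same front speeds and instability growth to within a
  few percent, so the positivity-preserving upwind form is kept.
- Zero **total** flux through boundary faces. (A reflecting-ghost
  treatment is equivalent for the diffusive term but would leak mass
  through the outflow boundary for the advective term, breaking the
  fixed-total-mass property; setting the boundary face flux to zero is the
  discrete statement of the zero-flux condition.)
- Both rates are evaluated at the incoming state; S̃ updates use the old
  C̃. With no decay the S̃ update is exactly S̃ + dt·C̃, so uniform fields
  obey the closed form S̃(n·dt) = C̃·n·dt used in the tests.

`stability_limit` returns 0.5·min(dx²/4, dx/β) (saturated mobility M̃ = 1).
The reference dt = 0.01 sits between the raw diffusive limit (0.015625 at
dx = 0.25) and the safety-factored recommendation 0.0078125 = 1/128; sweeps
default to 1/128, which also divides the snapshot stride exactly. All
integration scheduling lives on the integer step lattice (t = n·dt), so
snapshot times, bias-switch times and early stopping are immune to
floating-point drift.

Negativity handling: undershoots no deeper than 1e−12 are clipped to zero
and accumulated into a mass-error account reported on the result; anything
deeper raises a stability error naming the recommended dt. With the upwind
scheme at the recommended dt the update is positivity-preserving, so the
clip path is exercised only by rounding.

The production integrator is a numba kernel that fuses the flux and update
loops; the numpy implementations of `cell_rate`/`eps_rate`/`step` are the
readable reference path, and a test pins the two to rtol 1e−13 over
hundreds of steps.

## Initial conditions

`make_deposition` fills the bottom 20% of the domain with i.i.d. draws of
mean C̄ (default law: uniform on [0, 2C̄]; pluggable). This emulates cells
spotted on agarose: spatially uncorrelated density noise at the grid scale.
It does not emulate features of real depositions such as the circular drop
boundary, density gradients from drying, or discreteness of individual
cells — so passing tests show that the *model dynamics* amplify small
density noise into fingers, not that any particular experimental noise
spectrum is reproduced. EPS starts at zero except in trail/merge fixtures
built with `make_eps_trail`.

Seeding: every run takes one integer seed; sweep replicate r of phase point
p uses `master + 8191·p + r`, and all seeds are recorded in the outputs.
Identical (config, seed) pairs reproduce bit-identical snapshot sequences.

## Morphological analysis

- **Adaptive threshold.** 0.1 × the mass-weighted 95th percentile of C̃
  (the concentration below which 95% of the cell mass sits), floored at
  1e−3·C̄. Weighting by mass pins the threshold to the dense motile groups;
  an unweighted pixel percentile is dominated by the vast low-level
  halo/trail region and traces a spurious diffusive skin instead of the
  cell front. The same threshold drives front tracing, segmentation, and
  the early-stop rule (a run ends when any column's front reaches row
  ny−2).
- **Front trace.** Per column, the largest row index above threshold;
  columns with no super-threshold pixel are flagged absent and excluded.
- **Instability metric.** Population standard deviation of the final front
  positions divided by the mean front advance since t = 0, over columns
  present in both traces; 0 for a flat advancing front, undefined (NaN,
  treated as non-motile) when nothing advanced. Evaluated at the final
  snapshot (or at early stop).
- **Classification.** Non-motile if less than 50% of the cell mass sits
  outside the deposition region at the end; otherwise uniform front vs
  fingering split at instability 0.01.
- **Segmentation.** 8-connected components above threshold, discarding
  components under 10 grid elements (threshold speckle); biomass is the
  integral of C̃ over the component, the trail depth is the mean S̃ over
  the 4 rows immediately behind the component's trailing edge.
- **Tracking.** Greedy one-to-one matching of groups to previous-snapshot
  tracks by decreasing pixel overlap (label-free). Unmatched groups start
  new tracks and record the overlapped track as parent (splits); a track
  whose mask is taken over — or that fades within a 3-cell dilation of an
  absorbing group — is closed with a merge event on the survivor.
- **Kinetics.** Speeds are central differences of the mass centroid over
  snapshot times. v_ss and N are means over the final quarter of a track;
  the ramp time is the earliest time the 5-snapshot moving-average speed
  reaches 0.9·v_ss, searched over the track's *ancestor lineage*: a finger
  that splits off an already-moving front inherits the parent's
  acceleration history, otherwise its ramp would be floored at its own
  birth time and the ramp-vs-C̄ scaling would flatten at high C̄. Tracks
  spanning fewer than 10 snapshots are excluded from scaling statistics.
- **Trail crossings.** An event fires the first time a track overlaps EPS
  above 0.05 lying in another track's accumulated footprint (not its own,
  and outside the deposition region); the crossing area is recorded so
  that substantive crossings can be told from single-pixel grazes.

## Phase diagrams and scaling

Default sweep grid: 240×720 at dx = 0.25 — full domain height at 2/3 the
reference width. Height is not negotiable for kinetics: on a half-height
proxy the front crosses the domain before finger kinetics reach steady
state and the fitted exponents are visibly biased (v_ss-vs-C̄ steepens from
≈0.34 to ≈0.44). Width only sets how many fingers fit (≈λ·10 spacing), so
trading width for runtime is cheap.

Default axes (log₂-spaced, calibrated on the reproduced phase diagram):

- bias sweep: C̄ ∈ 2^−12 … 2^−3 (19 half-powers, 3.3 decades) ×
  β ∈ 2^0 … 2^3 (10 values, one decade), 3 seeds each (570 runs).
  Inside the deposition strip EPS accumulates without bound, so the
  non-motile boundary scales as C̄ ∝ 1/β (displacement ≈ β·C̄·t²/2); the
  chosen range brackets non-motile, fingering, and uniform-front regions.
- decay sweep: C̄ ∈ 2^−8 … 2^−2.5 (12 values) × τ̃ ∈ 2^0 … 2^6.5
  (14 half-powers) at fixed β = 4 (504 runs). Short τ̃ at low C̄ starves
  the strip of EPS (non-motile); intermediate τ̃ produces staggered
  multiple fronts whose laggards follow and coalesce onto leading trails;
  large τ̃ recovers the decay-free morphology.
- scaling band: β = 4 with C̄ ∈ {2^−10, 2^−8, …, 2^0} (3 decades),
  2 seeds, dt = 1/128.

Scaling fits are ordinary least squares on (ln x, ln y) over phase points
classified as fingering, using replicate means over the *leading groups*
(tracks alive at the end whose advance is ≥80% of the leader's). Fits need
≥4 usable points; sparser relations are reported as omitted with a reason.

Reference regime parameters: fingering C̄ = 2^−4, β = 2^1.5 (7–12 groups on
the full grid, replicate speed/ramp spreads well under 5%/10%);
uniform front C̄ = 2; non-motile C̄ = 2^−12 at β = 1.

## Merge demonstration

Fingers form under an upward bias until t = 80, the bias is rotated 90°
(instantaneous, since experimental reorientation is fast compared with the
snapshot stride), and groups sweep across their neighbors' trails. Because
a crossing finger disperses *below* the segmentation threshold as it melts
onto the trail, pre/post kinematics are measured in a fixed-radius
(5 length units) observation window advected with the group:

- speed = mass-weighted mean cell speed Σ|J̃| / ΣC̃ (the continuum analog
  of averaging single-cell velocities);
- spread = radius of the mass-effective area (ΣC̃)²/(ΣC̃²)·dx² (inverse
  participation ratio), which grows when the same mass occupies more
  elements and is independent of any threshold.

The demo reports the first substantive crossing (area ≥ the 10-element
group floor); "no merge" is a valid, non-fatal outcome.

## Problem sizes in the shipped checks

The test suite runs the scaling sweep at its default size (12 runs,
240×720), three full-size (360×720) replicates for finger counting and
replicate consistency, four single runs spanning the phase classes, one
merge demonstration, and fast closed-form property checks; the whole suite
completes in roughly 11 minutes on one CPU. `scripts/acceptance.py` runs
only the three full-size replicates (~2 minutes).

## Known limitations

- Mean-field continuum: no cell discreteness, no run-and-tumble
  statistics, no pili-mediated cell–cell mechanics; stochasticity enters
  only through the initial condition.
- No cell growth; experiments spanning days violate this.
- First-order upwind advection smears the front over ~1 grid cell along
  the bias axis; front *positions* are threshold-based and insensitive,
  but sub-cell front structure is not resolved.
- The instability metric saturates well below 1 on domain-crossing runs
  because leading fingers leave the domain (early stop) before the
  laggards fully retreat; classification uses only the 0.01 cut, far from
  the saturated regime.
- Finger counts on narrow grids are depressed at high C̄ (wide fingers
  merge); quantitative count statements use the full-width grid.
- The 0.05 trail threshold and the 5-unit demo window are heuristic
  scales; both are module constants and easy to change.
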