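# Methods

## Aperture dose model

A beam's fluence grid has `n_rows` leaf pairs × `n_cols` bixels of width L;
leaf positions are continuous real numbers in bixel units on a 0-based
half-open grid (bixel c spans [c, c+1)), and the open field of a row is the
open interval (x, y) with 0 ≤ x ≤ y ≤ n_cols.  The dose influence matrix
(DIM) stores, per beam, the dose to every voxel per unit fluence through
each bixel, compressed-sparse-column over the row-major flat bixel index so
one leaf row is a contiguous column slice (the annealer's hot path).

Row dose is piecewise linear in (x, y): full bixels [ceil(x), floor(y))
contribute their DIM column; when x is non-integer, bixel ceil(x)−1
contributes fraction ceil(x)−x of its column, symmetrically y−floor(y) on
the right.  Two conventions close the gaps the piecewise definition leaves
open:

* **Sub-bixel openings** (ceil(x) > floor(y)): a single partial bixel with
  fraction y−x.  This preserves continuity in (x, y) and the identity
  "covered fractions + full bixels = y − x" exactly.
* **Closed rows** (x = y) are legal and contribute zero, so the annealer's
  moves can close a row without special-casing.

Integer leaf positions reduce *bitwise* to the plain column sum — the two
code paths share the slice-sum kernel, and the acceptance suite checks the
equality on random instances.  Dose is Lipschitz in each leaf position with
constant max_j D_ij / L, nondecreasing in y, nonincreasing in x, and plan
dose is linear in the weight vector (superposition over apertures).

## Objective

F = Σ_s (w_s/N_s) Σ_{i∈V_s} (d_i^calc − d_i)², weights summing to one
(validated to 1e-9).  Prescriptions are scalar per structure: 1 on the
target, 0 on organs at risk.  Voxels may belong to several structures and
are counted in each; unscored voxels contribute nothing.  The per-structure
terms sum exactly to the total and are reported as the cost decomposition.
Feasibility checking (weights ≥ 0, x ≤ y, leaves within the field) reports
all violations rather than raising, so optimizers can re-sample.

## Simulated annealing

Move width after k accepted moves: σ(k) = 1 + (L0 − 1)·exp(−log(k+1)/α_cool)
— σ(0) = L0, strictly decreasing, → 1.  Acceptance of a worsening move:
2·P0/(1 + exp(log(k+1)/β_cool)) — P0 at k = 0, strictly decreasing;
improving moves are always accepted.  Temperature never enters the
acceptance rule; it only drives the outer schedule: geometric cooling by
`cool_factor` per sweep, re-raising by `reheat_factor` (at most
`max_reheats` times) when T < T*, termination when T < T_min with reheats
spent.  An inner sweep ends after `k_succ_max` acceptances or `i_max`
iterations.

Design choices made where the schedule alone does not fix behavior:

* **Move scope.**  One proposal perturbs a single randomly chosen variable
  (the weight, or one leaf pair jointly) of a randomly chosen aperture.
  Perturbing a whole aperture (~13 variables) at once kills late-stage
  refinement — almost every joint draw worsens the plan; single-variable
  moves reached 2–3× lower cost at equal iteration count on the C-shape
  case.  The whole-aperture scope remains available (`move_scope`).
* **Weight-move units.**  Leaf moves use σ directly (bixel units).  Weights
  have no natural unit, so weight moves use σ · `weight_move_scale` · (mean
  plan weight), keeping refinement possible at any dose scale.
* **Feasibility by re-sampling.**  A draw violating α ≥ 0 or
  0 ≤ x ≤ y ≤ n_cols is re-drawn up to `retry_cap` (20) times, then the
  variable keeps its value; every state the solver holds is feasible.
* **k semantics.**  By default the schedule argument k resets each inner
  sweep; `k_succ_mode="cumulative"` accumulates it over the run, giving the
  schedules a single monotone trajectory (the sweep-stopping counter is
  always per-sweep).  The comparison protocol uses cumulative mode, which
  converges substantially further on the phantom cases.
* **Restart from best.**  On each reheat the walk is re-anchored at the
  remembered best state (`restart_from_best`, default on).  Without it the
  early high-acceptance phase drifts the walk irreversibly away from a good
  start: we measured runs of 2·10⁵ iterations that never dipped below their
  starting cost although 5% of single moves from that start were improving.
  Re-searching *around the best solution* is how this implementation reads
  the reheating step; the best-state memory makes the returned plan the
  best ever visited regardless.
* **In-loop normalization** (`normalize_in_loop`): optionally the cost is
  evaluated on the D95-normalized dose inside the loop, aligning the search
  objective with the reported, normalized comparison metric.  Off by
  default; on in the comparison protocol.
* **Width-schedule exponent.**  The decaying form above is the only reading
  consistent with a width that *decreases* from L0 toward 1; the exponent
  sign is configurable (`width_sign`) for sensitivity checks.

Defaults: L0 = 4 bixels, α_cool = 3, P0 = 0.3, β_cool = 3, k_succ_max =
100, i_max = 2000, T schedule (1.0, 0.1, 0.05) with cool 0.95, reheat 2.0,
max_reheats 3.  The comparison protocol (`run_case_comparison`) overrides
α_cool = 2, β_cool = 1 (fast decay toward greedy refinement), cumulative k,
6 reheats, in-loop normalization.  Full-run determinism under `seed` is a
tested contract.

## Two-step baseline

FMO minimizes the same objective over per-bixel intensities ≥ 0 — a
nonnegative least-squares problem, solved exactly by the active-set method
(scipy.optimize.nnls) on the structure-weighted stacked system.  Bixels
whose DIM column deposits < 2% of the beam's maximum column mass into
scored voxels are fixed to zero first: such grazing columns otherwise
attract intensities orders of magnitude above the clinical scale for
negligible dose, and the subsequent quantization step then destroys the
real fluence.  The KKT residual (max |gradient| on the support, max
negative gradient off it) is reported and must be < 1e-6.

Leaf sequencing quantizes each map to `n_levels` (default 10) uniform
levels and decomposes the integer map exactly by the unidirectional sweep:
unit level t opens, in each row, where the running sum of positive
gradients has reached t and the running sum of negative gradients has not.
The weighted segment indicators reproduce the quantized map *exactly*
(integer arithmetic), and the total beam-on time equals the classical
minimum max_rows Σ_c max(0, q_c − q_{c−1}).  Segment count and beam-on time
are reported; minimizing the *number* of segments (NP-hard) is out of
scope, as are interdigitation and tongue-and-groove constraints.

## Comparison protocol

`run_case_comparison` runs the baseline, then direct optimization with the
aperture budget matched to the baseline's per-beam segment counts.  By
default the annealer is warm-started from the sequenced apertures
themselves, so both methods optimize the *same aperture set* and the
annealer's contribution is continuous-leaf, continuous-weight refinement of
the decomposition — from cold starts at this problem scale the annealer
cannot discover the coordinated aperture splits needed to shield a central
organ, and the comparison would measure initialization rather than
refinement.  Both final doses are rescaled so 95% of the target volume
receives the prescription (the empirical 95%-from-top quantile mapped to
1); the whole dose vector is scaled by the single target-derived factor,
since a delivered plan has one global monitor-unit scaling.  Costs, DVHs,
D95 values and per-structure relative changes are computed on the
normalized doses.

## Synthetic cases

The generator emulates the shape of a real planning dataset — one 3-D voxel
grid, several beams with m×n bixel grids, one sparse nonnegative DIM per
beam, disjoint target/OAR voxel sets — with deliberately minimal physics:
parallel rays, exponential depth attenuation (μ = 0.05 per length unit),
and a Gaussian lateral penumbra (σ = 0.8) integrated over each bixel
opening.  Per column, the smallest entries whose combined mass is below
0.1% of the column total are dropped.  Everything is deterministic from
(preset, arguments, seed); a manifest records every parameter for exact
regeneration.

Presets: `c_shape` (C-shaped target wrapping a cylindrical core OAR — the
classical commissioning geometry), `prostate_like` (central target, two
flanking OARs), `two_oar` (spherical target, two lateral OARs).  Default
study conditions: 24–32³ voxel grids, five equally spaced coplanar beams,
6×10 bixels of width 2 length units, target weight 0.9 with 0.1 split over
OARs, prescription 1/0.  The experiments in the test suite and the
acceptance script run on the 24×24×12 C-shape case (6912 voxels, 420
target voxels), which keeps a full five-seed comparison under two minutes
on one CPU.

What passing tests do *not* show: the phantoms have uniform density, no
scatter, no heterogeneity corrections, and penumbra/attenuation constants
chosen for plausibility, not commissioning data; conclusions transfer to
the optimization machinery, not to clinical dose accuracy.  Cost-reduction
percentages measured here are desk-scale, case-specific quantities and are
expected to differ from any published clinical-dataset values.

## Numerical notes

* D95 quantile: sort-based, ties broken toward greater coverage; the
  scaling factor is minimal by construction and coverage ≥ 95% exactly.
* DVH: 1000 uniform bins spanning [0, max dose] plus a sentinel edge just
  beyond the maximum, pinning the curve to 0; cumulative-from-above.
* Partial-overlap fractions are exact interval arithmetic; a fraction can
  round to 1.0 when a leaf sits within one ulp of a bixel boundary.
* The annealer evaluates cost on the union of scored voxels only, through
  per-row prefix sums of the densified DIM (two vector subtractions plus at
  most two scaled columns per row, independent of opening width); a parity
  test pins it to the reference sparse path at 1e-12.
* Empty aperture sets, all-zero fluence maps, beams that miss the grid, and
  zero-prescription cases all degrade to explicit no-op results rather than
  errors.

## Known limitations

* The annealer is a refinement engine at this scale: warm-started it
  reliably improves the two-step plan by ~8–11% total cost on the C-shape
  case; cold-started it does not reach two-step quality within the default
  iteration budget.
* Single-interval-per-row apertures cannot represent holes; shielding a
  central structure requires coordinated multi-aperture splits, which the
  baseline inherits from quantization and the annealer preserves but does
  not invent.
* No delivery constraints beyond x ≤ y (no interdigitation, leaf-speed or
  minimum-field-size rules).
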