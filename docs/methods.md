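# Methods

This note records the model assumptions, the design of the synthetic-data
generators, the numerical choices, and the known limitations of the
package. Units are micrometres and seconds throughout; mass densities are
kg/m³ and thermal energy is in joules, converted only inside the
sedimentation-length calculation.

## Wetting model of aggregate spreading

The precursor film is treated as an incompressible cell monolayer pulled
outward by the motile cells on its rim (driving force `S` per unit length
of contact line) against two dissipation channels: permeation of cells from
the aggregate into the film across a region of width `ξ` at the contact
radius `R_L ≈ R₀`, and slippage of the film on the substrate with friction
coefficient `k`. Permeation dominates when `η/R_L > k ln(R/R_L)`, which
holds for cell aggregates because the bulk tissue viscosity far exceeds the
sliding friction; `permeation_dominant` implements exactly this inequality
and `dissipation_terms` returns the two balance terms. In that regime the
area grows linearly, `A(t) = A₀ + R₀V*t`, which is what `spread_area`
evaluates and `fit_velocity` inverts (ordinary least squares of `A` on `t`;
`V* = slope/R₀`, `D = slope`). No PDE is solved anywhere: only the printed
balance and the regime check are implemented.

Velocity enhancement by substrate roughness is modelled as
`V*(φ_S) = V₀(1 + α φ_S)` with a *hard* clamp at the plateau coverage
`φ_S^P` (default 0.6, dense sphere packing): the velocity is reported as
exactly constant above the plateau, with no smooth crossover, because the
observation being modelled is a flat plateau.

## Particle conservation and the aureole

The conservation statement equates particles swept from the substrate disk,
`πR²ν`, with particles held in the aureole annulus. The annulus area is
approximated as `2πRΔ` (thin-annulus approximation) and the annulus holds
`2πRΔ/A_cell` cells, each with `C_i V_cell` internal particles and
`2 C_S A_cell` membrane-adsorbed particles — the factor 2 counts both the
apical and basal membrane faces and is required to reproduce the published
per-cell adsorbed counts. Below the critical radius `R_c` the aureole is
defined as the first cell row, `Δ = d_cell`, a constant (not a
partial-filling interpolation); above `R_c` the width follows
`Δ(3φ_is V_cell/(d A_cell) + 4φ_s) = Rφ_S`. The two branches are
algebraically continuous at `R_c` when `φ_s = 0`, and `conservation_residual`
verifies the balance for any state (normalized by `πR²ν`).

Parameter conventions:

* `V_cell` defaults to **1600 µm³**, the value used in the conservation
  algebra (it reproduces the 137-µm critical-radius coefficient exactly);
  the suspended-cell measurement of 1620 µm³ is available through
  `CellGeometry(V_cell_um3=1620)`. The two differ because they are
  independent measurements on cells in different states.
* `cluster_factor` (≥ 1, default 1) expresses that flocculating particles
  (amine-functionalized polystyrene in culture medium) are taken up as
  clusters. It divides **counts only** (`particle_counts` returns numbers
  of clusters); volume- and surface-fraction algebra is invariant under
  clustering and carries no correction.
* `φ_s = a(φ_S − φ_S0)` clipped at zero. The printed thresholds are only
  order-of-magnitude ("~0.5", "~0.2", "~0.46"), so preset `phi_S0` values
  are treated as initial conditions for fitting, not as truths.

## Synthetic-data generators

The generators produce every input the pipeline consumes, with ground truth
attached, under the conditions of the source experiments: aggregates of
initial radius 75 µm imaged one frame per 10 minutes for 15 h.

**Trajectories** (`make_trajectory`): each aggregate draws its own velocity
once from `N(V*, σ_v)` — aggregates genuinely differ — then every area
sample receives independent multiplicative Gaussian noise (default relative
SD 5%). The per-aggregate σ_v defaults to the across-aggregate SDs of the
reported velocities (0.9×10⁻² µm/s on the bare substrate). The source data
do not state a per-frame measurement noise, so the 5% figure is a modelling
choice; it is of the order of hand-traced contour variability.

**Front-uptake simulator** (`simulate_front_uptake`): cell rows are
*material cohorts* riding at the film edge — row 0 is the leading row
occupying `[R − d_cell, R]`, and a row's cell count (hence capacity) grows
as `R` grows and new cells join it. At each time step the integer increment
of `round(νπ(R² − R₀²))` particles is offered to row 0 first; a row
internalizes up to `φ_is V_cell/v_p` per cell, then (above the threshold
coverage) adsorbs up to `2φ_s A_cell/(πd²/4)` per cell, and leftovers pass
inward to the next row. Using differences of a cumulative rounded count
makes the ledger *exactly* integer-conserving at every step:
in-cells + unclaimed + on-substrate = initial. The aureole width
`Δ = d_cell × (number of particle-loaded rows)` is emergent, not imposed;
in the continuum limit the model reproduces the critical radius identically
(first-row capacity `2πR_c d_cell n_i/A_cell = πR_c²ν` is the critical-radius
relation rearranged). Particle partitioning within a row is uniform by
default (`partition_row_load`), matching the observation of constant
particle density inside the aureole; a multinomial mode exists for
heterogeneity studies.

Two discretization effects matter when comparing the simulator against the
closed-form width law: (i) `Δ` is a staircase in steps of `d_cell = 22 µm`,
so slopes must be regressed over runs whose aureole spans many rows; and
(ii) the simulator uses exact annulus areas while the conservation law uses
the thin-annulus `2πRΔ`, so the emergent `Δ/R` exceeds the closed form by
≈ `Δ/2R`. Cross-module recovery checks therefore use sub-threshold
coverages with `Δ/R ≲ 0.15–0.2` and fronts run to `R ≈ 1.5–2 mm`; under
those conditions `φ_is` inverts to within 6–8% of truth, and no better —
that residual is the approximation itself, not a bug.

**Bright-field renderer** (`render_micrograph`): concentric flat-intensity
regions — aggregate disk (dark), cleared film (bright), aureole annulus
(darkest), and the particle carpet as per-pixel Bernoulli speckle at
probability `φ_S` (multilayers `φ_S > 1` cannot be rendered and saturate).
No optical point-spread function, shading or sensor noise is simulated:
the measurement operations are threshold-based, and flat regions exercise
them fully. Default 2 µm/pixel; rendering refuses pixel sizes that do not
resolve a cell (< 4 px per `d_cell`) or fields of view smaller than the
aureole.

**Confocal renderer** (`render_zstack`): a spherical cell of volume
`V_cell`, a concentric spherical nucleus at the requested volume fraction,
and non-overlapping bead spheres placed in the cytoplasm by random
sequential addition (packing refused above volume fraction 0.4; placement
has a bounded retry budget). Slices are 0.25 µm apart in z, matching the
confocal sampling; channels carry mild Gaussian noise so the threshold step
is non-trivial. Voxel-counted true volumes are stored as ground truth.

What passing tests on these synthetics do **not** show: robustness to
uneven illumination, debris, out-of-focus light, irregular cell shapes or
non-circular films. The measurement operations are deterministic analogs of
a manual tracing workflow, validated on clean geometry.

## Image measurements

Segmentation replaces hand tracing with a three-class Otsu threshold
(dark structures / carpet background / bright film), largest connected
component, and hole filling. The film-plus-aureole region is the filled
union of the bright and dark classes; the film-without-aureole region is
the filled bright class (the aggregate sits as a hole inside it and is
filled). Radii are *equivalent-circle* radii `sqrt(A/π)` — matching the
area-difference definition of the aureole width, `Δ = R_outer − R_inner` —
rather than maximal or mean contour radii. A frame with less than about one
pixel-ring of dark annulus area reports `Δ = 0` with a low-confidence flag.
The optical surface fraction is the dark-pixel fraction of the carpet
region (outside the outer contour) under a global Otsu threshold; it
saturates below 1 and cannot resolve multilayers. Z-stack volumes use the
rectangle rule — per-slice thresholded area × z-step, the lower slice's
area — deliberately mirroring the elementary-volume summation procedure
rather than trapezoidal integration. Radial intensity profiles use pixel
centers with the origin at the image center, in bins of one cell diameter,
and report uncalibrated relative intensity.

## Fitting

* `fit_velocity`: OLS of `A` on `t`; needs ≥ 3 points; a negative slope is
  reported with a "non-spreading" flag rather than an error.
* `fit_enhancement`: writing `V = b₀ + b₁ min(φ_S, φ_S^P)` makes the
  piecewise model linear for a fixed breakpoint, so the breakpoint is found
  by a coarse grid (step 0.05) with local refinement (step 0.01) — robust
  with the ≤ 7 coverage levels of a realistic ladder, where a
  derivative-based search is not. Candidate breakpoints must leave ≥ 3
  points on the linear branch; `α = b₁/b₀` with a delta-method standard
  error. Flat responses and single-branch data are flagged
  "plateau unidentifiable" instead of failing. Optional per-point weights
  (1/SE) support ladders whose levels average different numbers of
  aggregates.
* `fit_uptake`: two-step, as the quantities are reported: the sub-threshold
  branch (`φ_s = 0`) gives `φ_is` from a through-origin slope of `Δ/R` on
  `φ_S`; with `φ_is` fixed, the supra-threshold branch is linear in `a` for
  each candidate threshold, and `φ_S0` is grid-searched like the breakpoint
  above. A joint refit of `(φ_is, a)` is available behind `joint=True`.
* Estimator note: with few points and large noise the breakpoint ratio
  `α = b₁/b₀` is heavy-tailed; recovery checks therefore fit per-level
  *ensemble means* (each level averaging its study-sized aggregate sample)
  and average the fitted `α` over replicate experiments. A small positive
  selection bias (~+0.03–0.05 on α ≈ 1.3) from choosing the breakpoint by
  minimum RSS remains and is visible in the swept estimates.

## Problem sizes

The test suite and the acceptance script run synthetic experiments at the
scale of the source study: 10–20 aggregates per ensemble, 90-frame
trajectories, coverage ladders of 5–8 levels with per-level sample sizes
(48, 9, 11, 11, 8, 10), 16-replicate sweeps for the enhancement fit,
single frames of ~500² px at 2 µm/px, and one ~67³-voxel Z-stack per
check. Front simulations used for slope recovery run to R ≈ 1–2 mm so the
aureole spans ≥ 10 cell rows.

## Known limitations

* The conservation model's thin-annulus approximation biases `Δ` low (or
  fitted fractions high) once `Δ/R` approaches its 0.3 plateau; the fitted
  `a` partially absorbs this.
* The printed slope `a = 0.9` and the plateau `Δ/R = 0.3` are not exactly
  mutually consistent (`1/(4a) ≈ 0.28`), and which points or weights the
  original fits used is unstated; fitted `(a, φ_S0)` should be read with
  that latitude.
* Flocculation is not modelled: `PsAmine200` carries a free
  `cluster_factor` instead, and its count rows are counts of clusters.
* Particles larger than ~5 µm, which are pushed by the film instead of
  internalized, are out of scope, as are cell division with internalized
  particles and soft-particle rigidity effects.
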