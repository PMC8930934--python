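# Methods

## Coordinate conventions and input model

A segmented compartment is a pair of binary grids on a coronal slice
stack: a solid 3D meniscus mask with axes `(y, z, x)` — coronal slice
(anterior→posterior), inferior→superior, internal→external medio-lateral —
and a 2D tibial plateau footprint over `(y, x)`, representing the total
area of subchondral bone (cartilage surface including denuded bone,
ACdAB) projected onto the tibial plane.  "External" always points away
from the knee midline for the compartment at hand, so medial and lateral
compartments use the same code after mirroring the x axis at load time if
necessary.  Default spacing is the coronal DESS reconstruction used in
OA imaging: 1.5 mm slice thickness, 0.37 mm in-plane.

The original measurement technique segments three meniscus surfaces
(tibial, femoral, external).  This package stores a solid meniscus region
instead and derives the tibial surface as the per-column (y, x) projection
of the solid mask: the surfaces are recoverable from the solid voxel set,
and a solid representation makes phantom generation and label-volume I/O
straightforward.

## Position and morphology measures

Per slice, the extrusion distance is the signed in-slice distance between
the external-most occupied cell of the meniscus tibial footprint and of
the plateau footprint, times the in-plane spacing.  Design choices that
the measure definitions leave open, resolved here:

* **Signed averaging.** Negative per-slice extrusions (meniscus margin
  internal to the plateau margin — the rule rather than the exception
  laterally) enter the mean untruncated.  A lateral mean extrusion of
  about −0.3 mm is expected in OA cohorts, which signed averaging
  reproduces and positive-truncation cannot.
* **Averaging domain.** A slice contributes to mean/max extrusion only if
  both structures are present in it; slices lacking either are excluded,
  never zero-imputed, because zero-imputation would bias means toward zero
  in proportion to slice coverage, i.e. in a spacing-dependent way.
* **Central windows.** The central slice index is `floor((y_first +
  y_last)/2)` over slices containing meniscus; for an even slice count
  this is the anterior of the two middle slices (a deterministic,
  documented tie-break).  The central-5 window is that index ±2,
  intersected with the occupied slices.
* **Margins are cells, not contours.** The external margin is the
  external-most occupied cell; no sub-voxel contour fitting.  This keeps
  every measure exactly reproducible by integer cell enumeration, which
  the oracle tests exploit.  Sub-voxel refinement is out of scope.
* **Degenerate inputs raise typed errors** (`EmptyStructureError`,
  `UndefinedSliceError`, `UndefinedMeasureError`) rather than returning 0,
  so cohort aggregation can distinguish "absent" from "zero".

Coverage is the covered fraction of plateau cells; extrusion area is the
fraction of meniscus-footprint cells outside the plateau (cell counts —
the uniform cell area cancels).  Height is counted per (y, x) column as
voxel count × z-spacing, width per slice as the inclusive x-extent of the
meniscus footprint, volume as voxel count × voxel volume.  Anterior/
posterior extrusion is deliberately not measured: coronal stacks do not
support it.

## SDC-based progression classification

The smallest detectable change is `SDC = 1.96 · SD(test–retest change
differences)` with the n−1 SD (equivalently `1.96·√2·SEM`).  The method
literature's thresholds — 102 µm (medial cartilage thickness), 92 µm
(lateral), 328 µm (medial minJSW) — are injected as defaults rather than
recomputed, so the classification thresholds never drift with a
simulation; `compute_sdc` exists to recover such thresholds from
test–retest data.

"Exceeding" a threshold is strict (`>`) for progressors and complementary
(`≤`) for non-progressors, so boundary values are non-progressor-compatible;
the `strict` flag flips this, documented because the verbal definition does
not pin it down.  Losses are computed in µm from mm-stored values (×1000
fixed).  Any record missing a needed baseline/follow-up value is
unclassifiable and reported with a reason code, mirroring funnel-style
exclusion logging.

## Matching

Eligibility: exact sex and KLG, |Δheight| ≤ 3 cm, |ΔBMI| ≤ 5 kg/m²,
|ΔWOMAC pain| ≤ 5.  Among maximum-cardinality 1:1 matchings on that
graph, the default algorithm picks one minimizing the total
caliper-normalized L1 distance, via an assignment problem in which
ineligible edges carry a cost that dwarfs any sum of eligible distances
(each eligible distance ≤ 3, the penalty 10⁹).  This is deterministic
given input order.  A greedy nearest-available variant is provided for
sensitivity analysis.  No claim is made that this reproduces the pairing
algorithm of any particular study — only the constraints and optimality.

## Statistics

Cohen's D uses the pooled two-group form `(m₁−m₂)/√((s₁²+s₂²)/2)`: it is
the only variant verifiable against published group cells (the paired
form needs the SD of pair differences, which results tables do not print).
Paired t and 95% CIs are the textbook `t_{0.975,n−1}` constructions on
within-pair differences (scipy's t distribution).  r²% is `round(100·r²)`.
No multiple-testing correction is applied, matching the analysis being
emulated.  Raw tables carry full precision; rounding (half away from
zero, 1 dp for measures, 2 dp for d and p, `< 0.01` floor below 0.005) is
strictly a presentation-layer concern.

## Phantoms

The box phantom (rectangular footprints, per-slice integer offsets) has
exact closed forms for all ten measures and anchors the exact tests.  The
C phantom is an annulus-sector wedge (height linear from 0 at the inner
rim to 5 mm at the outer rim, 160° arc, radii 8/18 mm) over an 18 mm
disc plateau, rasterized by cell-center membership; its reference values
come from rasterizing the same continuous geometry at 4× finer spacing,
plus a closed-form volume integral.  It is a geometric idealization for
convergence testing, not an anatomical model: validation claims rest on
oracle agreement, not anatomy.

## Cohort simulator

The simulator draws per-knee values from normal (or multivariate normal)
distributions whose means/SDs are the published group summary cells of a
37-pair medial-progression case-control study: nine meniscus measures per
compartment and group, baseline and 12-month-change cartilage/minJSW
values, and covariates.  Structure beyond the printed moments:

* Entire-vs-central extrusion is drawn trivariate with correlations 0.93
  (central 5) and 0.88 (central slice); the unprinted central5–central1
  correlation defaults to 0.95 (within the PSD-feasible range).  The
  central-window variants of coverage, volume, height and width reuse the
  entire-meniscus moments (their central moments are unpublished) with
  published entire-vs-central-5 correlations 0.84/0.85/0.73/0.90.  All
  other cross-measure correlations default to 0 — no others are published.
* MFTC and minJSW 12-month losses are drawn with correlation 0.8 within
  each group: both track medial structural progression and the progressor
  definition requires them to co-exceed their thresholds, so independent
  draws would be unrealistic; under this default the closed-form
  bivariate-normal probability that a progressor-arm draw exceeds both
  thresholds is 0.755, and the tests compare the simulated classification
  rate against that closed form.
* Maximal height (unpublished) is mean height plus a positive truncated-
  normal rim offset, which also keeps max ≥ mean per knee.
* Draws are clipped to physical bounds (percentages to [0, 100];
  volumes/heights/widths ≥ 0) and the truncation rate is reported.  Where
  the bound is active — notably lateral extrusion area, mean 7.8 ± 7.3 —
  the realized moments are those of the censored normal, and the tests use
  the censored-normal closed form as the oracle.
* Control covariates are drawn relative to the matched case (truncated
  normals inside the calipers; same sex and KLG), so simulated pairs
  satisfy the matching constraints by construction.

All randomness flows through one `numpy` Generator seeded explicitly;
identical spec + seed give bit-identical tables.  Simulated measure rows
are statistical draws, not geometry: deterministic inequalities that hold
for any real segmentation (e.g. max ≥ mean extrusion within a knee) are
not enforced across independently drawn columns.  Consequently, passing
simulation tests demonstrates correct statistical machinery and parameter
recovery — not anatomical realism, segmentation robustness, or behaviour
under non-normal measurement error.

## Problem sizes and tolerances

The oracle suite checks ≥ 100 random masks up to 16³ voxels against exact
rational enumeration (agreement to 1e−12, i.e. float round-off).
C-phantom agreement with the 4×-finer oracle is required within one
in-plane voxel (0.37 mm) for distances, 5% for volume, and 5 percentage
points for area fractions.  Simulation recovery uses 5000 pairs (pooled-d
sampling error ≈ 0.02) and matching oracles search exhaustively up to
8×8 via bitmask dynamic programming.  CI coverage is checked over 5000
replicates of n = 37 (binomial SE ≈ 0.3%, acceptance line 94% for nominal
95%).

## Known limitations

* Published effect sizes whose printed value is inconsistent with the
  printed group cells (height rows; lateral rows affected by censoring)
  cannot be regenerated from those cells; the simulator recovers the
  cell-implied (censored-)normal effect sizes instead.  The corresponding
  strict print-level check in the acceptance tests documents this gap.
* The solid-mask representation assumes the segmentation already encodes
  the internal meniscus border convention; no segmentation, damage/tear
  scoring, or sagittal (anterior/posterior) extrusion.
* Extrusion is measured along the in-slice medio-lateral axis, not
  perpendicular to the local plateau margin contour; with near-coronal
  margins the two coincide to within the stated voxel tolerance.
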