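# meniquant

Quantitative 3D meniscus morphometry and structural-progression analysis
for knee osteoarthritis (OA) imaging studies.

Meniscus extrusion — displacement of the meniscus beyond the external
margin of the tibial plateau — is a candidate predictor of subsequent
structural OA progression. `meniquant` implements the full quantitative
workflow around that question:

* **Morphometry** — from a voxelized coronal segmentation of one
  femorotibial compartment (solid meniscus mask + tibial plateau footprint,
  ACdAB), compute the position measures (signed per-slice extrusion
  distance, mean/max extrusion over the entire meniscus and over the
  central 1 or 5 coronal slices, tibial plateau coverage %, extrusion
  area %) and the morphology measures (volume, mean/max height, mean
  width).  Per slice *y*, the extrusion distance is

  `e(y) = (x_max^meniscus(y) − x_max^plateau(y)) · Δx`

  where `x_max` is the external-most occupied cell of each footprint;
  negative values (meniscus margin internal to the plateau margin) are kept.
* **Progression** — smallest detectable change (SDC = 1.96 · SD of
  test–retest change differences) thresholds; a knee is a *progressor* when
  its 12-month medial cartilage-thickness loss (MFTC) **and** medial
  minimum joint-space-width loss both exceed their SDC thresholds (defaults
  102 µm and 328 µm), a *non-progressor* when medial and lateral losses all
  stay within thresholds (lateral SDC 92 µm); KLG 2–3 eligibility; optimal
  1:1 case-control matching under exact sex/KLG and ±3 cm height, ±5 BMI,
  ±5 WOMAC-pain calipers.
* **Statistics** — paired comparison tables (group mean ± SD, mean paired
  difference with 95% CI, paired *t*, pooled-SD Cohen's D
  `d = (m₁ − m₂)/√((s₁² + s₂²)/2)`) and the central-slice surrogate
  analysis (Pearson r and r²% between entire-meniscus and central-window
  measures).
* **Phantoms & simulation** — box phantoms with closed-form ground truth,
  a C-shaped wedge phantom rasterized against a finer-grid oracle, and a
  cohort simulator whose defaults reproduce the published group summary
  statistics of a 37-pair progressor/non-progressor study — so the whole
  pipeline runs and is tested without any imaging data.

## Worked example

```python
import meniquant as mq

# A box phantom: 11 coronal slices, plateau 20 cells wide, an 8-cell
# meniscus whose external margin rises to 5 cells beyond the plateau rim.
seg, truth = mq.make_box_phantom(mq.BoxPhantomSpec(
    n_slices=11, plateau_extent_x=20, meniscus_extent_x=8,
    external_offset=[0, 1, 2, 3, 4, 5, 4, 3, 2, 1, 0], meniscus_height=4))
for k, v in mq.compute_all_measures(seg).as_dict().items():
    print(f"{k:28s} {v:8.3f}")
```

```
extrusion_area_pct             28.409
mean_extrusion_mm               0.841
max_extrusion_mm                1.850
mean_extrusion_central5_mm      1.406
mean_extrusion_central1_mm      1.850
coverage_pct                   28.636
width_mean_mm                   2.960
height_mean_mm                  1.480
height_max_mm                   1.480
volume_ml                       0.072
```

At the default DESS spacing (1.5 mm slices, 0.37 mm in-plane) the mean
offset of 2.27 cells corresponds to 0.841 mm mean extrusion; the central
slice carries the maximal 5-cell offset (1.85 mm); 28.4% of the meniscus
tibial surface lies outside the plateau.  Every one of these numbers has a
pencil-and-paper closed form (`truth`), which the test suite asserts
exactly.

A simulated 37-pair matched cohort, compared like a study results table:

```python
cohort = mq.simulate_cohort(mq.CohortSimSpec(n_pairs=37), seed=1)
table = mq.comparison_table(mq.measures_frame(cohort.cases, "med"),
                            mq.measures_frame(cohort.controls, "med"))
print(mq.format_comparison_table(table).to_string(index=False))
```

```
                             Measure Mean cases SD cases Mean controls SD controls Mean diff    95% CI Cohen's D      P
                  Extrusion area (%)       29.6     11.3          30.2        16.9      -0.6 -7.1, 5.8     -0.04   0.84
        Mean extrusion distance (mm)        2.6      1.2           2.1         1.3       0.5 -0.1, 1.1      0.38   0.11
        Max. extrusion distance (mm)        5.3      1.3           4.1         0.9       1.2  0.6, 1.7      1.03 < 0.01
Mean extrusion 5 central slices (mm)        3.4      1.6           2.3         1.8       1.2  0.4, 2.0      0.69 < 0.01
   Mean extrusion central slice (mm)        3.5      1.7           2.3         1.7       1.3  0.4, 2.1      0.75 < 0.01
         Tibial plateau coverage (%)       34.7     13.7          34.8        14.0      -0.1 -7.2, 7.0     -0.01   0.98
               Width mean total (mm)        7.7      1.6           7.8         1.6      -0.1 -0.9, 0.7     -0.06   0.82
                    Height mean (mm)        2.9      0.4           2.6         0.4       0.3  0.1, 0.5      0.74   0.01
                         Volume (ml)        2.0      0.6           1.9         0.7       0.1 -0.1, 0.4      0.19   0.34
```

Max extrusion and the central-slice extrusion measures separate the groups
(large d, p < 0.01) while coverage, width and volume do not — the pattern
the method is designed to detect.  At n = 37 the effect sizes are noisy;
at n = 5000 they converge to the values implied by the generator.

## Command line

```bash
meniquant simulate --out-dir cohort --seed 1 --n-pairs 37
meniquant compare  --cases cohort/cases.csv --controls cohort/controls.csv --out table3.csv
meniquant correlate --cohort cohort/cases.csv --out table5.csv
meniquant measure knee_*.nii.gz --out measures.csv
meniquant classify --cohort cohort/cases.csv --out classified.csv
meniquant match --cases classified_cases.csv --controls classified_controls.csv --out pairs.csv
```

Masks are NIfTI or MetaImage label volumes (1 = meniscus, 2 = plateau
footprint, 3 = both; configurable).  Every subcommand writes a provenance
record (config hash, input checksums, package version).

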