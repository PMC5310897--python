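# flowtaxis

Quantification of fluid-shear-driven cell migration ("flowtaxis") from
time-lapse microscopy.

Adherent cells — here modelled on MC3T3-E1 osteoblasts in a parallel-plate
flow chamber — change their migration behaviour when exposed to wall shear
stress (groups labelled static, FF2, FF15, FF25 for 0/2/15/25 dyne cm⁻²).
Given phase-contrast image stacks recorded once per minute, or pre-tracked
centroid tables, this package computes the standard single-cell migration
statistics used to characterise that response, together with the group
comparison statistics, end to end:

* **drift correction** by normalised cross-correlation of a fixed cell-free
  template region (integer-pixel shifts);
* **segmentation** combining an Otsu threshold on the local image entropy
  with an Otsu threshold on the Sobel gradient magnitude, followed by hole
  filling, opening and small-object removal;
* **tracking** by deterministic greedy nearest-neighbour linking, with
  whole-track exclusion of cells that touched another cell, reached the
  frame border, or disappeared early;
* **migration metrics** per cell and per ensemble (below);
* **group statistics**: one-way ANOVA with a Tukey–Kramer post-hoc test,
  with optional log₁₀ transform of skewed metrics and back-transformed
  (geometric-mean) reporting.

A fully-tested synthetic-data module simulates cohorts with the statistical
structure the analysis assumes (a two-state biased persistent random walk)
and renders them as phase-contrast-like TIFF stacks with exact ground
truth, so every stage is verifiable without microscopy recordings.

## The statistics

For cell *i* with position **x**ᵢ(t), the ensemble dispersion at each frame
is the root-mean-square displacement over the N cells of a group,

```
X_RMS(t) = sqrt( (1/N) Σᵢ |xᵢ(t) − xᵢ(0)|² )
```

and the **motility coefficient** is the slope of X_RMS against √t
(µm min⁻¹ᐟ²), a diffusion-coefficient analogue for cell dispersal.  Per
cell and per time window (short-term 0–30 min, long-term 0–120 min) the
package reports:

* **displacement** |**x**(t_end) − **x**(t_start)| and total **path
  length** Σ|Δ**x**| (µm);
* **confinement ratio** = displacement / path length (1 = straight path,
  0 = closed loop);
* **arrest coefficient** — the fraction of frames with instantaneous speed
  strictly below a pause threshold set one standard deviation below the
  mean static-condition speed (the published static statistics, mean
  0.21 µm min⁻¹ and SD 0.05 µm min⁻¹, give 0.16 µm min⁻¹);
* **directionality** — a cell (or step) migrates *with* the flow if its
  direction lies within ±π/8 of the flow axis, *against* if within ±π/8 of
  the opposite direction.

## Worked example

Simulate the shear-series cohort, quantify it, and compare the short-term
arrest coefficients across groups:

```sh
$ flowtaxis simulate --preset paper_osteoblast --seed 1 --out tracks.csv
wrote 120 tracks (4 groups) to tracks.csv

$ flowtaxis quantify --tracks tracks.csv --out-dir quant --static-group static
arrest threshold 0.08148 um/min; wrote summaries to quant

$ flowtaxis stats --summary quant/summary_per_cell.csv \
      --metric arrest_coefficient --window short_term
metric: arrest_coefficient/short_term
transform: none
ANOVA: F = 12.54, p = 3.698e-07 ***
  FF15: mean = 0.1322 (n = 30)
  FF2: mean = 0.1522 (n = 30)
  FF25: mean = 0.07444 (n = 30)
  static: mean = 0.24 (n = 30)
pairwise (Tukey-Kramer):
  FF15 vs FF2: diff = -0.02, p = 0.885
  FF15 vs FF25: diff = 0.05778, p = 0.1567
  FF15 vs static: diff = -0.1078, p = 0.000819 ***
  FF2 vs FF25: diff = 0.07778, p = 0.02716 *
  FF2 vs static: diff = -0.08778, p = 0.0094 **
  FF25 vs static: diff = -0.1656, p = 1.138e-07 ***
```

The quantify step derives the pause threshold from the simulated static
group (0.081 µm min⁻¹ here — the simulated cohort is not the published
recording) and every flowed group pauses significantly less than the
static control in the first 30 min, with the effect ordered by shear
(static 0.24 > FF2 0.15 > FF15 0.13 > FF25 0.07): the short-term
shear-sensitivity the pipeline is built to measure.  `quant/` also holds
per-cell tables, RMS-displacement curves and per-minute speed series.

The same stages run from a single config file (`flowtaxis all --config
run.yaml`), including image mode: drift-correct a TIFF stack
(`flowtaxis segment --template y0,x0,h,w ...`), link detections
(`flowtaxis track ...`), then quantify as above.  All stages are importable
as a library (`import flowtaxis`).

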