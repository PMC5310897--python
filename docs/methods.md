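# Methods

## Scope and data model

The package quantifies single-cell migration under steady fluid shear from
time-lapse imaging sampled at a uniform frame interval (default 1 min for
121 frames, covering 0–120 min).  The atom of every statistic is a
`Track` — one cell's centroid positions (µm) on a strictly uniform time
base — and tracks are grouped into a `TrackSet` per experimental condition
(shear level × genotype).  Shear stress itself is metadata: it labels
groups and selects simulation presets but never enters any equation.

## The synthetic cohort generator

No public recordings exist for the experiments this pipeline targets, so
the generator supplies ground truth.  It is a **two-state biased
persistent random walk** — the minimal model that produces every
phenomenon the analysis layer measures, with one parameter per phenomenon:

* **Motile state.** The heading θ evolves each frame by wrapped-normal
  noise (SD `persistence_sigma`, rad) plus a deterministic pull
  `bias_kappa·sin(−θ)` toward the flow axis (+x).  The step speed is drawn
  as `max(0, Normal(µ(t), speed_sd))` with

      µ(t) = base_speed · (1 + transient_amp · exp(−t / transient_tau)),

  i.e. a speed transient that decays with time constant `transient_tau`
  (min), emulating the short-lived shear sensitivity seen after flow
  onset.
* **Paused state.** The cell jitters by `pause_speed·dt` in a uniformly
  random direction; its heading is retained for resumption.
* **Switching.** A Markov chain with per-frame probabilities `p_pause`
  (motile→paused) and `p_resume`.  The initial state is drawn from the
  stationary distribution `p_pause/(p_pause+p_resume)` so that windowed
  arrest statistics estimate the stationary paused fraction without
  burn-in bias.

Random draws are consumed for every cell at every step regardless of
state, so the random stream layout — and therefore reproducibility under a
fixed seed — does not depend on realised states.  Cohorts spawn one
independent child stream per group from the master seed; repeated runs are
byte-identical.

### Presets

`paper_osteoblast` emulates the shear series {static, FF2, FF15, FF25}.
The parameters were fixed once from pause-mixture arithmetic (stationary
pause fraction × truncated-normal motile speed): a common motile base
speed of 0.22 µm min⁻¹ (SD 0.10), pause jitter 0.05 µm min⁻¹,
shear-ordered transient amplitudes (0, 1.1, 1.9, 3.2; τ = 10 min),
shear-ordered pause occupancies (0.18, 0.16, 0.09, 0.05) and heading
biases (0, 0.15, 0.30, 0.45).  These land the pooled 1-min ensemble speeds
near 0.20/0.42/0.57/0.81 µm min⁻¹ and make short-term arrest decrease with
shear while long-term contrasts attenuate (the transient is gone and only
the small pause-occupancy differences remain).  The preset values are
calibration choices, not measurements; only orderings and convergence
properties are asserted anywhere.

`paper_rock_sh` represents ROCK-shRNA knockdown purely as a parameter
preset: higher base speed, almost no pausing, and — under shear — stronger
heading bias with a much slower transient decay (τ = 40 min, a sustained
sensitivity window); the static knockdown instead wanders with high
heading noise and no bias (fast but unconfined).  `null` gives four
identically parameterised groups as a negative control for the statistics
layer.

Field-of-view and density defaults (30 cells per group, 256×256 px
renders) are configurable conventions, not inferred quantities.

### Rendering

`render_stack` draws each cell as a dark disk (radius default 6 px) with a
2-px bright rim (the phase halo) on a mid-grey background, scattered with
small static "debris" marks (radius 2 px) as on a real slide.  The whole
scene is shifted by an integer per-frame drift schedule and per-frame
Gaussian noise is added.  Debris serves the drift-correction template
(which needs structure), is kept ≥18 px from other debris and well clear
of every cell path (so entropy footprints never chain or attach to cells),
and stays below any sensible segmentation area cutoff.  Cells start on a
deterministic grid spaced by their maximum excursion, keeping rendered
cohorts well separated; the returned ground-truth table holds the exact
drift-free centroid per cell per frame and an `in_frame` flag (cells may
leave the frame — that is ground truth for the exclusion rules, not an
error).

## Image pipeline

**Drift.** The user designates a cell-free `template_box` in frame 0; each
frame is searched within ±`search_radius` px (default 20) by normalised
cross-correlation and the integer argmax is that frame's shift, with ties
broken by smallest magnitude then lexicographic (dy, dx).  A zero-variance
template is rejected with advice to pick a textured region.  Correction
translates each frame by the negated shift with nearest-edge padding;
sub-pixel registration is out of scope.

**Segmentation.** The cell mask is the union of (a) an Otsu threshold on
the local entropy (disk radius 5 px) of the fixed-scale uint8 image and
(b) an Otsu threshold on the Sobel gradient magnitude; union is the
default because faint-interior cells are found by entropy and sharp-edged
cells by Sobel (an AND mode is available).  Otsu's criterion degenerates
when foreground is absent — on a noise-only frame it bisects the
background — so either mask is discarded when it claims more than
`max_foreground_frac` (default 0.35) of the frame; cells are sparse, so a
mask claiming a third of the field has split background, and a blank frame
then yields zero detections as it should.  The mask is hole-filled, opened
with a radius-1 disk, and components below `min_area` are dropped.  The
default `min_area` of 30 px² is a scale-free floor; for the package's own
renders (radius-6 cells → ~300–500 px² components, debris entropy
footprints ≤ ~160 px²) the fixtures use 200 px².  Each 8-connected
component yields a detection: unweighted pixel-mean centroid converted to
µm, area, a border flag (bounding box touching the image edge), and a
`merged` flag for areas above `merge_area_factor` × the frame's median
component area — a relative rule, since magnification is configuration.
Note that entropy dilates components by roughly its disk radius, so two
touching cells merge into ≈1.4–1.6× a single-cell component, not 2×;
fixtures exercising the flag use a factor of 1.4.

## Tracking and exclusion

Linking is greedy nearest-neighbour per frame pair: candidate links are
taken globally in order of increasing distance (ties by lowest existing
cell id), each link capped at `max_step_um` (default 20 µm ≈ 20× the
fastest reported per-minute speed); unmatched detections found new tracks
and tracks unmatched for more than `gap_frames` (default 3) terminate.
Global assignment or probabilistic linking is unnecessary at the sparse
densities this pipeline targets, and greedy linking is fully
deterministic.

Exclusion is whole-track, applied after linking: any merged detection →
`touched_cell`; any border detection → `exited_frame`; failure to span the
observation window contiguously → `washed_away` (the operationalisation of
early permanent disappearance; late first appearance falls in the same
bucket).  Checks apply in that order.  Survivors are re-zeroed so the
position at t = 0 is the origin; an empty surviving cohort raises an
explicit error.  Simulated tracks are exact and bypass linking unless the
image route is deliberately exercised.

## Migration metrics: conventions

* Per-frame speed is the raw single-step speed |Δx|/dt — no smoothing.
* Ensemble per-minute speed averages over cells; SEM = SD(n−1)/√n, zero
  by convention for a single cell.
* Windows are closed intervals [t_start, t_end]; a window not fully
  covered by a track raises.  Metrics on [0, 120] equal whole-track
  metrics.
* Confinement ratio is defined as 0 when the path length is 0.
* The arrest threshold is the pooled static mean minus the pooled SD over
  all static per-frame speeds (population SD by default, `ddof`
  configurable — indistinguishable on realistic pools); a non-positive
  derived threshold raises with advice to pass an explicit one.  "Paused"
  is *strictly* below the threshold; boundary speeds count as moving.
* Direction classification uses the closed interval: |Δθ| ≤ π/8 is
  *with*, |Δθ − π| ≤ π/8 *against*; zero-magnitude vectors are *neither*.
  Angles follow the mathematical convention from +x; flow defaults to +x
  (left to right).
* The ensemble RMS curve requires complete, equal-length tracks
  (incomplete tracks must be excluded upstream, never zero-padded).
* The motility coefficient is an ordinary least-squares slope of RMS
  against √t with a free intercept, including the t = 0 point — the
  well-behaved reading of "slope of the plot" that keeps a plateau at
  slope ≈ 0; both a through-origin mode and exclusion of t = 0 are
  exposed.

## Group statistics

One-way ANOVA from explicit sums of squares, with documented degenerate
conventions: all values identical → (F = 0, p = 1); zero within-group
variance with unequal means → (F = ∞, p = 0).  Tukey–Kramer computes
q = |mean_a − mean_b| / sqrt(MSW/2·(1/n_a + 1/n_b)) per pair and takes the
adjusted p from the studentized-range distribution with k groups and N − k
df (valid for unequal n).  With two groups this reduces exactly to the
pooled two-sided t-test (q = |t|·√2), which the tests verify numerically.
Skewness handling applies log₁₀ when the absolute sample skewness of
pooled within-group residuals exceeds a cutoff (default 1.0; forcible
either way per metric, since the choice is configuration, not inference);
group means are then reported back-transformed (geometric means).
Significance is annotated in figure-style tiers (*, **, *** at 0.05, 0.01,
0.001).

## Orchestration

`run_pipeline` validates a single YAML/JSON config (one input mode among
simulate/tracks/images; seed mandatory for simulate), runs the stages in
order, and writes CSV artifacts (tracks, detections, exclusions, per-cell
and group summaries, speed series, RMS curves, motility table, stats
report), figures (raw and compass track plots; RMS curves with a dashed
marker at the 30-min end of the short-term window; speed curves with SEM
bands), and a provenance record (config hash, seed, versions).  Outputs
are byte-reproducible given the same config and seed.  Figures are
conveniences; all quantitative checks run on the CSV outputs.

## What the tests do and do not show

The synthetic generator reproduces the *statistical structure* the
analysis assumes — two-state kinetics, a decaying speed transient,
directional bias, drift, phase-halo-like appearance — but not the
morphology of real phase-contrast cells (shape changes, ruffling,
illumination gradients), cell division, or density effects beyond simple
overlap.  Passing tests therefore validate the correctness and calibration
of the measurement pipeline, not segmentation fidelity on real microscopy;
segmentation parameters (`entropy_radius`, `min_area`,
`merge_area_factor`, `max_foreground_frac`) must be chosen per dataset.
Published per-group values serve as preset calibration targets only; the
quantities asserted are exact arithmetic (the 0.16 µm min⁻¹ threshold),
internal-consistency oracles (double-loop RMS, brute-force walk slope,
Markov stationary fraction, arc fractions), image round trips against
rendered ground truth, null calibration of the statistics layer, and the
qualitative shear orderings.

Problem sizes used by the test suite and the acceptance script (e.g.
1000–1500 cells for parameter recovery, 400–1000 replicates for
calibration, 12–15-frame renders) were chosen to keep Monte-Carlo error
comfortably inside the asserted tolerances while remaining quick to run.

## Known limitations

* Integer-pixel drift only; large rotational drift is not modelled.
* Greedy linking can swap identities if cells approach within one frame's
  step limit; the exclusion rules remove most such cells (as merged
  components) but the linker itself has no global optimisation.
* The entropy/Sobel segmentation assumes sparse cells on a roughly uniform
  background; confluent fields violate the foreground-fraction guard.
* The arrest threshold inherits the static cohort's sampling noise; with
  few static cells the derived threshold can drift near the pause-jitter
  magnitude.
* The two-state walk has constant switching probabilities, so arrest
  contrasts attenuate over long windows only through the speed transient
  and modest occupancy differences, not through time-varying kinetics.
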