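# Methods

## Scientific background and scope

After aneurysmal subarachnoid hemorrhage (SAH), narrowing of the large
intracranial arteries (cerebral vasospasm) can cause delayed cerebral
ischemia.  Surveillance commonly combines CT angiography (CTA) and CT
perfusion (CTP); catheter angiography (DSA) is the invasive gold standard
for grading spasm and delivering endovascular treatment.  `vasovol`
implements an investigator-independent volumetric read-out of CTA: for each
segment of the circle of Willis and its major branches, the vessel volume V
(µL) and centerline length L (mm) are measured and summarized as the
volume/length ratio V/L (µL/mm).  Since V/L is the segment's mean
cross-sectional area, a diameter reduction by a fraction d scales it by
(1 − d)².  Severe vasospasm on DSA means grade 2 on the 0/1/2 scale
(0 none, 1 < 50% diameter change, 2 > 50% narrowing).

The package covers: synthetic phantom and cohort generation, vessel
reconstruction and per-segment measurement, per-segment severity-threshold
calibration (ROC/Youden with stratified bootstrap), decision rules
(k-segment CTA criteria, CTP hypoperfusion flag, their conjunction), and
diagnostic-table evaluation.  It does not segment bone, label anatomy
automatically, process raw perfusion time series, or handle DSA images.
No threshold is calibrated for the vertebral artery (its caliber varies too
much between sides and individuals); vertebral rows are rejected wherever
they appear.

## Vessel reconstruction and measurement

1. **Windowing** (`window_segmentation`): voxels with intensity in
   `[low, high]`, keeping 26-connected components of at least
   `min_component_voxels` voxels (default 1; 50 is a sensible value for
   noisy data).  The window bounds are required configuration with no
   defaults: they depend on scanner and contrast protocol and any built-in
   constant would be arbitrary.  Bone removal is supported only as an
   optional user-supplied exclusion mask applied before windowing.
2. **Skeletonization** (`skeletonize`): sequential 3-D thinning ordered by
   the Euclidean distance transform.  A border voxel is deleted iff it is a
   simple point (deletion preserves both the 26-connected foreground and
   6-connected background topology, decided in the 3×3×3 neighborhood by
   the standard two-component characterization) and not a curve endpoint.
   Sequential deletion makes topology preservation exact; distance ordering
   peels the mask in shells so the skeleton stays on the medial ridge.
   Endpoint-preserving thinning leaves short side spurs where the voxelized
   surface is stair-stepped; leaf branches that terminate at a junction
   within `prune_spurs` voxels (default 12) are pruned.  Free chain ends
   are never shortened by pruning.  The implementation is numba-compiled;
   the first call in a session pays a one-time JIT cost of a few seconds.
3. **Tracing** (`trace_segment`): landmarks (world mm) are snapped to the
   nearest skeleton voxel within `max_snap_distance` (default 5 mm); the
   centerline is the shortest path on the 26-connected skeleton graph with
   edge weights equal to physical step lengths under the (possibly
   anisotropic) voxel spacing.  Thinning necessarily retracts a tube's
   skeleton by about one radius from a flat end (the medial axis of a
   capped cylinder genuinely stops short of the cap), so the path is
   extended from each snapped tip straight to the landmark voxel, after
   trimming terminal path voxels that lie no farther from the landmark
   than the tip itself (these belong to the wandering tip cluster).
   Landmarks should therefore be placed at the anatomical ends of the
   segment, on or near the vessel axis.
4. **Length** (`path_length`): sum of physical step lengths along the
   path.  A raw 26-connected chain overestimates a smooth curve's length
   by several percent (staircase zigzag); `measure_segment` therefore
   smooths the voxel-center polyline with a centered moving average of
   window 3 (edge-replicated, endpoints fixed) before summing.  On
   phantoms this reduces the length error of a semicircular tube from
   +6.0% to −0.1% while leaving straight chains exact.  `path_length`
   defaults to the raw sum (`smooth_window=1`).
5. **Volume attribution** (`assign_segment_voxels`): a segment's voxels
   are the mask voxels within `max_radius` (default 5 mm) of the
   centerline polyline — the rule that apportions voxels near branch
   points.  **Measurement** (`measure_segment`): V = voxel count × voxel
   volume (1 mm³ ≡ 1 µL), L = smoothed path length, ratio = V/L.
6. **PCA pooling** (`pca_ratio`): the posterior cerebral artery ratio pools
   P1 and P2 (volumes and lengths summed before dividing); for a
   fetal-type PCA with atretic P1, P2 alone is used.

Coordinates are NIfTI-convention: voxel indices 0-based, world = origin +
index × spacing.  Thinning runs on the voxel grid; all lengths use
physical spacing, so anisotropic grids need no resampling.

On noise-free phantoms at 0.25 mm spacing the full chain recovers the
ratio of a 2 mm-radius, 40 mm cylinder to within ±3% across axis
placements (the acceptance check allows 5%), and a 50% diameter narrowing
is recovered as a ratio-of-ratios of 0.25 within 1%.

## Threshold calibration

Per segment class (left/right pooled), observations are (ratio, severe)
pairs where severe means DSA grade 2.  The test direction is fixed:
predicted severe ⇔ ratio strictly below the cutoff.  Candidate cutoffs are
the midpoints of consecutive distinct sorted ratios plus one candidate
below the minimum (half of it) and one above the maximum (twice it) —
multiplicative offsets keep the candidate set scale-equivariant, which is
well-defined because ratios are strictly positive.  The Youden-optimal
cutoff maximizes sensitivity + specificity, computed with an integer
objective (tp·n_neg + tn·n_pos) so ties are exact; among ties the largest
cutoff wins (detection-oriented: it maximizes sensitivity).

The point estimate is the full-sample Youden cutoff.  The confidence
interval is the percentile interval of cutoffs over `n_bootstrap`
(default 2000) stratified replicates: severe and non-severe observations
are resampled with replacement independently, preserving both group sizes,
so no replicate can collapse to one class (a redraw guard is kept
regardless).  Strata are sorted before resampling so results depend only
on the multiset of values and the seed, not input row order; each segment
class draws from its own seed stream derived from the configured seed, so
results are also independent of the order classes appear in a table.

The shipped `reference_thresholds.json` carries the per-class thresholds,
95% CIs and sample counts calibrated on the original single-center
clinical cohort (20 DSA examinations from 10 patients; the M2 frontal
branch used 17 exams from 9 patients, and similar reductions apply where a
segment could not be evaluated in every DSA).  These values cannot be
recomputed without the patients' images; the calibration code is instead
validated by property checks: exact agreement with an exhaustive
exact-arithmetic scan on 1000 random samples, ≥90% empirical coverage of a
known generative cutoff by the 95% CI over 200 simulations at n = 40 per
class, and bit-identical results under identical seeds.  Percentile
bootstrap intervals for Youden cutoffs are known to undercover slightly;
across simulation seeds the empirical coverage of the nominal 95% CI sits
around 0.89-0.93.  An additional
cross-check verifies agreement of the Youden cutoff with the R `pROC`
package on an untied sample.

One property deserves a caveat: when a simulated cohort has all spastic
segments at (1 − d*)² × baseline and healthy segments at baseline, the
calibrated cutoff does *not* sit at (1 − d*)² × median(baseline) — every
Youden-optimal cutoff lies in the gap between the severe cluster's upper
edge and the healthy cluster's lower edge, near their geometric midpoint.
The test suite asserts this separation property (threshold and CI inside
the gap), which is what the generative model actually implies.

## Decision rules

- Per-segment severity on CTA: ratio **strictly below** the class
  threshold; boundary equality is not severe.  Ties are measure-zero for
  continuous ratios; the choice is documented and tested.
- k-segment criterion (k ∈ {1, 2, 3}): at least k measured (class, side)
  slots severe.  Left and right count separately (each measured vessel is
  a segment).  Measurements of a class without a threshold do not
  contribute (warned); unmeasured segments simply do not count.
- CTP hypoperfusion: the seven regions (frontal, temporal, parietal,
  occipital, thalamus, basal ganglia, insula) are graded 0/1 per side (14
  gradeable slots); the flag is positive iff any graded slot is non-zero.
  An exam with no graded region is an error, never silently negative.
- Combined criterion: pathological CTA (k segments) AND the CTP flag.
- Treatment gold standard: endovascular vasospasm treatment within the
  closed interval [0 h, 24 h] after the CTA acquisition
  (`treated_within_24h` helper); cohort files may carry the precomputed
  boolean instead.

## Diagnostic evaluation

`build_contingency` and `metrics` keep sensitivity, specificity, NPV and
PPV as exact fractions; a zero-denominator metric is `None` (flagged, never
0 or 100).  The whole-percent rendering rounds half away from zero to one
decimal and then to a whole percent — the two-stage rule that matches how
such tables are conventionally reported (a value first published to one
decimal, then rounded again).  Against the shipped reference tables this
rendering reproduces 39 of 40 printed cells; the one exception (CTA
≥3-segment sensitivity vs treatment, 13/19 = 68.4% printed as 69%) is a
rounding anomaly on the reporting side and is recorded in
`reference_tables.json` under `rounding_anomalies`.

Examinations are treated as independent observations; repeated exams of
one patient are not clustered, matching the design of the original
analysis.  Exams lacking CTP (or the treatment flag) are errors for the
respective evaluation rather than being silently dropped.

The shipped `reference_cohort_cells.json` is the joint count table over
(severe-segment count category, CTP flag, treated flag) for a synthetic
96-examination cohort that simultaneously realizes all three reference
contingency tables.  The decomposition is unique: the three k-criterion
columns of each table fix the marginal counts of the severity categories
(≥3, exactly 2, exactly 1, 0) against each gold standard, and the
combined-criterion table fixes the three-way cells; all resulting cells
are non-negative integers summing to 96 with 28 CTP-positive and 19
treated.  `synthetic_cohort_from_cells` realizes it deterministically
(severe slots at half the class threshold, all others at twice it; a
positive CTP as a single abnormal insula grade).

## Synthetic data

**Phantom volumes** (`phantom_gen`): tubes along piecewise-linear
centerlines, rasterized by including every voxel whose center lies within
the local radius of the nearest point of a densely resampled centerline
(step ≤ 0.1 × min spacing), with the spherical caps beyond the tube ends
clipped flat so the voxelized volume converges to the analytic piecewise-
cylinder volume (with caps it would converge to analytic + (4/3)πr³ per
tube).  Narrowing multiplies the radius by `narrowing_factor` inside an
arc-length span.  Additive Gaussian noise with configurable SD; tubes
outside the grid are an error naming the tube; overlapping tubes are
permitted and flagged.  The ground truth carries the analytic length,
volume, ratio and the exact voxel mask per tube.

**Cohorts** (`generate_cohort`): per examination, 15 segment slots (one
midline basilar artery, seven sided classes × 2).  Healthy ratios are
log-normal per class; the default medians (BA 8.5, PCA 2.5, ICA 16, M1 9,
M2 frontal 3.5, M2 temporal 5.5, A1 4.5, A2 3.5 µL/mm, log-SD 0.25) sit
roughly at twice the calibrated severity thresholds — plausible unspastic
calibers with the right ordering and scale, not estimates of any clinical
cohort (no distributional facts about healthy segments are published
beyond the thresholds themselves).  A segment is spastic with probability
`spasm_prevalence` (default 0.15); its diameter reduction d is uniform on
`diameter_reduction_range` (default (0.3, 0.7)); the observed ratio is
baseline × (1 − d)² times mean-one multiplicative log-normal noise with
coefficient of variation `measurement_noise_cv` (default 0.05).  The DSA
grade is exactly the clinical rule: 2 iff d > 0.5, 1 iff 0 < d ≤ 0.5,
else 0.  The CTP flag is Bernoulli with probability keyed on the exam's
count of truly severe segments (defaults 0.10/0.35/0.55/0.75 for 0/1/2/3,
0.85 beyond) — severity of true narrowing, not the milder grade-1 spasm,
is what plausibly drives hypoperfusion.  The treatment flag is keyed on
(any-truly-severe-segment, CTP flag) (defaults 0.02/0.30/0.15/0.70 for
−−/−+/+−/++), encoding that treatment decisions weigh perfusion more than
angiographic narrowing alone.  A condition without a configured
probability is an error.  Everything is reproducible from one seed, and
the hidden-truth table shares the consumable CSV schema plus
`true_baseline_ratio`, `true_diameter_reduction`, `true_severe`,
`exam_n_severe`, `exam_ctp_positive` columns.

What the simulator does **not** emulate: bone and soft tissue, contrast
dynamics, beam hardening, within-patient correlation over serial exams,
anatomical variants (beyond the fetal-PCA code path), or region-specific
CTP patterns (the flag is drawn at exam level and painted onto one
region).  Passing tests therefore demonstrate correctness of the
measurement and evaluation machinery under controlled geometry and a
plausible statistical linkage — not clinical performance on patient data.

## Numerical choices and problem sizes

- Candidate cutoffs below-min/above-max use factors 0.5/2.0 (any values
  outside the data range are equivalent; these preserve scale
  equivariance).
- Percentile CIs use `numpy.quantile` linear interpolation.
- Phantom checks run at 0.25 mm spacing on grids of ≲ 0.9 M voxels; the
  coverage simulation uses 200 repeats × 2000 bootstrap replicates at
  n = 40 per class; the Youden oracle check uses 1000 random samples of
  size ≤ 50.  These sizes make the full suite run in well under a minute
  apart from the coverage simulation (~25 s).
- Degenerate inputs: empty windowed mask, unsnappable landmarks,
  disconnected skeleton components, zero-length centerlines, one-class
  calibration samples, ungraded CTP, and all-zero contingency tables are
  all explicit errors, tested as such.

## Known limitations

- Thresholds are not adjusted for age or sex, and serial exams of one
  patient are treated as independent — both match the original analysis
  and widen true uncertainty beyond the reported intervals.
- The skeleton-based length is one defensible reading of "centerline
  length"; other software may measure slightly differently (smoothing
  window and spur pruning are exposed as parameters).
- The shipped clinical thresholds are single-center values; transferring
  them to differently acquired CTA data is not expected to be valid.
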