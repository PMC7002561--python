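# vasovol

Automated, investigator-independent volumetric grading of cerebral
vasospasm from CT angiography (CTA), for researchers and imaging
scientists working on delayed cerebral ischemia surveillance after
subarachnoid hemorrhage.

After aneurysmal subarachnoid hemorrhage, narrowing (vasospasm) of the
large intracranial arteries can silently progress to infarction.
Surveillance combines CTA with CT perfusion (CTP), but conventional CTA
reading is subjective.  `vasovol` replaces the visual read with a number:
for each vessel segment of the circle of Willis (basilar, posterior
cerebral P1+P2, internal carotid, M1, frontal/temporal M2, A1, A2 — left
and right separately), it measures

&nbsp;&nbsp;&nbsp;&nbsp;**ratio = V / L**&nbsp;&nbsp;(µL/mm),

the segment's vessel volume over its centerline length, i.e. its mean
cross-sectional area.  A diameter reduction by a fraction *d* scales the
ratio by (1 − *d*)², so severe spasm (> 50% narrowing, DSA grade 2)
depresses it by more than four-fold.  The package:

- reconstructs the vascular tree from a NIfTI angiographic volume
  (intensity windowing → topology-preserving 3-D thinning → shortest-path
  centerline between landmarks) and measures per-segment V, L and V/L;
- calibrates per-segment severity cutoffs against DSA grades by ROC
  analysis (Youden criterion, "ratio below cutoff = severe") with 95%
  confidence intervals from 2000 stratified bootstrap replicates;
- applies the decision rules: k-of-n segment CTA criteria (k = 1, 2, 3),
  the CTP hypoperfusion flag (any abnormal region grade), and their
  conjunction;
- evaluates each rule against a gold standard (CTP hypoperfusion, or
  endovascular vasospasm treatment within 24 h) as contingency tables
  with exact sensitivity/specificity/NPV/PPV;
- generates ground-truthed synthetic inputs at every level: tubular
  phantoms with known geometry and focal narrowing, and surveillance
  cohorts with known statistical structure.

Reference severity thresholds from the original single-center clinical
calibration cohort ship with the package (e.g. M1: 5.0 µL/mm, 95% CI
[4.6, 8.0]) and are used wherever real calibration data are unavailable.

## Worked example

```python
import numpy as np
from vasovol import (
    PhantomSpec, TubeSpec, generate_phantom_volume, ImageVolume,
    window_segmentation, skeletonize, trace_segment,
    assign_segment_voxels, measure_segment, SegmentId,
    load_reference_thresholds, thresholds_by_class, classify_segment,
)

# a 40 mm vessel of 2 mm radius with a 50% focal narrowing over 15-30 mm
tube = TubeSpec(
    control_points=((6.0, 6.0, 2.0), (6.0, 6.0, 42.0)),
    baseline_radius=2.0, narrowing_factor=0.5, narrowing_span=(15.0, 30.0),
    segment_label="M1",
)
spec = PhantomSpec(grid_shape=(48, 48, 180), spacing=(0.25, 0.25, 0.25), tubes=(tube,))
volume, truth = generate_phantom_volume(spec)

vol = ImageVolume(volume, spec.spacing)
mask = window_segmentation(vol, low=200, high=600, min_component_voxels=50)
skel = skeletonize(mask)
path = trace_segment(skel, (6, 6, 2), (6, 6, 42), vol.spacing)
sub = assign_segment_voxels(mask, path, vol.spacing, max_radius=4.0)
m = measure_segment(sub, path, vol.spacing, SegmentId("M1", "left"))

thresholds = thresholds_by_class(load_reference_thresholds())
print(f"true ratio     {truth.tubes[0].ratio_uL_per_mm:.2f} uL/mm")
print(f"measured ratio {m.ratio:.2f} uL/mm  (volume {m.volume:.0f} uL / length {m.length:.1f} mm)")
print("severe on CTA:", classify_segment(m, thresholds["M1"]))
```

prints

```
true ratio     9.03 uL/mm
measured ratio 8.82 uL/mm  (volume 355 uL / length 40.2 mm)
severe on CTA: False
```

The analytic truth is π·2² µL/mm over the healthy 25 mm and a quarter of
that over the narrowed 15 mm, averaging 9.03 µL/mm; the full
reconstruction chain recovers it within 3%.  The segment is not called
severe because its average ratio stays above the M1 cutoff of 5.0 µL/mm —
a focal spasm must be measured over the narrowed span (or depress the
whole-segment average) to trip the threshold.

The same machinery runs from the shell:

```sh
vasovol simulate --out cohort.csv --truth truth.csv --seed 1
vasovol calibrate --measurements cohort.csv --boot 2000 --seed 1 --out thresholds.json
vasovol evaluate --cohort cohort.csv --thresholds thresholds.json --gold ctp --out report.tsv
```

`report.tsv` mirrors the standard diagnostic-table layout (rows N, FP, FN,
TP, TN, Sensitivity, Specificity, NPV, PPV; one column per k-criterion).
`vasovol phantom` and `vasovol measure` cover the imaging side, and
`vasovol run --config run.json` executes a full synthetic
simulate→calibrate→evaluate pipeline reproducibly from one seed.

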