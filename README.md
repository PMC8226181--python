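# dbsdeform

Quantification of early deep-brain-stimulation (DBS) electrode deformation
from immediate post-implantation CT.

After a DBS lead is implanted and its stylet removed, the lead bends: the
brain shifts (CSF loss and frontal air entry), tissue layers of different
stiffness push back, and the lead's own rigid distal contact block resists.
This package operationalizes the measurement of those deformations for
researchers in stereotactic neurosurgery and brain biomechanics: it
extracts the metal-bright lead from a CT volume, models its trajectory,
computes deformation parameters along the lead and per tissue layer, and
runs the cohort-level statistics — all validated end to end on synthetic
volumes with known ground truth, since no public imaging accompanies the
original cohort.

## Method

For each implanted lead:

1. **Segmentation & centerline.** Voxels above an intensity threshold are
   candidate lead; connected components are filtered by an elongation
   criterion (principal-axis extent ≥ 5 × mean transverse extent) to reject
   skull shells and artifact blobs. The centerline is the slab-wise
   intensity-weighted centroid along the component's principal axis —
   sub-voxel, ordered, branch-free.
2. **Electrode frame.** The proximal point (lead entry through the inner
   skull table) becomes the origin; axes are +x toward the midline
   (hemisphere-mirrored), +y posterior, +z inferior.
3. **Trajectory model.** A third-order polynomial per axis,
   r(t) = c₀ + c₁t + c₂t² + c₃t³ (t = normalized cumulative chord-length),
   fitted by least squares; diagnostics R² (pooled over axes) and RMS
   residual.
4. **Deformation profile.** The fitted curve is resampled at 100 points
   uniform in arc length. At each sample: per-axis deviation from the
   straight chord (matched arc fraction), curvature
   κ = |r′×r″|/|r′|³ and torsion τ = (r′×r″)·r‴/|r′×r″|² (mm⁻¹) from the
   cubic's exact derivatives.
5. **Regionalization.** Samples are labelled subdural / gyration /
   white-matter stem / deep brain by Euclidean distance from the proximal
   point against measured frontier distances; per-layer parameter means are
   the regional values.
6. **Indices.** Lead length (chord), rigid-part percentage (7.5 mm
   non-directional, 21.5 mm directional), extracerebral percentage, brain
   shift index (boxed frontal air-bubble volume / hemisphere volume, in
   10⁻⁴ %), surgical inaccuracy (planned-vs-achieved distance, 0.1 mm
   resolution).
7. **Cohort statistics.** Mixed linear model per parameter (fixed: type ×
   hemisphere × layer; random intercept per patient, REML), pairwise
   contrasts Sidak-corrected within families, ICC = σ²_between/(σ²_between
   + σ²_residual) classed low (< 0.6) / moderate (0.6–0.8) / high (> 0.8),
   and a normality-gated two-sample comparison (Student/Welch t vs
   Mann–Whitney).

The synthetic-data module generates exact-cubic ground-truth trajectories,
rasterizes them into CT-like volumes at the emulated scanner geometry
(0.488 × 0.488 × 0.625 mm voxels, 1.27 mm lead diameter), and samples whole
cohorts with the study design: 30 patients bilateral, left hemisphere
implanted first, two electrode types, left-sided pneumocephalus excess.

## Worked example

```python
from dbsdeform import (make_ground_truth_curve, rasterize_case,
                       threshold_segment, select_electrode_components,
                       skeletonize, to_electrode_frame, fit_cubic,
                       deformation_profile)

curve = make_ground_truth_curve("directional", "left", (0.8, -0.4, 0.2),
                                chord_length=68.0, seed=42)
case = rasterize_case(curve, seed=42)
mask = threshold_segment(case.volume, 2000.0)
comp = select_electrode_components(mask, n_electrodes=1)[0]
skel = to_electrode_frame(skeletonize(comp), case.entry_point["left"], "left")
model = fit_cubic(skel)
print(round(model.r_squared, 6), round(model.rms_residual * 1000, 1))
```

prints `1.0 4.8` — the recovered centerline is a cubic to within ~5 µm RMS,
so measured deviation profiles track the ground truth to hundredths of a
millimetre.  The `examples/` directory has one narrative script per
capability (synthetic cases, extraction, profiles, layers/indices, cohort
statistics); for instance `python examples/04_layers_and_indices.py` prints

```
rigid part:        11.08 % of lead
extracerebral:     6.09 % of lead
```

— the rigid distal 7.5 mm of a 67.7 mm non-directional lead and a 4.12 mm
extracerebral segment, matching the cohort's reported mean percentages.

A thin CLI wraps the same library:

```bash
dbsdeform run --simulate --n 30 --seed 1 --out out/
dbsdeform measure --chord 67.7 --electrode-type directional \
    --cortex-entry 4.12 --hemisphere-volume 474000
```

## Layout

- `src/dbsdeform/` — library (`synthetic`, `extraction`, `geometry`,
  `regional`, `indices`, `stats`, `io`, `pipeline`, `cli`)
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — models, assumptions, parameter choices, limitations
- `docs/data_dictionary.md` — output CSV column definitions
- `tests/` — unit, property and end-to-end validation suites
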