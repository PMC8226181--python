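# Data dictionary

All CSV outputs are comma-separated UTF-8 with dot decimals. Lengths are
mm, curvature/torsion mm⁻¹, brain shift index 10⁻⁴ %, volumes mm³.

## Cohort tables (`cohort_truth.csv`, `cohort_measured.csv`)

One row per (patient, hemisphere, tissue layer).

| column | meaning |
| --- | --- |
| `patient` | patient id (`P000`...) |
| `hemisphere` | `left` / `right` (left is always implanted first) |
| `electrode_type` | `non_directional` (rigid distal 7.5 mm) / `directional` (21.5 mm) |
| `target` | `subthalamus` / `ventrolateral_thalamus` |
| `layer` | `gyration` / `wms` / `deep_brain` (subdural excluded) |
| `x_mm`, `y_mm`, `z_mm` | regional mean per-axis deviation from the chord; +x toward midline, +y posterior, +z inferior |
| `torsion_per_mm` | regional mean torsion over torsion-defined samples (NaN if none) |
| `curvature_per_mm` | regional mean curvature |
| `chord_length_mm` | proximal-to-distal Euclidean lead length |
| `rigid_pct` | 100 × rigid length / chord |
| `extracerebral_pct` | 100 × cortex-entry distance / chord |
| `brain_shift_index` | air-bubble box volume / hemisphere volume × 10⁶ (units 10⁻⁴ %) |
| `surgical_inaccuracy_mm` | planned-vs-achieved distance, 0.1 mm resolution |
| `cortex_entry_mm`, `gyration_wms_mm`, `wms_deep_mm` | frontier distances from the proximal point |
| `hemisphere_volume_mm3` | hemisphere volume |
| `model_r_squared`, `model_rms_mm` | cubic-fit diagnostics (measured table only) |

## Profile table (`profiles.csv`)

One row per profile sample (100 per electrode).

| column | meaning |
| --- | --- |
| `electrode_id` | `<patient>_<hemisphere>` |
| `sample_index` | 0–99 |
| `t` | curve parameter of the sample |
| `arc_mm` | cumulative arc length at the sample |
| `deviation_x_mm`, `deviation_y_mm`, `deviation_z_mm` | per-axis deviation from the chord at matched arc fraction |
| `curvature_per_mm`, `torsion_per_mm` | Frenet-Serret values from the cubic |
| `torsion_defined` | False where curvature < 10⁻⁶ mm⁻¹ (torsion reported 0) |
| `layer` | tissue layer label of the sample |

## Skeleton CSV (`skeleton.csv`)

`t_index, x_mm, y_mm, z_mm, arc_mm` — ordered centerline points
(electrode frame, proximal first) with cumulative arc length.

## Stats report (`stats_report.json`)

Per parameter: `icc`, `icc_class`, variance components, `log_transformed`
flag, declared contrast `families` (name → size), and the contrast list
(`estimate`, `se`, `p_raw`, Sidak-adjusted `p_sidak`, `significant` at the
report's alpha). `run_log.json` records package/numpy versions, seeds,
threshold, voxel size and unit declarations.
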