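"""Cohort-level statistics on a simulated 30-patient bilateral series.

Generates a cohort with the study's design (left hemisphere implanted
first, two electrode types, three tissue layers, patient random
intercepts), injects a 0.3 mm gyration-vs-deep x-deviation difference, and
recovers it with the random-intercept mixed model, Sidak-corrected within
contrast families, plus the ICC classification.
"""

from dbsdeform import CohortSpec, generate_cohort, layer_contrasts, sidak_alpha
from dbsdeform.regional import BRAIN_LAYERS

stats = {}
for etype in ("non_directional", "directional"):
    for hemi in ("left", "right"):
        for layer in BRAIN_LAYERS:
            mean = 0.3 if layer == "gyration" else 0.0
            stats[(etype, hemi, layer)] = {
                "x_mm": (mean, 0.15), "y_mm": (0.0, 0.15), "z_mm": (0.0, 0.15),
                "torsion_per_mm": (0.0, 0.05), "curvature_per_mm": (0.003, 0.001),
            }

spec = CohortSpec(n_patients=30, seed=11, parameter_stats=stats, patient_sd_ratio=0.5)
table, _ = generate_cohort(spec)
print(f"cohort table: {len(table)} rows "
      f"({table['patient'].nunique()} patients x 2 hemispheres x 3 layers)")

report = layer_contrasts(table, "x_mm", alpha=0.05)
print(f"per-test Sidak alpha for a family of 3: {sidak_alpha(0.05, 3):.6f}")
print(f"ICC = {report.icc:.3f} ({report.icc_class}); "
      f"log-transformed: {report.log_transformed}")
for c in report.contrasts:
    flag = "*" if c.significant else " "
    print(f" {flag} {c.description:32s} estimate {c.estimate:+.3f} "
          f"p_sidak {c.p_adjusted:.4f}")
# The gyration-vs-deep contrasts recover the injected 0.3 mm difference;
# the hemisphere contrasts stay null.  ICC ~ 0.2 reflects the patient
# intercept sd being half the residual sd.
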