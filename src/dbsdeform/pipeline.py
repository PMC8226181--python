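"""End-to-end pipeline: simulate/load -> extract -> model -> regionalize -> stats.

``run_pipeline`` composes every stage on a simulated cohort (or a single
supplied volume) and writes the cohort CSV, tidy per-electrode profile CSV,
a JSON statistics report and a JSON log of seeds, thresholds and versions.
Outputs are deterministic given the seeds; every row carries the case id it
came from, and any stage failure is re-raised tagged with its stage and
case id.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import DbsDeformError, InvalidArgumentError, PipelineStageError
from .extraction import (
    DEFAULT_THRESHOLD,
    select_electrode_components,
    skeletonize,
    threshold_segment,
    to_electrode_frame,
)
from .geometry import deformation_profile, fit_cubic, frenet_profile
from .indices import (
    brain_shift_index,
    electrode_length,
    extracerebral_fraction,
    rigid_fraction,
    surgical_inaccuracy,
)
from .io import profile_frame, read_volume, write_table_csv
from .regional import assign_layers, orient_signs, regional_summary
from .stats import DEFAULT_ALPHA, group_compare, layer_contrasts
from .synthetic import (
    DEFAULT_ELECTRODE_RADIUS,
    SCANNER_VOXEL_SIZE,
    PARAMS,
    CohortSpec,
    SyntheticCase,
    generate_cohort,
)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected.

    Units: lengths mm, curvature/torsion mm^-1, brain shift index 1e-4 %.
    """

    out_dir: str = "dbsdeform_out"
    simulate: bool = True
    n_patients: int = 4
    seed: int = 0
    voxel_size: tuple = SCANNER_VOXEL_SIZE
    electrode_radius: float = DEFAULT_ELECTRODE_RADIUS
    threshold: float = DEFAULT_THRESHOLD
    alpha: float = DEFAULT_ALPHA
    volume_path: str | None = None
    run_stats: bool = True
    units: dict = field(default_factory=lambda: {
        "lengths": "mm", "curvature": "mm^-1", "torsion": "mm^-1",
        "brain_shift_index": "1e-4 %",
    })

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    def __post_init__(self):
        if self.n_patients < 0:
            raise InvalidArgumentError("n_patients must be >= 0")
        if not 0 < self.alpha < 1:
            raise InvalidArgumentError("alpha must be in (0, 1)")


def analyze_case(
    case: SyntheticCase,
    patient: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[list[dict], list[pd.DataFrame]]:
    """Measure one rasterized case: both electrodes through the full chain.

    Returns cohort-table rows (one per hemisphere and brain layer) and tidy
    per-electrode profile frames.
    """
    if case.volume is None:
        raise InvalidArgumentError(f"case {patient} carries no volume")
    mask = threshold_segment(case.volume, threshold)
    hemis = sorted(case.truth)
    comps = select_electrode_components(mask, n_electrodes=len(hemis))

    # match each component to its hemisphere by proximity to the entry point
    assignments = {}
    for comp in comps:
        idx = np.argwhere(comp.mask)
        coords = idx @ comp.affine[:3, :3].T + comp.affine[:3, 3]
        dists = {h: float(np.min(np.linalg.norm(coords - case.entry_point[h], axis=1)))
                 for h in hemis}
        assignments[min(dists, key=dists.get)] = comp
    if set(assignments) != set(hemis):
        raise InvalidArgumentError("could not match one component per hemisphere")

    rows, profiles = [], []
    for hemi in hemis:
        curve = case.truth[hemi]
        skel = skeletonize(assignments[hemi])
        skel_e = to_electrode_frame(skel, case.entry_point[hemi], hemi)
        model = fit_cubic(skel_e)
        profile = frenet_profile(model, deformation_profile(model))
        labels = assign_layers(profile, case.frontiers[hemi])
        summaries = [orient_signs(s, hemi) for s in regional_summary(profile, labels, hemi)]

        length = electrode_length(skel_e)
        rigid = rigid_fraction(length, curve.electrode_type)
        extracer = extracerebral_fraction(case.frontiers[hemi].cortex_entry, length)
        bsi = brain_shift_index(case.bubble[hemi], case.hemisphere_volume[hemi])
        inacc = surgical_inaccuracy(case.planned_point[hemi], case.contact_point[hemi])

        electrode_id = f"{patient}_{hemi}"
        profiles.append(profile_frame(profile, electrode_id, labels))
        for s in summaries:
            rows.append({
                "patient": patient, "hemisphere": hemi,
                "electrode_type": curve.electrode_type, "target": case.target,
                "layer": s.layer, "x_mm": s.x_mm, "y_mm": s.y_mm, "z_mm": s.z_mm,
                "torsion_per_mm": s.torsion_per_mm,
                "curvature_per_mm": s.curvature_per_mm,
                "chord_length_mm": length, "rigid_pct": rigid,
                "extracerebral_pct": extracer, "brain_shift_index": bsi,
                "surgical_inaccuracy_mm": inacc,
                "cortex_entry_mm": case.frontiers[hemi].cortex_entry,
                "gyration_wms_mm": case.frontiers[hemi].gyration_wms,
                "wms_deep_mm": case.frontiers[hemi].wms_deep,
                "hemisphere_volume_mm3": case.hemisphere_volume[hemi],
                "model_r_squared": model.r_squared,
                "model_rms_mm": model.rms_residual,
            })
    return rows, profiles


def _stats_report(cohort: pd.DataFrame, alpha: float) -> dict:
    report = {"alpha": alpha, "parameters": {}}
    for param in PARAMS:
        try:
            rep = layer_contrasts(cohort, param, alpha=alpha)
            report["parameters"][param] = {
                "icc": rep.icc,
                "icc_class": rep.icc_class,
                "between_patient_var": rep.components.between_patient_var,
                "residual_var": rep.components.residual_var,
                "log_transformed": rep.log_transformed,
                "families": rep.metadata["families"],
                "contrasts": [
                    {
                        "family": c.family, "contrast": c.description,
                        "estimate": c.estimate, "units": c.units, "se": c.se,
                        "p_raw": c.p_raw, "p_sidak": c.p_adjusted,
                        "significant": c.significant,
                    }
                    for c in rep.contrasts
                ],
            }
        except DbsDeformError as exc:
            report["parameters"][param] = {"error": str(exc)}
    # between-type comparison of per-electrode mean x deformation
    per_lead = cohort.groupby(["patient", "hemisphere", "electrode_type"],
                              observed=True)["x_mm"].mean().reset_index()
    groups = {t: g["x_mm"].to_numpy() for t, g in per_lead.groupby("electrode_type",
                                                                   observed=True)}
    if len(groups) == 2 and all(len(v) >= 3 for v in groups.values()):
        a, b = groups.values()
        cmp = group_compare(a, b, alpha=alpha)
        report["type_comparison_x"] = {
            "test": cmp.test_name, "statistic": cmp.statistic, "p": cmp.p_value,
        }
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis per the configuration; returns output paths.

    In simulate mode a cohort of ``n_patients`` bilateral cases is
    generated, rasterized and measured end-to-end.  In file mode the
    configured volume is loaded instead (metadata must accompany it).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        spec = CohortSpec(n_patients=config.n_patients, seed=config.seed)
        try:
            truth_table, cases = generate_cohort(
                spec, include_volumes=True, voxel_size=config.voxel_size,
                electrode_radius=config.electrode_radius,
            )
        except DbsDeformError as exc:
            raise PipelineStageError("simulate", "cohort", exc) from exc
        case_items = [(f"P{i:03d}", c) for i, c in enumerate(cases)]
        write_table_csv(truth_table, out / "cohort_truth.csv")
    else:
        if config.volume_path is None or not Path(config.volume_path).exists():
            raise PipelineStageError(
                "read_volume", str(config.volume_path),
                FileNotFoundError(f"volume not found: {config.volume_path}"),
            )
        read_volume(config.volume_path)
        raise PipelineStageError(
            "measure", str(config.volume_path),
            InvalidArgumentError(
                "file mode needs per-case metadata; use the extract/measure "
                "commands for single volumes"
            ),
        )

    rows, profiles = [], []
    for patient, case in case_items:
        try:
            r, p = analyze_case(case, patient, threshold=config.threshold)
        except DbsDeformError as exc:
            raise PipelineStageError("measure", patient, exc) from exc
        rows.extend(r)
        profiles.extend(p)

    cohort = pd.DataFrame(rows)
    paths = {
        "cohort": str(write_table_csv(cohort, out / "cohort_measured.csv")),
    }
    if profiles:
        prof = pd.concat(profiles, ignore_index=True)
        paths["profiles"] = str(write_table_csv(prof, out / "profiles.csv"))

    if config.run_stats and cohort["patient"].nunique() >= 3:
        try:
            report = _stats_report(cohort, config.alpha)
        except DbsDeformError as exc:
            raise PipelineStageError("stats", "cohort", exc) from exc
        stats_path = out / "stats_report.json"
        stats_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        paths["stats"] = str(stats_path)

    log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "threshold": config.threshold,
        "voxel_size_mm": list(config.voxel_size),
        "electrode_radius_mm": config.electrode_radius,
        "n_patients": config.n_patients,
        "units": config.units,
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    paths["log"] = str(log_path)
    return paths
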