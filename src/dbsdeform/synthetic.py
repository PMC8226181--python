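"""Synthetic ground truth: electrode curves, CT-like volumes, cohorts.

No imaging data accompanies the study this package operationalizes, so every
downstream stage is validated against synthetic cases with known ground
truth.  The generator emulates the study's imaging geometry (0.488 x 0.488
mm pixels, 0.625 mm slices), lead caliber (1.27 mm diameter, rigid distal
7.5 or 21.5 mm), deformation magnitudes of the reported per-type /
per-hemisphere means, and the cohort design: 30 patients implanted
bilaterally, first electrode always in the left hemisphere, two electrode
types, three tissue layers, and a left-hemisphere (first-implanted) excess
of pneumocephalus.

Ground-truth trajectories are exact cubics so the downstream cubic
regression is identifiable and fitting error can be separated from modeling
error; an optional quartic perturbation exists to exercise the fit
diagnostics.  Volumes use an arbitrary CT-like intensity scale: air -1000,
tissue 40, bone 1200 (a shell at the grid boundary), electrode 3000, with a
narrow linear partial-volume skirt at the lead edge; this reproduces a
thresholdable metal-bright lead without modelling CT physics.  A single
global seed expands to per-patient and per-case seeds through
``numpy.random.SeedSequence`` spawning, so cohorts are bit-reproducible.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InvalidArgumentError
from .extraction import DEFAULT_THRESHOLD, VoxelVolume, electrode_frame_matrix
from .geometry import CubicCurveModel, poly_eval
from .indices import (
    AirBubble,
    RIGID_LENGTHS,
    brain_shift_index,
    extracerebral_fraction,
    rigid_fraction,
)
from .regional import BRAIN_LAYERS, TissueFrontiers

# --------------------------------------------------------------------------
# study-geometry constants
# --------------------------------------------------------------------------

#: scanner voxel size of the emulated acquisition (mm)
SCANNER_VOXEL_SIZE = (0.488, 0.488, 0.625)

#: lead radius: 1.27 mm diameter / 2
DEFAULT_ELECTRODE_RADIUS = 0.635

#: intensity classes (arbitrary CT-like scale)
INTENSITY = {"air": -1000.0, "tissue": 40.0, "bone": 1200.0, "electrode": 3000.0}

#: label codes for the class volume
LABEL = {"air": 0, "tissue": 1, "bone": 2, "electrode": 3, "artifact": 4}

#: default proximal entry points, scanner LPS mm
DEFAULT_ENTRY_POINTS = {"left": (28.0, 0.0, 0.0), "right": (-28.0, 0.0, 0.0)}

#: regional deformation parameter names (cohort-table columns)
PARAMS = ("x_mm", "y_mm", "z_mm", "torsion_per_mm", "curvature_per_mm")

#: per-(type, hemisphere) deformation means and sds: the study conditions
DEFORMATION_STATS = {
    ("non_directional", "right"): {
        "x_mm": (0.18, 0.20), "y_mm": (0.06, 0.20), "z_mm": (-0.14, 0.12),
        "torsion_per_mm": (0.015, 0.056), "curvature_per_mm": (0.0029, 0.0012),
    },
    ("non_directional", "left"): {
        "x_mm": (0.14, 0.23), "y_mm": (0.12, 0.43), "z_mm": (-0.09, 0.22),
        "torsion_per_mm": (-0.016, 0.076), "curvature_per_mm": (0.0036, 0.0027),
    },
    ("directional", "right"): {
        "x_mm": (0.12, 0.16), "y_mm": (0.33, 0.25), "z_mm": (0.07, 0.17),
        "torsion_per_mm": (-0.007, 0.044), "curvature_per_mm": (0.0025, 0.001),
    },
    ("directional", "left"): {
        "x_mm": (-0.13, 0.13), "y_mm": (0.04, 0.23), "z_mm": (0.06, 0.12),
        "torsion_per_mm": (0.025, 0.044), "curvature_per_mm": (0.0022, 0.007),
    },
}

#: frontal air bubble mean dimensions (mm): thickness, width, height
BUBBLE_MEAN_DIMS = {"left": (1.54, 1.91, 3.20), "right": (0.51, 1.28, 1.63)}

#: hemisphere volume mean/sd (cm^3)
HEMISPHERE_VOLUME_CM3 = {"right": (480.5, 53.0), "left": (474.0, 55.0)}

#: lead chord length mean/sd and clip range (mm)
CHORD_STATS = (67.7, 3.6, 58.0, 77.0)

#: surgical inaccuracy mean/sd by hemisphere (mm)
SURGICAL_INACCURACY_STATS = {"right": (1.03, 0.5), "left": (1.28, 0.5)}

COHORT_COLUMNS = [
    "patient", "hemisphere", "electrode_type", "target", "layer",
    "x_mm", "y_mm", "z_mm", "torsion_per_mm", "curvature_per_mm",
    "chord_length_mm", "rigid_pct", "extracerebral_pct",
    "brain_shift_index", "surgical_inaccuracy_mm",
    "cortex_entry_mm", "gyration_wms_mm", "wms_deep_mm",
    "hemisphere_volume_mm3",
]


# --------------------------------------------------------------------------
# ground-truth curves
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthCurve:
    """Exact per-axis cubic over t in [0, 1], proximal point at the origin.

    ``coeffs`` is (4, 3) in the electrode frame (mm); the curve runs from
    (0, 0, 0) to (0, 0, chord_length).  ``quartic`` optionally holds a
    small (3,) quartic-term vector used to make the truth deliberately
    non-cubic when testing fit diagnostics.
    """

    coeffs: np.ndarray
    chord_length: float
    hemisphere: str
    electrode_type: str
    rigid_length: float
    quartic: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))
        if self.coeffs.shape != (4, 3):
            raise InvalidArgumentError("curve coeffs must be (4, 3)")
        if not self.chord_length > 0:
            raise InvalidArgumentError("chord_length must be positive")
        if self.hemisphere not in ("left", "right"):
            raise InvalidArgumentError(f"unknown hemisphere {self.hemisphere!r}")
        if self.electrode_type not in RIGID_LENGTHS:
            raise InvalidArgumentError(f"unknown electrode type {self.electrode_type!r}")
        if abs(self.rigid_length - RIGID_LENGTHS[self.electrode_type]) > 1e-9:
            raise InvalidArgumentError(
                f"rigid_length {self.rigid_length} does not match electrode type "
                f"{self.electrode_type}"
            )

    def position(self, t):
        p = poly_eval(self.coeffs, np.asarray(t, dtype=float))
        if self.quartic is not None:
            tt = np.asarray(t, dtype=float)[..., None]
            p = p + self.quartic * (tt**2) * ((1.0 - tt) ** 2)
        return p

    def as_model(self) -> CubicCurveModel:
        """View the exact cubic as a fitted-model object (r^2 = 1, RMS 0)."""
        model = CubicCurveModel(
            coeffs=self.coeffs, r_squared=1.0, rms_residual=0.0, source_arc_length=0.0
        )
        return CubicCurveModel(
            coeffs=self.coeffs,
            r_squared=1.0,
            rms_residual=0.0,
            source_arc_length=model.arc_length(),
        )


def _shape_cubic(gamma: float) -> np.ndarray:
    """Coefficients of b(t) = t (1-t) (1 + gamma (t - 1/2)): zero at 0 and 1."""
    return np.array([0.0, 1.0 - gamma / 2.0, 1.5 * gamma - 1.0, -gamma])


def _cubic_max_abs(coeffs: np.ndarray) -> float:
    """Exact max |cubic| on [0, 1] via the closed-form critical points."""
    a1, a2, a3 = coeffs[1], coeffs[2], coeffs[3]
    candidates = [0.0, 1.0]
    # derivative a1 + 2 a2 t + 3 a3 t^2
    if abs(a3) > 1e-300:
        disc = 4.0 * a2**2 - 12.0 * a3 * a1
        if disc >= 0:
            root = np.sqrt(disc)
            for r in ((-2.0 * a2 + root) / (6.0 * a3), (-2.0 * a2 - root) / (6.0 * a3)):
                if 0.0 < r < 1.0:
                    candidates.append(r)
    elif abs(a2) > 1e-300:
        r = -a1 / (2.0 * a2)
        if 0.0 < r < 1.0:
            candidates.append(r)
    vals = [abs(coeffs[0] + t * (a1 + t * (a2 + t * a3))) for t in candidates]
    return max(vals)


def make_ground_truth_curve(
    electrode_type: str,
    hemisphere: str,
    deviation_amplitudes,
    chord_length: float,
    seed: int = 0,
    asymmetry: float = 0.8,
    quartic_amplitude: float = 0.0,
) -> GroundTruthCurve:
    """Random cubic lead trajectory with exact per-axis deviation amplitudes.

    Each axis gets a bump ``amp * b(t) / max|b|`` with
    ``b(t) = t(1-t)(1 + gamma(t - 1/2))`` and a seed-drawn asymmetry
    ``gamma``; the z axis adds the straight run ``chord_length * t``.  The
    per-axis maximum deviation from the straight chord (parametrized by the
    same t) therefore equals ``|amp|`` exactly; amplitudes may be signed to
    set the bending direction.  ``quartic_amplitude`` adds a non-cubic
    perturbation ``q t^2 (1-t)^2`` for diagnostics testing.
    """
    if electrode_type not in RIGID_LENGTHS:
        raise InvalidArgumentError(f"unknown electrode type {electrode_type!r}")
    amps = np.asarray(deviation_amplitudes, dtype=float)
    if amps.shape != (3,):
        raise InvalidArgumentError("deviation_amplitudes must be a length-3 triplet")
    if not np.all(np.isfinite(amps)):
        raise InvalidArgumentError("deviation amplitudes must be finite")
    if not (np.isfinite(chord_length) and chord_length > 0):
        raise InvalidArgumentError(f"chord_length must be positive, got {chord_length}")

    rng = np.random.default_rng(seed)
    coeffs = np.zeros((4, 3))
    for axis in range(3):
        gamma = float(rng.uniform(-asymmetry, asymmetry))
        if amps[axis] != 0.0:
            shape = _shape_cubic(gamma)
            coeffs[:, axis] = amps[axis] / _cubic_max_abs(shape) * shape
    coeffs[1, 2] += chord_length

    quartic = None
    if quartic_amplitude != 0.0:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        quartic = quartic_amplitude * direction

    curve = GroundTruthCurve(
        coeffs=coeffs,
        chord_length=float(chord_length),
        hemisphere=hemisphere,
        electrode_type=electrode_type,
        rigid_length=RIGID_LENGTHS[electrode_type],
        quartic=quartic,
    )
    # regularity: the parametrization speed must never vanish
    t = np.linspace(0.0, 1.0, 501)
    speed = np.linalg.norm(poly_eval(coeffs, t, order=1), axis=-1)
    if np.any(speed <= 1e-9):
        raise InvalidArgumentError(
            "requested amplitudes produce an irregular curve (vanishing speed)"
        )
    return curve


# --------------------------------------------------------------------------
# case metadata and rasterization
# --------------------------------------------------------------------------

@dataclass
class SyntheticCase:
    """One synthetic patient: volume, per-hemisphere truths and metadata.

    ``volume``/``class_labels`` are None when the case was generated without
    rasterization.  All lengths mm, volumes mm^3.
    """

    truth: dict[str, GroundTruthCurve]
    frontiers: dict[str, TissueFrontiers]
    bubble: dict[str, AirBubble]
    hemisphere_volume: dict[str, float]
    planned_point: dict[str, np.ndarray]
    contact_point: dict[str, np.ndarray]
    entry_point: dict[str, np.ndarray]
    surgical_inaccuracy_mm: dict[str, float]
    seed: int
    target: str = "subthalamus"
    volume: VoxelVolume | None = None
    class_labels: np.ndarray | None = None
    electrode_voxels: dict[str, int] = field(default_factory=dict)


def _truth_scanner_samples(curve: GroundTruthCurve, entry: np.ndarray, spacing: float = 0.1):
    """Dense scanner-frame samples of the true curve (for distance queries)."""
    m = electrode_frame_matrix(curve.hemisphere)
    arc_est = curve.as_model().arc_length()
    n = max(int(np.ceil(arc_est / spacing)) + 1, 51)
    t = np.linspace(0.0, 1.0, n)
    return curve.position(t) @ m.T + entry


def _sample_frontiers(rng: np.random.Generator, chord: float) -> TissueFrontiers:
    ce = float(np.clip(rng.normal(4.12, 0.8), 1.5, 8.0))
    gw = float(np.clip(rng.normal(25.3, 3.4), ce + 5.0, chord - 20.0))
    wd = float(np.clip(rng.normal(40.6, 3.5), gw + 5.0, chord - 8.0))
    return TissueFrontiers(ce, gw, wd, chord)


def _sample_bubble(rng: np.random.Generator, hemisphere: str) -> AirBubble:
    # half-normal per dimension, scaled so the mean matches the study value
    t, w, h = BUBBLE_MEAN_DIMS[hemisphere]
    scale = np.sqrt(np.pi / 2.0)
    return AirBubble(
        thickness=float(abs(rng.normal(0.0, t * scale))),
        width=float(abs(rng.normal(0.0, w * scale))),
        height=float(abs(rng.normal(0.0, h * scale))),
    )


def _sample_hemisphere_volume(rng: np.random.Generator, hemisphere: str) -> float:
    mean, sd = HEMISPHERE_VOLUME_CM3[hemisphere]
    return float(np.clip(rng.normal(mean, sd), 300.0, 700.0)) * 1e3


def rasterize_case(
    truth,
    voxel_size=SCANNER_VOXEL_SIZE,
    electrode_radius: float = DEFAULT_ELECTRODE_RADIUS,
    artifact_level: int = 0,
    seed: int = 0,
    margin_mm: float = 4.0,
    entry_points: Mapping[str, Sequence[float]] | None = None,
    bounds: tuple | None = None,
    metadata: SyntheticCase | None = None,
) -> SyntheticCase:
    """Rasterize one or two ground-truth curves into a CT-like volume.

    The grid is sized to the curves plus ``margin_mm``, wrapped in a
    two-voxel bone shell and a one-voxel air rim; pass ``bounds = (origin,
    shape)`` to fix the grid instead, in which case a curve leaving the
    interior raises an out-of-bounds error naming the offending parameter.
    Voxel intensity follows a linear partial-volume skirt of half-width a
    quarter of the largest voxel dimension around the lead radius; the
    electrode voxel class is intensity >= the default segmentation
    threshold.  ``artifact_level`` adds that many small (< 30 voxel) metal-
    bright blobs away from the leads.  Per-case anatomy metadata is sampled
    from the study distributions unless supplied.
    """
    curves = list(truth) if isinstance(truth, (list, tuple)) else [truth]
    voxel = np.asarray(voxel_size, dtype=float)
    if voxel.shape != (3,) or not np.all(voxel > 0):
        raise InvalidArgumentError("voxel_size must be a positive mm triplet")
    if electrode_radius < voxel.max() / 4.0:
        raise InvalidArgumentError(
            f"electrode radius {electrode_radius} mm must be at least a quarter of "
            f"the largest voxel dimension {voxel.max()} mm"
        )
    hemis = [c.hemisphere for c in curves]
    if len(set(hemis)) != len(hemis):
        raise InvalidArgumentError("at most one curve per hemisphere")

    entries = dict(DEFAULT_ENTRY_POINTS)
    if entry_points:
        entries.update({k: tuple(v) for k, v in entry_points.items()})
    entry = {h: np.asarray(entries[h], dtype=float) for h in hemis}

    rng = np.random.default_rng(seed)
    samples = {c.hemisphere: _truth_scanner_samples(c, entry[c.hemisphere]) for c in curves}
    all_pts = np.vstack(list(samples.values()))
    skirt = 0.25 * voxel.max()
    pad = electrode_radius + skirt + margin_mm

    n_shell = 3  # 1 voxel air rim + 2 voxel bone shell
    if bounds is None:
        lo = all_pts.min(axis=0) - pad - n_shell * voxel
        hi = all_pts.max(axis=0) + pad + n_shell * voxel
        origin = lo
        shape = np.ceil((hi - lo) / voxel).astype(int) + 1
    else:
        origin = np.asarray(bounds[0], dtype=float)
        shape = np.asarray(bounds[1], dtype=int)
        interior_lo = origin + n_shell * voxel + electrode_radius
        interior_hi = origin + (shape - 1 - n_shell) * voxel - electrode_radius
        for c in curves:
            pts = samples[c.hemisphere]
            bad = np.any((pts < interior_lo) | (pts > interior_hi), axis=1)
            if bad.any():
                t_bad = np.linspace(0.0, 1.0, pts.shape[0])[bad][0]
                raise InvalidArgumentError(
                    f"curve ({c.hemisphere}) exits the grid interior at t = {t_bad:.3f}"
                )

    affine = np.eye(4)
    affine[:3, :3] = np.diag(voxel)
    affine[:3, 3] = origin

    data = np.full(tuple(shape), INTENSITY["tissue"], dtype=np.float32)
    labels = np.full(tuple(shape), LABEL["tissue"], dtype=np.uint8)
    for axis in range(3):
        for face_idx, layer in ((0, "air"), (1, "bone"), (2, "bone")):
            sl = [slice(None)] * 3
            sl[axis] = face_idx
            data[tuple(sl)] = INTENSITY[layer]
            labels[tuple(sl)] = LABEL[layer]
            sl[axis] = shape[axis] - 1 - face_idx
            data[tuple(sl)] = INTENSITY[layer]
            labels[tuple(sl)] = LABEL[layer]

    electrode_voxels = {}
    trees = {}
    for c in curves:
        pts = samples[c.hemisphere]
        tree = cKDTree(pts)
        trees[c.hemisphere] = tree
        lo_idx = np.maximum(
            np.floor((pts.min(axis=0) - electrode_radius - skirt - origin) / voxel).astype(int),
            0,
        )
        hi_idx = np.minimum(
            np.ceil((pts.max(axis=0) + electrode_radius + skirt - origin) / voxel).astype(int),
            shape - 1,
        )
        grids = np.meshgrid(
            *[np.arange(lo_idx[a], hi_idx[a] + 1) for a in range(3)], indexing="ij"
        )
        idx = np.stack([g.ravel() for g in grids], axis=1)
        centers = idx * voxel + origin
        d, _ = tree.query(centers)
        coverage = np.clip(0.5 + (electrode_radius - d) / (2.0 * skirt), 0.0, 1.0)
        hit = coverage > 0
        flat_idx = tuple(idx[hit].T)
        tissue_like = labels[flat_idx] == LABEL["tissue"]
        vals = (INTENSITY["tissue"]
                + (INTENSITY["electrode"] - INTENSITY["tissue"]) * coverage[hit])
        sel = tuple(np.asarray(a)[tissue_like] for a in flat_idx)
        data[sel] = np.maximum(data[sel], vals[tissue_like].astype(np.float32))
        is_elec = data[sel] >= DEFAULT_THRESHOLD
        lab = labels[sel]
        lab[is_elec] = LABEL["electrode"]
        labels[sel] = lab
        electrode_voxels[c.hemisphere] = int(np.count_nonzero(is_elec))

    # artifact blobs: metal-bright specks well away from the leads
    for _ in range(int(artifact_level)):
        for _attempt in range(200):
            center = origin + (n_shell + 2) * voxel + rng.random(3) * (
                (shape - 2 * (n_shell + 2)) * voxel
            )
            if min(float(t.query(center)[0]) for t in trees.values()) > 5.0:
                break
        radius = rng.uniform(0.5, 0.9)
        lo_idx = np.maximum(np.floor((center - radius - origin) / voxel).astype(int), 0)
        hi_idx = np.minimum(np.ceil((center + radius - origin) / voxel).astype(int), shape - 1)
        grids = np.meshgrid(
            *[np.arange(lo_idx[a], hi_idx[a] + 1) for a in range(3)], indexing="ij"
        )
        idx = np.stack([g.ravel() for g in grids], axis=1)
        centers = idx * voxel + origin
        inside = np.linalg.norm(centers - center, axis=1) <= radius
        sel = tuple(idx[inside].T)
        ok = labels[sel] == LABEL["tissue"]
        sel = tuple(np.asarray(a)[ok] for a in sel)
        data[sel] = INTENSITY["electrode"]
        labels[sel] = LABEL["artifact"]

    volume = VoxelVolume(data=data, affine=affine)

    if metadata is None:
        frontiers, bubble, hemi_vol = {}, {}, {}
        planned, contact, inacc = {}, {}, {}
        for c in curves:
            h = c.hemisphere
            frontiers[h] = _sample_frontiers(rng, c.chord_length)
            bubble[h] = _sample_bubble(rng, h)
            hemi_vol[h] = _sample_hemisphere_volume(rng, h)
            m = electrode_frame_matrix(h)
            tip = c.position(1.0) @ m.T + entry[h]
            contact[h] = tip
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            dist_mean, dist_sd = SURGICAL_INACCURACY_STATS[h]
            dist = float(np.clip(rng.normal(dist_mean, dist_sd), 0.0, 3.0))
            planned[h] = tip + dist * direction
            inacc[h] = dist
        case = SyntheticCase(
            truth={c.hemisphere: c for c in curves},
            frontiers=frontiers,
            bubble=bubble,
            hemisphere_volume=hemi_vol,
            planned_point=planned,
            contact_point=contact,
            entry_point=entry,
            surgical_inaccuracy_mm=inacc,
            seed=int(seed),
        )
    else:
        case = metadata
        case.entry_point = entry

    case.volume = volume
    case.class_labels = labels
    case.electrode_voxels = electrode_voxels
    return case


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Statistical design of a synthetic cohort.

    ``type_allocation`` is either the fraction of non-directional patients
    (allocated first, as in the study) or an explicit per-patient list.
    ``layer_offsets`` maps parameter name -> {layer: additive offset},
    enabling injected between-layer contrasts; the per-(type, hemisphere)
    baselines default to the study's reported means/sds, whose sd is
    treated as the residual sd.  The patient random intercept sd is
    ``patient_sd_ratio`` times the residual sd.
    """

    n_patients: int = 30
    type_allocation: float | Sequence[str] = 0.5
    parameter_stats: Mapping | None = None
    layer_offsets: Mapping[str, Mapping[str, float]] | None = None
    patient_sd_ratio: float = 0.5
    measurement_noise_sd: float = 0.0
    subthalamus_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0:
            raise InvalidArgumentError("n_patients must be >= 0")
        if isinstance(self.type_allocation, (int, float)):
            if not 0.0 <= float(self.type_allocation) <= 1.0:
                raise InvalidArgumentError("type allocation fraction must be in [0, 1]")
        elif len(self.type_allocation) != self.n_patients:
            raise InvalidArgumentError("explicit type allocation must list every patient")
        if self.patient_sd_ratio < 0 or self.measurement_noise_sd < 0:
            raise InvalidArgumentError("sd parameters must be >= 0")
        if self.parameter_stats is not None:
            for cell in self.parameter_stats.values():
                for _, sd in cell.values():
                    if sd < 0:
                        raise InvalidArgumentError("all sds must be >= 0")

    def stats_for(self, etype: str, hemisphere: str, layer: str, param: str):
        """(mean, sd) of a regional parameter in one design cell."""
        if self.parameter_stats is not None:
            cell = self.parameter_stats[(etype, hemisphere, layer)]
            return cell[param]
        mean, sd = DEFORMATION_STATS[(etype, hemisphere)][param]
        if self.layer_offsets and param in self.layer_offsets:
            mean = mean + self.layer_offsets[param].get(layer, 0.0)
        return mean, sd

    def patient_types(self) -> list[str]:
        if not isinstance(self.type_allocation, (int, float)):
            return list(self.type_allocation)
        n_nd = int(round(float(self.type_allocation) * self.n_patients))
        return ["non_directional"] * n_nd + ["directional"] * (self.n_patients - n_nd)


def generate_cohort(
    spec: CohortSpec,
    include_volumes: bool = False,
    voxel_size=SCANNER_VOXEL_SIZE,
    electrode_radius: float = DEFAULT_ELECTRODE_RADIUS,
) -> tuple[pd.DataFrame, list[SyntheticCase]]:
    """Sample a full cohort: ground-truth table plus per-patient cases.

    The table has one row per (patient, hemisphere, layer): the regional
    deformation parameters follow the per-cell normal laws plus a
    patient-level random intercept (sd = ratio x residual sd), with
    optional extra measurement noise.  The first electrode is always the
    left hemisphere.  Cases carry ground-truth curves whose per-axis
    amplitudes are the patient's sampled deviation means; volumes are
    rasterized only on request (they dominate the cost).
    """
    root = np.random.SeedSequence(spec.seed)
    rows: list[dict] = []
    cases: list[SyntheticCase] = []
    types = spec.patient_types()

    for i, child in enumerate(root.spawn(spec.n_patients)):
        rng = np.random.default_rng(child)
        etype = types[i]
        patient = f"P{i:03d}"
        target = ("subthalamus" if rng.random() < spec.subthalamus_fraction
                  else "ventrolateral_thalamus")

        intercept = {}
        for param in PARAMS:
            sds = [spec.stats_for(etype, h, l, param)[1]
                   for h in ("left", "right") for l in BRAIN_LAYERS]
            intercept[param] = rng.normal(0.0, spec.patient_sd_ratio * float(np.mean(sds)))

        truth, frontiers, bubble, hemi_vol = {}, {}, {}, {}
        planned, contact, inacc = {}, {}, {}
        entry = {h: np.asarray(DEFAULT_ENTRY_POINTS[h]) for h in ("left", "right")}
        for hemi in ("left", "right"):  # left implanted first
            mean_c, sd_c, lo_c, hi_c = CHORD_STATS
            chord = float(np.clip(rng.normal(mean_c, sd_c), lo_c, hi_c))
            layer_vals = {}
            for layer in BRAIN_LAYERS:
                vals = {}
                for param in PARAMS:
                    mean, sd = spec.stats_for(etype, hemi, layer, param)
                    v = (mean + intercept[param] + rng.normal(0.0, sd)
                         + (rng.normal(0.0, spec.measurement_noise_sd)
                            if spec.measurement_noise_sd else 0.0))
                    if param == "curvature_per_mm":
                        v = max(v, 1e-5)  # curvature is nonnegative
                    vals[param] = v
                layer_vals[layer] = vals

            fr = _sample_frontiers(rng, chord)
            bu = _sample_bubble(rng, hemi)
            hv = _sample_hemisphere_volume(rng, hemi)
            dist_mean, dist_sd = SURGICAL_INACCURACY_STATS[hemi]
            dist = float(np.clip(rng.normal(dist_mean, dist_sd), 0.0, 3.0))
            dist = float(np.floor(dist / 0.1 + 0.5) * 0.1)
            bsi = brain_shift_index(bu, hv)
            rigid = rigid_fraction(chord, etype)
            extracer = extracerebral_fraction(fr.cortex_entry, chord)

            amps = [float(np.mean([layer_vals[l][f"{ax}_mm"] for l in BRAIN_LAYERS]))
                    for ax in ("x", "y", "z")]
            curve_seed = int(rng.integers(2**31))
            curve = make_ground_truth_curve(
                etype, hemi, amps, chord, seed=curve_seed
            )
            m = electrode_frame_matrix(hemi)
            tip = curve.position(1.0) @ m.T + entry[hemi]
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)

            truth[hemi] = curve
            frontiers[hemi] = fr
            bubble[hemi] = bu
            hemi_vol[hemi] = hv
            contact[hemi] = tip
            planned[hemi] = tip + dist * direction
            inacc[hemi] = dist

            for layer in BRAIN_LAYERS:
                rows.append({
                    "patient": patient, "hemisphere": hemi, "electrode_type": etype,
                    "target": target, "layer": layer, **layer_vals[layer],
                    "chord_length_mm": chord, "rigid_pct": rigid,
                    "extracerebral_pct": extracer, "brain_shift_index": bsi,
                    "surgical_inaccuracy_mm": dist,
                    "cortex_entry_mm": fr.cortex_entry,
                    "gyration_wms_mm": fr.gyration_wms,
                    "wms_deep_mm": fr.wms_deep,
                    "hemisphere_volume_mm3": hv,
                })

        case_seed = int(rng.integers(2**31))
        case = SyntheticCase(
            truth=truth, frontiers=frontiers, bubble=bubble,
            hemisphere_volume=hemi_vol, planned_point=planned,
            contact_point=contact, entry_point=entry,
            surgical_inaccuracy_mm=inacc, seed=case_seed, target=target,
        )
        if include_volumes:
            case = rasterize_case(
                list(truth.values()), voxel_size=voxel_size,
                electrode_radius=electrode_radius, seed=case_seed, metadata=case,
            )
        cases.append(case)

    table = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return table, cases
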