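"""Volume and table I/O.

NIfTI is the canonical volume container (nibabel); the affine is taken at
face value as the voxel-index -> scanner-mm map and all coordinates are
handled in scanner mm (LPS assumed).  Tables are comma-separated UTF-8 CSV
with dot decimals; the column dictionary lives in docs/data_dictionary.md.
A DICOM series directory can be read as an alternative input and is
converted to the same internal volume.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, InvalidArgumentError
from .extraction import SkeletonPolyline, VoxelVolume
from .geometry import CubicCurveModel, DeformationProfile

_FLOAT_FORMAT = "%.9g"


def read_volume(path) -> VoxelVolume:
    """Read a NIfTI volume (or a DICOM series directory) as a VoxelVolume."""
    path = Path(path)
    if path.is_dir():
        return _read_dicom_series(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float32)
        affine = np.asarray(img.affine, dtype=float)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    return VoxelVolume(data=data, affine=affine)


def write_volume(volume: VoxelVolume, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    nib.save(img, str(path))
    return path


def _read_dicom_series(directory: Path) -> VoxelVolume:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise FormatError("pydicom is required to read DICOM series") from exc
    files = sorted(directory.glob("*.dcm")) or sorted(directory.iterdir())
    slices = []
    for f in files:
        if f.is_file():
            try:
                slices.append(pydicom.dcmread(str(f)))
            except Exception:
                continue
    if not slices:
        raise FormatError(f"no readable DICOM slices in {directory}")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    data = np.stack([s.pixel_array.T for s in slices], axis=2).astype(np.float32)
    px = [float(v) for v in slices[0].PixelSpacing]
    dz = (float(slices[1].ImagePositionPatient[2]) - float(slices[0].ImagePositionPatient[2])
          if len(slices) > 1 else float(getattr(slices[0], "SliceThickness", 1.0)))
    origin = [float(v) for v in slices[0].ImagePositionPatient]
    affine = np.eye(4)
    affine[:3, :3] = np.diag([px[1], px[0], dz])
    affine[:3, 3] = origin
    return VoxelVolume(data=data, affine=affine)


def write_skeleton_csv(skeleton: SkeletonPolyline, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "t_index": np.arange(skeleton.points.shape[0]),
            "x_mm": skeleton.points[:, 0],
            "y_mm": skeleton.points[:, 1],
            "z_mm": skeleton.points[:, 2],
            "arc_mm": skeleton.cumulative_arc,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def profile_frame(
    profile: DeformationProfile, electrode_id: str, labels=None
) -> pd.DataFrame:
    """Tidy one-row-per-sample frame of a deformation profile."""
    df = pd.DataFrame(
        {
            "electrode_id": electrode_id,
            "sample_index": np.arange(profile.n_samples),
            "t": profile.t,
            "arc_mm": profile.arc_mm,
            "deviation_x_mm": profile.deviations[:, 0],
            "deviation_y_mm": profile.deviations[:, 1],
            "deviation_z_mm": profile.deviations[:, 2],
            "curvature_per_mm": profile.curvature,
            "torsion_per_mm": profile.torsion,
            "torsion_defined": profile.torsion_defined,
        }
    )
    if labels is not None:
        df["layer"] = labels
    return df


def write_model_json(model: CubicCurveModel, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "coeffs_mm": model.coeffs.tolist(),
        "r_squared": model.r_squared,
        "rms_residual_mm": model.rms_residual,
        "source_arc_length_mm": model.source_arc_length,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def write_table_csv(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_config(path) -> dict:
    """Read a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise InvalidArgumentError(f"config {path} must be a mapping")
    return cfg
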