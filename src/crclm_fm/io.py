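"""File I/O: NRRD/NIfTI volumes and masks, feature CSVs, manifests.

Volumes travel as one intensity file plus one binary mask file per patient
(NRRD by default; any format SimpleITK recognises from the extension works,
including ``.nii``/``.nii.gz``).  Arrays are (slice, row, col), the slice
axis cranio-caudal.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .phantoms import PatientVolume, _normalize_label
from .radiomics import FEATURE_NAMES

__all__ = [
    "write_volume",
    "read_volume",
    "write_patient",
    "read_patient",
    "write_cohort",
    "write_feature_table",
    "read_feature_table",
    "read_manifest",
]


def write_volume(array: np.ndarray, path: str | Path) -> None:
    sitk.WriteImage(sitk.GetImageFromArray(np.asarray(array)), str(path))


def read_volume(path: str | Path) -> np.ndarray:
    return sitk.GetArrayFromImage(sitk.ReadImage(str(path)))


def write_patient(patient: PatientVolume, out_dir: str | Path) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol_path = out_dir / f"{patient.patient_id}.nrrd"
    mask_path = out_dir / f"{patient.patient_id}_mask.nrrd"
    write_volume(patient.volume.astype(np.float32), vol_path)
    write_volume(patient.masks.astype(np.uint8), mask_path)
    return vol_path, mask_path


def read_patient(vol_path: str | Path, mask_path: str | Path,
                 patient_id: str = "", label: str = "healthy") -> PatientVolume:
    volume = read_volume(vol_path).astype(float)
    masks = read_volume(mask_path).astype(bool)
    pid = patient_id or Path(vol_path).stem
    return PatientVolume(patient_id=pid, label=_normalize_label(label),
                         volume=volume, masks=masks)


def write_cohort(patients, manifest: pd.DataFrame, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for p in patients:
        write_patient(p, out_dir)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=True)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col=0)
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    return table


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    if not {"patient_id", "label"} <= set(manifest.columns):
        raise ValueError("manifest needs patient_id and label columns")
    manifest["label"] = manifest["label"].map(_normalize_label)
    return manifest
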