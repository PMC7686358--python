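"""Cohort persistence: NIfTI volumes plus a CSV manifest."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import PatientVolume

__all__ = ["save_cohort", "load_cohort"]

_VOLUMES = ("ct", "dose", "lung_mask", "gtv_mask")


def _affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def save_cohort(patients: list[PatientVolume], out_dir: str | Path) -> Path:
    """Write each patient's four volumes as .nii.gz plus manifest.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patients:
        pdir = out_dir / p.patient_id
        pdir.mkdir(exist_ok=True)
        aff = _affine(p.spacing)
        row = {"patient_id": p.patient_id, "rp_label": p.rp_label}
        for name in _VOLUMES:
            arr = getattr(p, name)
            img = nib.Nifti1Image(arr.astype(np.float32), aff)
            path = pdir / f"{name}.nii.gz"
            nib.save(img, path)
            row[name] = str(path.relative_to(out_dir))
        row["spacing"] = ";".join(str(s) for s in p.spacing)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def load_cohort(manifest_path: str | Path) -> list[PatientVolume]:
    """Load a cohort written by :func:`save_cohort`."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    patients = []
    for _, row in manifest.iterrows():
        arrays = {}
        for name in _VOLUMES:
            arrays[name] = np.asarray(nib.load(base / row[name]).dataobj, dtype=np.float64)
        spacing = tuple(float(s) for s in str(row["spacing"]).split(";"))
        patients.append(
            PatientVolume(
                ct=arrays["ct"],
                dose=arrays["dose"],
                lung_mask=arrays["lung_mask"] > 0.5,
                gtv_mask=arrays["gtv_mask"] > 0.5,
                spacing=spacing,
                rp_label=int(row["rp_label"]),
                patient_id=str(row["patient_id"]),
            )
        )
    return patients
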