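"""Dose-threshold lung ROIs (LVx) and dose-volume histogram parameters.

LVx is the lung volume, excluding the gross tumor volume, receiving
more than x Gy (strict inequality). The four default thresholds 0, 5,
10 and 20 Gy give nested masks LV20 ⊆ LV10 ⊆ LV5 ⊆ LV0. Vx is the
percentage of the (GTV-excluded) lung receiving more than x Gy and MLD
its mean dose; both use lung∖GTV as the reference volume, consistent
with the ROI definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import PatientVolume

logger = logging.getLogger(__name__)

__all__ = [
    "RoiMask",
    "DvhParams",
    "DEFAULT_THRESHOLDS_GY",
    "extract_lvx",
    "extract_all_rois",
    "compute_vx",
    "compute_mld",
    "compute_dvh_params",
    "dvh_table",
]

DEFAULT_THRESHOLDS_GY: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0)


@dataclass
class RoiMask:
    """Binary ROI for one dose threshold."""

    mask: np.ndarray
    threshold_gy: float

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0

    @property
    def label(self) -> str:
        return f"LV{self.threshold_gy:g}"


@dataclass(frozen=True)
class DvhParams:
    """V5/V10/V20 (% of lung∖GTV volume) and mean lung dose (Gy)."""

    v5: float
    v10: float
    v20: float
    mld: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.v20 <= self.v10 <= self.v5 <= 100.0):
            raise ValueError("Vx must satisfy 0 <= V20 <= V10 <= V5 <= 100")
        if self.mld < 0:
            raise ValueError("MLD must be non-negative")


def extract_lvx(patient: PatientVolume, threshold_gy: float) -> RoiMask:
    """Lung voxels (GTV excluded) with dose strictly above the threshold."""
    if threshold_gy < 0:
        raise ValueError("threshold_gy must be >= 0")
    mask = patient.lung_minus_gtv & (patient.dose > threshold_gy)
    if not mask.any():
        logger.warning(
            "LV%g is empty for patient %s", threshold_gy, patient.patient_id or "<unnamed>"
        )
    return RoiMask(mask=mask, threshold_gy=float(threshold_gy))


def extract_all_rois(
    patient: PatientVolume, thresholds_gy: tuple[float, ...] = DEFAULT_THRESHOLDS_GY
) -> dict[str, RoiMask]:
    """All LVx masks for one patient, keyed by label (LV0, LV5, ...)."""
    rois = {}
    for t in thresholds_gy:
        roi = extract_lvx(patient, t)
        rois[roi.label] = roi
    return rois


def compute_vx(patient: PatientVolume, threshold_gy: float) -> float:
    """Percentage of lung∖GTV volume receiving more than ``threshold_gy``."""
    lung = patient.lung_minus_gtv
    n = int(lung.sum())
    if n == 0:
        raise ValueError("lung is empty after GTV exclusion")
    return 100.0 * float((patient.dose[lung] > threshold_gy).sum()) / n


def compute_mld(patient: PatientVolume) -> float:
    """Mean dose (Gy) over lung∖GTV."""
    lung = patient.lung_minus_gtv
    if not lung.any():
        raise ValueError("lung is empty after GTV exclusion")
    return float(patient.dose[lung].mean())


def compute_dvh_params(patient: PatientVolume) -> DvhParams:
    return DvhParams(
        v5=compute_vx(patient, 5.0),
        v10=compute_vx(patient, 10.0),
        v20=compute_vx(patient, 20.0),
        mld=compute_mld(patient),
    )


def dvh_table(patients: list[PatientVolume]) -> pd.DataFrame:
    """Per-patient DVH parameters, indexed by patient_id."""
    rows = []
    for p in patients:
        d = compute_dvh_params(p)
        rows.append(
            {
                "patient_id": p.patient_id,
                "v5": d.v5,
                "v10": d.v10,
                "v20": d.v20,
                "mld": d.mld,
                "rp_label": p.rp_label,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")
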