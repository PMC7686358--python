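"""The 486-feature radiomic vector for one (patient, ROI) pair.

54 features — 14 histogram-based plus 40 texture features (9 GLCM,
13 GLRLM, 13 GLSZM, 5 NGTDM) — are computed on the original masked CT
and on each of the 8 single-level wavelet subbands, giving
54 x 9 = 486 named values. Names follow the ``"<feature> (<domain>)"``
scheme, e.g. ``"Correlation (original)"`` or ``"RLV (LHL)"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dosimetry import RoiMask, extract_all_rois, DEFAULT_THRESHOLDS_GY
from .synthetic import PatientVolume
from .texture import (
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    NGTDM_FEATURE_NAMES,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    quantize,
)
from .wavelets import SUBBAND_LABELS, wavelet_subbands

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "HISTOGRAM_FEATURE_NAMES",
    "FEATURE_NAMES_54",
    "DOMAINS",
    "ALL_FEATURE_NAMES",
    "histogram_features",
    "extract_feature_vector",
    "extract_cohort_features",
]

HISTOGRAM_FEATURE_NAMES = (
    "Mean",
    "Variance",
    "SD",
    "Skewness",
    "Kurtosis",
    "Entropy",
    "Uniformity",
    "Energy",
    "Minimum",
    "Maximum",
    "Median",
    "Range",
    "MAD",
    "RMS",
)

#: the 54 per-domain feature names: 14 histogram + 40 texture
FEATURE_NAMES_54: tuple[str, ...] = (
    HISTOGRAM_FEATURE_NAMES
    + GLCM_FEATURE_NAMES
    + GLRLM_FEATURE_NAMES
    + GLSZM_FEATURE_NAMES
    + NGTDM_FEATURE_NAMES
)

DOMAINS: tuple[str, ...] = ("original",) + SUBBAND_LABELS

#: all 486 feature names, original domain first then the 8 subbands
ALL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{name} ({domain})" for domain in DOMAINS for name in FEATURE_NAMES_54
)

assert len(FEATURE_NAMES_54) == 54
assert len(ALL_FEATURE_NAMES) == 486


@dataclass(frozen=True)
class FeatureConfig:
    """Extraction settings: quantization depth and wavelet choice."""

    n_levels: int = 32
    wavelet: str = "coif1"
    wavelet_mode: str = "symmetric"
    thresholds_gy: tuple[float, ...] = DEFAULT_THRESHOLDS_GY


def histogram_features(values: np.ndarray, quantized_hist: np.ndarray) -> dict[str, float]:
    """Fourteen first-order statistics of the in-mask intensities.

    Entropy (bits) and uniformity are computed on the quantized
    histogram; everything else on the raw values. Skewness and kurtosis
    of a zero-variance sample are defined as 0 (kurtosis is the
    non-excess Pearson form otherwise).
    """
    if values.size == 0:
        raise ValueError("cannot compute histogram features of an empty mask")
    values = values.astype(float)
    mean = float(values.mean())
    var = float(values.var())
    if var > 0:
        skew = float(stats.skew(values))
        kurt = float(stats.kurtosis(values, fisher=False))
    else:
        logger.debug("zero-variance region: skewness/kurtosis set to 0")
        skew = 0.0
        kurt = 0.0
    p = quantized_hist.astype(float)
    p = p[p > 0]
    p = p / p.sum()
    return {
        "Mean": mean,
        "Variance": var,
        "SD": float(np.sqrt(var)),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Uniformity": float((p**2).sum()),
        "Energy": float((values**2).sum()),
        "Minimum": float(values.min()),
        "Maximum": float(values.max()),
        "Median": float(np.median(values)),
        "Range": float(values.max() - values.min()),
        "MAD": float(np.abs(values - mean).mean()),
        "RMS": float(np.sqrt((values**2).mean())),
    }


def _domain_features(volume: np.ndarray, roi: RoiMask, config: FeatureConfig) -> dict[str, float]:
    """All 54 features of one domain (original volume or a subband)."""
    q = quantize(volume, roi.mask, n_levels=config.n_levels)
    hist = np.bincount(q.in_mask_levels, minlength=config.n_levels + 1)[1:]
    out = histogram_features(volume[roi.mask], hist)
    out.update(glcm_features(q))
    out.update(glrlm_features(q))
    out.update(glszm_features(q))
    out.update(ngtdm_features(q))
    return out


def extract_feature_vector(
    patient: PatientVolume,
    roi: RoiMask,
    config: FeatureConfig = FeatureConfig(),
) -> pd.Series:
    """The 486 named features of one (patient, ROI) pair.

    Deterministic for fixed input and config. Raises on an empty ROI.
    Any non-finite value is replaced by 0 and logged.
    """
    if roi.is_empty:
        raise ValueError(f"ROI {roi.label} is empty; cannot extract features")
    subbands = wavelet_subbands(patient.ct, wavelet=config.wavelet, mode=config.wavelet_mode)
    values: dict[str, float] = {}
    for domain in DOMAINS:
        vol = patient.ct if domain == "original" else subbands[domain]
        feats = _domain_features(vol, roi, config)
        for name, v in feats.items():
            if not np.isfinite(v):
                logger.warning("non-finite %s (%s): replaced by 0", name, domain)
                v = 0.0
            values[f"{name} ({domain})"] = v
    out = pd.Series(values, dtype=float).reindex(list(ALL_FEATURE_NAMES))
    assert not out.isna().any()
    return out


def extract_cohort_features(
    patients: list[PatientVolume],
    roi_label: str = "LV5",
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Feature table for one ROI across a cohort.

    Returns a DataFrame indexed by patient_id with the 486 feature
    columns plus ``roi`` and ``rp_label``.
    """
    rows = []
    for p in patients:
        rois = extract_all_rois(p, config.thresholds_gy)
        if roi_label not in rois:
            raise KeyError(f"unknown ROI label {roi_label!r}; have {sorted(rois)}")
        vec = extract_feature_vector(p, rois[roi_label], config)
        vec["roi"] = roi_label
        vec["rp_label"] = p.rp_label
        vec.name = p.patient_id
        rows.append(vec)
    df = pd.DataFrame(rows)
    df.index.name = "patient_id"
    df["rp_label"] = df["rp_label"].astype(int)
    return df
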