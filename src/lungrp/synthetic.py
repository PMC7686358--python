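"""Seeded synthetic CT/dose cohorts for exercising the RP pipeline.

Each synthetic patient carries a planning-CT-like intensity grid, a dose
grid peaked at the tumor, a lung mask (ellipsoid) with an embedded
spherical gross tumor volume (GTV), and a binary radiation-pneumonitis
(RP, grade >= 2) label.

The planted class effect is spatial: RP-positive lungs are filled with
texture noise smoothed by a longer Gaussian kernel than RP-negative
lungs, so neighboring voxels are more strongly correlated in positives.
A per-patient monotone intensity response (a random signed-power
"display curve" exponent, independent of the label) varies the marginal
intensity distribution across patients; it preserves the spatial rank
structure that neighbor correlation measures while decoupling
amplitude-driven histogram and contrast statistics from the label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PatientVolume", "CohortSpec", "generate_patient", "generate_cohort"]


@dataclass
class PatientVolume:
    """One patient's co-registered planning volumes.

    All four grids share one shape, axis order (z, y, x). ``spacing`` is
    mm per voxel along (z, y, x). ``rp_label`` is 1 for grade >= 2
    radiation pneumonitis. The GTV is carved out of the lung downstream;
    ``lung_mask`` itself may overlap ``gtv_mask``.
    """

    ct: np.ndarray
    dose: np.ndarray
    lung_mask: np.ndarray
    gtv_mask: np.ndarray
    spacing: tuple[float, float, float]
    rp_label: int
    patient_id: str = ""

    def __post_init__(self) -> None:
        shapes = {self.ct.shape, self.dose.shape, self.lung_mask.shape, self.gtv_mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"grids must share one shape, got {shapes}")
        if self.dose.min() < 0:
            raise ValueError("dose must be non-negative everywhere")
        if not np.any(self.lung_mask & ~self.gtv_mask):
            raise ValueError("lung mask is empty after GTV exclusion")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def lung_minus_gtv(self) -> np.ndarray:
        """Boolean mask of lung voxels excluding the GTV."""
        return self.lung_mask.astype(bool) & ~self.gtv_mask.astype(bool)


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for one synthetic cohort.

    correlation_length_pos / _neg are the Gaussian smoothing sigmas (in
    voxels) of the lung texture noise; the positive class uses the
    longer kernel, which is what plants the higher neighbor correlation
    in RP cases. dose_peak is the dose (Gy) at the GTV centroid and
    dose_falloff the Gaussian falloff length (voxels) of the dose field.
    contrast_gamma_range bounds the per-patient signed-power intensity
    response exponent and noise_sd_jitter the per-patient multiplicative
    spread of the texture amplitude; both are label-independent nuisance
    variation (patients differ in parenchymal contrast and display
    response), which leaves neighbor correlation as the feature that
    tracks the class.
    """

    n_positive: int
    n_negative: int
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 1.0, 1.0)
    correlation_length_pos: float = 1.5
    correlation_length_neg: float = 0.7
    dose_peak: float = 48.0
    dose_falloff: float = 8.0
    noise_sd: float = 50.0
    lung_intensity: float = -800.0
    contrast_gamma_range: tuple[float, float] = (0.6, 1.8)
    noise_sd_jitter: tuple[float, float] = (0.6, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("both classes must have at least one patient")
        if min(self.grid_shape) < 16:
            raise ValueError("grid_shape must be >= 16 along every axis")
        if self.correlation_length_neg <= 0 or self.correlation_length_pos <= 0:
            raise ValueError("correlation lengths must be positive")
        if self.correlation_length_pos <= self.correlation_length_neg:
            raise ValueError(
                "correlation_length_pos must exceed correlation_length_neg "
                "(RP-positive lungs have the longer texture correlation length)"
            )
        if self.dose_peak <= 0 or self.dose_falloff <= 0:
            raise ValueError("dose_peak and dose_falloff must be positive")


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def generate_patient(spec: CohortSpec, rp_status: int, seed: int) -> PatientVolume:
    """Generate one synthetic patient; bit-identical for fixed arguments.

    The lung is an ellipsoid with jittered axes, the GTV a sphere placed
    off-center inside it. Dose is a radial Gaussian about the GTV
    centroid (monotone decreasing in distance, so dose-threshold ROIs
    nest). CT intensity is a lung baseline plus smoothed, contrast-
    transformed Gaussian noise whose smoothing length depends on
    ``rp_status``.
    """
    if rp_status not in (0, 1):
        raise ValueError("rp_status must be 0 or 1")
    rng = np.random.default_rng(seed)
    shape = tuple(spec.grid_shape)
    dims = np.asarray(shape, dtype=float)

    # lung: jittered ellipsoid around the grid center
    semi = dims * np.array([0.38, 0.36, 0.34]) * rng.uniform(0.92, 1.08, size=3)
    center = dims / 2.0 + rng.uniform(-2.0, 2.0, size=3)
    lung = _ellipsoid_mask(shape, center, semi)

    # GTV: sphere strictly inside the lung
    gtv_radius = rng.uniform(2.5, 4.5)
    if gtv_radius >= semi.min():
        raise ValueError("GTV radius exceeds the lung's smallest semi-axis")
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    offset = direction * rng.uniform(0.0, 0.35) * semi.min()
    gtv_center = center + offset
    gtv = _ellipsoid_mask(shape, gtv_center, (gtv_radius,) * 3)
    if gtv.sum() >= lung.sum():
        raise ValueError("GTV is not smaller than the lung")

    # dose: radial Gaussian about the GTV centroid (voxel-index distance)
    falloff = spec.dose_falloff * rng.uniform(0.75, 1.25)
    grids = np.indices(shape, dtype=float)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, gtv_center))
    dose = spec.dose_peak * np.exp(-d2 / (2.0 * falloff**2))

    # texture: smoothed noise, class-dependent kernel, label-independent
    # monotone contrast response
    corr_len = spec.correlation_length_pos if rp_status else spec.correlation_length_neg
    corr_len *= rng.uniform(0.85, 1.15)
    g = rng.standard_normal(shape)
    sm = gaussian_filter(g, sigma=corr_len, mode="reflect")
    sm /= sm.std()
    gamma = rng.uniform(*spec.contrast_gamma_range)
    t = np.sign(sm) * np.abs(sm) ** gamma
    t /= t.std()
    sd = spec.noise_sd * rng.uniform(*spec.noise_sd_jitter)
    ct = spec.lung_intensity + sd * t

    return PatientVolume(
        ct=ct,
        dose=dose,
        lung_mask=lung,
        gtv_mask=gtv,
        spacing=spec.spacing,
        rp_label=int(rp_status),
    )


def generate_cohort(spec: CohortSpec) -> list[PatientVolume]:
    """Generate the full cohort described by ``spec``.

    Per-patient seeds derive deterministically from ``spec.seed``;
    patient order is a seeded permutation so position never leaks the
    label.
    """
    n = spec.n_positive + spec.n_negative
    state = np.random.SeedSequence(spec.seed).generate_state(n + 1)
    labels = [1] * spec.n_positive + [0] * spec.n_negative
    patients = [
        generate_patient(spec, labels[i], int(state[i])) for i in range(n)
    ]
    order = np.random.default_rng(int(state[n])).permutation(n)
    shuffled = [patients[i] for i in order]
    for idx, p in enumerate(shuffled):
        p.patient_id = f"P{idx + 1:03d}"
    return shuffled
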