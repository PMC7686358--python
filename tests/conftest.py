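import numpy as np
import pytest

from lungrp import CohortSpec, PatientVolume, generate_patient


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(n_positive=2, n_negative=2, grid_shape=(16, 16, 16), seed=5)


@pytest.fixture(scope="session")
def patient(small_spec) -> PatientVolume:
    return generate_patient(small_spec, rp_status=1, seed=7)


@pytest.fixture()
def toy_patient() -> PatientVolume:
    """2x2x1 lung with doses {4, 6, 21, 30} Gy and no GTV."""
    dose = np.array([[[4.0], [6.0]], [[21.0], [30.0]]])
    return PatientVolume(
        ct=np.zeros_like(dose),
        dose=dose,
        lung_mask=np.ones_like(dose, dtype=bool),
        gtv_mask=np.zeros_like(dose, dtype=bool),
        spacing=(1.0, 1.0, 1.0),
        rp_label=0,
        patient_id="TOY",
    )


def random_quantized(rng: np.random.Generator, max_side: int = 5, n_levels: int = 4):
    """A random small QuantizedRoi with a random (non-empty) mask."""
    from lungrp.texture import QuantizedRoi

    shape = tuple(rng.integers(2, max_side + 1, size=3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[0] = True
    levels = np.zeros(shape, dtype=np.int32)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return QuantizedRoi(levels=levels, n_levels=n_levels, mask=mask)
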