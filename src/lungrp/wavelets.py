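"""Single-level separable 3-D wavelet decomposition into 8 subbands.

Each axis is filtered with either the scaling (low-pass, L) or the
wavelet (high-pass, H) function, giving the 8 subbands LLL ... HHH.
Subband labels are written x-major: label[0] is the x-axis filter,
label[1] the y-axis filter, label[2] the z-axis filter, while arrays
use (z, y, x) axis order.

Decimated subbands are aligned back onto the original grid (nearest-
coefficient upsampling, center crop) so the original ROI mask applies
unchanged to every domain.
"""

from __future__ import annotations

import numpy as np
import pywt

__all__ = ["SUBBAND_LABELS", "wavelet_subbands"]

SUBBAND_LABELS: tuple[str, ...] = (
    "LLL",
    "LLH",
    "LHL",
    "LHH",
    "HLL",
    "HLH",
    "HHL",
    "HHH",
)


def _key_to_label(key: str) -> str:
    """pywt dwtn key (axis order z,y,x; a=low, d=high) -> x-major label."""
    f = {"a": "L", "d": "H"}
    z, y, x = key
    return f[x] + f[y] + f[z]


def _upsample_align(coeff: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Repeat each coefficient 2x per axis, then center-crop to ``shape``."""
    out = coeff
    for ax in range(out.ndim):
        out = np.repeat(out, 2, axis=ax)
    slices = []
    for ax, n in enumerate(shape):
        extra = out.shape[ax] - n
        if extra < 0:
            raise ValueError("upsampled subband smaller than the original grid")
        start = extra // 2
        slices.append(slice(start, start + n))
    return out[tuple(slices)]


def wavelet_subbands(
    volume: np.ndarray,
    wavelet: str = "coif1",
    mode: str = "symmetric",
    align: bool = True,
) -> dict[str, np.ndarray]:
    """Decompose a 3-D volume into its 8 single-level wavelet subbands.

    Parameters
    ----------
    volume
        3-D array, axis order (z, y, x); every axis must be at least as
        long as the wavelet filter.
    wavelet
        Any PyWavelets wavelet name (default Coiflet-1).
    mode
        Signal extension mode at the boundary (default symmetric
        padding). Use ``"periodization"`` with an orthogonal wavelet for
        an exactly energy-preserving (Parseval) decomposition.
    align
        When True (default) subbands are upsampled and center-cropped
        back to ``volume.shape``; when False the raw decimated
        coefficient arrays are returned.

    Returns
    -------
    dict mapping the x-major labels LLL..HHH to subband arrays.
    """
    if volume.ndim != 3:
        raise ValueError("expected a 3-D volume")
    w = pywt.Wavelet(wavelet)
    if min(volume.shape) < w.dec_len:
        raise ValueError(
            f"grid {volume.shape} is smaller than the {wavelet} filter length {w.dec_len}"
        )
    coeffs = pywt.dwtn(volume, wavelet=w, mode=mode, axes=(0, 1, 2))
    out: dict[str, np.ndarray] = {}
    for key, arr in coeffs.items():
        label = _key_to_label(key)
        out[label] = _upsample_align(arr, volume.shape) if align else arr
    return {label: out[label] for label in SUBBAND_LABELS}
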