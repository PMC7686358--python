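"""Gray-level texture matrices and their scalar features.

Implements the four classic 3-D texture characterizations on a
quantized ROI: the gray level co-occurrence matrix (GLCM), gray level
run-length matrix (GLRLM), gray level size-zone matrix (GLSZM) and the
neighborhood gray-tone difference matrix (NGTDM).

Conventions (all configurable where noted):

* intensities are quantized to ``n_levels`` equal-width bins over the
  in-mask range (min -> level 1, max -> level Ng), per ROI and domain;
* GLCM: the 13 unique distance-1 3-D offsets are merged into one
  symmetric matrix (raw pair counts, then probability-normalized);
* GLRLM: runs (maximal collinear same-level in-mask segments) are
  accumulated over the same 13 directions into one matrix;
* GLSZM zones and NGTDM neighborhoods use 26-connectivity;
* only voxel pairs / neighbors inside the mask ever contribute.

Degenerate inputs (constant region, zero-variance marginals, no valid
neighborhoods) are mapped to the documented fallback values and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

logger = logging.getLogger(__name__)

__all__ = [
    "QuantizedRoi",
    "quantize",
    "DIRECTIONS_3D",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "ngtdm_features",
    "GLCM_FEATURE_NAMES",
    "GLRLM_FEATURE_NAMES",
    "GLSZM_FEATURE_NAMES",
    "NGTDM_FEATURE_NAMES",
]

#: the 13 unique distance-1 offsets in 3-D (one per +/- direction pair),
#: axis order (z, y, x)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

#: cap returned for NGTDM coarseness when sum(p_i * s_i) vanishes
COARSENESS_CAP = 1.0e6


@dataclass
class QuantizedRoi:
    """Gray levels 1..Ng inside the mask, 0 outside.

    ``degenerate`` flags a constant in-mask intensity (all voxels were
    assigned level 1).
    """

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray
    degenerate: bool = False

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def quantize(volume: np.ndarray, mask: np.ndarray, n_levels: int = 32) -> QuantizedRoi:
    """Equal-width quantization of in-mask intensities into 1..Ng.

    Monotone in intensity and invariant under positive affine intensity
    rescaling. A constant region maps every voxel to level 1 and sets
    the degenerate flag.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("cannot quantize an empty mask")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    vals = volume[mask].astype(float)
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        logger.debug("constant in-mask intensity: quantization degenerate")
        levels[mask] = 1
        return QuantizedRoi(levels=levels, n_levels=n_levels, mask=mask, degenerate=True)
    binned = np.floor((vals - lo) / (hi - lo) * n_levels).astype(np.int32) + 1
    np.clip(binned, 1, n_levels, out=binned)
    levels[mask] = binned
    return QuantizedRoi(levels=levels, n_levels=n_levels, mask=mask, degenerate=False)


# --------------------------------------------------------------------------
# GLCM


def glcm_matrix(
    q: QuantizedRoi, directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D
) -> np.ndarray:
    """Merged symmetric co-occurrence matrix, probability-normalized.

    Pairs are counted at distance 1 along each direction, both voxels
    in-mask; each pair contributes to (i, j) and (j, i).
    """
    ng = q.n_levels
    lev = q.levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    for d in directions:
        a, b = _shifted_pair(lev, d)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        idx = (a[valid].astype(np.int64) - 1) * ng + (b[valid] - 1)
        counts += np.bincount(idx, minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no in-mask voxel pairs at distance 1")
    return counts / total


def _shifted_pair(lev: np.ndarray, d: tuple[int, int, int]):
    """Views of the level grid offset by direction d."""
    sl_a, sl_b = [], []
    for k in d:
        n = None
        if k == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif k > 0:
            sl_a.append(slice(0, -k))
            sl_b.append(slice(k, n))
        else:
            sl_a.append(slice(-k, n))
            sl_b.append(slice(0, k))
    return lev[tuple(sl_a)], lev[tuple(sl_b)]


GLCM_FEATURE_NAMES = (
    "Energy_GLCM",
    "Contrast_GLCM",
    "Correlation",
    "Homogeneity",
    "Variance_GLCM",
    "SumAverage",
    "Entropy_GLCM",
    "Dissimilarity",
    "Autocorrelation",
)


def glcm_features(
    q: QuantizedRoi, directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D
) -> dict[str, float]:
    """Nine co-occurrence features from the merged symmetric GLCM.

    Correlation is sum_ij p(i,j) (i - mu)(j - mu) / sigma^2 on the
    symmetric matrix; a zero-variance marginal yields 0 (flagged).
    """
    p = glcm_matrix(q, directions)
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    p_i = p.sum(axis=1)  # marginal (symmetric: both marginals equal)
    mu = float((i * p_i).sum())
    var = float(((i - mu) ** 2 * p_i).sum())
    nz = p > 0

    if var > 0:
        correlation = float(((ii - mu) * (jj - mu) * p).sum()) / var
    else:
        logger.debug("GLCM marginal variance is zero: correlation set to 0")
        correlation = 0.0

    return {
        "Energy_GLCM": float((p**2).sum()),
        "Contrast_GLCM": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": correlation,
        "Homogeneity": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Variance_GLCM": var,
        "SumAverage": float(((ii + jj) * p).sum()) / 2.0,
        "Entropy_GLCM": float(-(p[nz] * np.log2(p[nz])).sum()),
        "Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "Autocorrelation": float((ii * jj * p).sum()),
    }


# --------------------------------------------------------------------------
# GLRLM


def _flip_to_nonnegative(lev: np.ndarray, d: tuple[int, int, int]):
    """Flip axes so every component of d is >= 0 (runs are unchanged)."""
    out = lev
    dd = []
    for ax, k in enumerate(d):
        if k < 0:
            out = np.flip(out, axis=ax)
            dd.append(-k)
        else:
            dd.append(k)
    return out, tuple(dd)


def _lines_along(lev: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """Shear the grid so voxels collinear along ``d`` align on one axis.

    Returns a 2-D array whose rows are the grid's maximal lines along
    ``d``, zero-padded; 0 is the out-of-mask sentinel, so padding can
    never join two runs.
    """
    lev, d = _flip_to_nonnegative(lev, d)
    primary = next(ax for ax, k in enumerate(d) if k != 0)
    np_len = lev.shape[primary]
    new_shape = []
    for ax, k in enumerate(d):
        if ax == primary:
            new_shape.append(np_len)
        else:
            new_shape.append(lev.shape[ax] + (np_len - 1) * k)
    sheared = np.zeros(new_shape, dtype=lev.dtype)
    coords = np.indices(lev.shape)
    new_coords = []
    for ax, k in enumerate(d):
        if ax == primary:
            new_coords.append(coords[ax])
        else:
            # invariant along the line: c_ax - k * c_primary
            new_coords.append(coords[ax] - k * coords[primary] + k * (np_len - 1))
    sheared[tuple(new_coords)] = lev
    # lines run along the primary axis: move it last and flatten the rest
    lines = np.moveaxis(sheared, primary, -1)
    return lines.reshape(-1, np_len)


def _run_lengths(lines: np.ndarray):
    """Run-length encode every row; returns (levels, lengths) of runs.

    Rows are separated by an injected sentinel column so runs never
    bridge lines. Sentinel/out-of-mask (level 0) runs are dropped.
    """
    sep = np.full((lines.shape[0], 1), -1, dtype=lines.dtype)
    flat = np.concatenate([lines, sep], axis=1).ravel()
    change = np.flatnonzero(np.diff(flat) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [flat.size - 1]])
    values = flat[starts]
    lengths = ends - starts + 1
    keep = values > 0
    return values[keep], lengths[keep]


def glrlm_matrix(
    q: QuantizedRoi, directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D
) -> np.ndarray:
    """Raw run-length counts, rows = gray level, columns = run length.

    Runs are maximal in-mask collinear segments of equal level,
    accumulated over all requested directions.
    """
    ng = q.n_levels
    max_len = int(np.ceil(np.sqrt(sum(s**2 for s in q.levels.shape)))) + 1
    mat = np.zeros((ng, max_len), dtype=np.int64)
    for d in directions:
        values, lengths = _run_lengths(_lines_along(q.levels, d))
        if values.size:
            np.add.at(mat, (values.astype(np.int64) - 1, lengths - 1), 1)
    if mat.sum() == 0:
        raise ValueError("mask produced no runs")
    # trim trailing all-zero length columns
    last = np.flatnonzero(mat.sum(axis=0))[-1]
    return mat[:, : last + 1]


GLRLM_FEATURE_NAMES = (
    "SRE",
    "LRE",
    "GLN_GLRLM",
    "RLN",
    "RP",
    "LGRE",
    "HGRE",
    "SRLGE",
    "SRHGE",
    "LRLGE",
    "LRHGE",
    "GLV_GLRLM",
    "RLV",
)


def glrlm_features(
    q: QuantizedRoi, directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D
) -> dict[str, float]:
    """Thirteen run-length features.

    Emphasis features use run-probability weights p(i,j) = m(i,j)/n_runs;
    RP normalizes the run count by voxels x directions so a fully
    fragmented region (all runs length 1) scores exactly 1. GLV/RLV are
    the p-weighted variances of gray level and run length.
    """
    m = glrlm_matrix(q, directions).astype(float)
    n_runs = m.sum()
    ng, nl = m.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nl + 1, dtype=float)[None, :]
    p = m / n_runs
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    mu_i = float((i[:, 0] * row / n_runs).sum())
    mu_j = float((j[0, :] * col / n_runs).sum())
    n_vox = q.n_voxels * len(directions)
    return {
        "SRE": float((m / j**2).sum() / n_runs),
        "LRE": float((m * j**2).sum() / n_runs),
        "GLN_GLRLM": float((row**2).sum() / n_runs),
        "RLN": float((col**2).sum() / n_runs),
        "RP": float(n_runs / n_vox),
        "LGRE": float((m / i**2).sum() / n_runs),
        "HGRE": float((m * i**2).sum() / n_runs),
        "SRLGE": float((m / (i**2 * j**2)).sum() / n_runs),
        "SRHGE": float((m * i**2 / j**2).sum() / n_runs),
        "LRLGE": float((m * j**2 / i**2).sum() / n_runs),
        "LRHGE": float((m * i**2 * j**2).sum() / n_runs),
        "GLV_GLRLM": float((p * (i - mu_i) ** 2).sum()),
        "RLV": float((p * (j - mu_j) ** 2).sum()),
    }


# --------------------------------------------------------------------------
# GLSZM


def glszm_matrix(q: QuantizedRoi) -> np.ndarray:
    """Raw zone counts, rows = gray level, columns = zone size.

    Zones are 26-connected components of equal level inside the mask.
    """
    labels = cc_label(q.levels, background=0, connectivity=3)
    flat_lab = labels.ravel()
    flat_lev = q.levels.ravel()
    inside = flat_lab > 0
    n_zones = flat_lab.max()
    sizes = np.bincount(flat_lab[inside], minlength=n_zones + 1)[1:]
    zone_level = np.zeros(n_zones + 1, dtype=np.int64)
    zone_level[flat_lab[inside]] = flat_lev[inside]  # uniform within a zone
    zone_level = zone_level[1:]
    if n_zones == 0:
        raise ValueError("mask produced no zones")
    mat = np.zeros((q.n_levels, int(sizes.max())), dtype=np.int64)
    np.add.at(mat, (zone_level - 1, sizes - 1), 1)
    return mat


GLSZM_FEATURE_NAMES = (
    "SZE",
    "LZE",
    "GLN_GLSZM",
    "ZSN",
    "ZP",
    "LGZE",
    "HGZE",
    "SZLGE",
    "SZHGE",
    "LZLGE",
    "LZHGE",
    "GLV_GLSZM",
    "ZSV",
)


def glszm_features(q: QuantizedRoi) -> dict[str, float]:
    """Thirteen size-zone features (zone-probability weighted)."""
    m = glszm_matrix(q).astype(float)
    n_zones = m.sum()
    ng, nz = m.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, nz + 1, dtype=float)[None, :]
    p = m / n_zones
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    mu_i = float((i[:, 0] * row / n_zones).sum())
    mu_j = float((j[0, :] * col / n_zones).sum())
    return {
        "SZE": float((m / j**2).sum() / n_zones),
        "LZE": float((m * j**2).sum() / n_zones),
        "GLN_GLSZM": float((row**2).sum() / n_zones),
        "ZSN": float((col**2).sum() / n_zones),
        "ZP": float(n_zones / q.n_voxels),
        "LGZE": float((m / i**2).sum() / n_zones),
        "HGZE": float((m * i**2).sum() / n_zones),
        "SZLGE": float((m / (i**2 * j**2)).sum() / n_zones),
        "SZHGE": float((m * i**2 / j**2).sum() / n_zones),
        "LZLGE": float((m * j**2 / i**2).sum() / n_zones),
        "LZHGE": float((m * i**2 * j**2).sum() / n_zones),
        "GLV_GLSZM": float((p * (i - mu_i) ** 2).sum()),
        "ZSV": float((p * (j - mu_j) ** 2).sum()),
    }


# --------------------------------------------------------------------------
# NGTDM

NGTDM_FEATURE_NAMES = (
    "Coarseness",
    "Contrast_NGTDM",
    "Busyness",
    "Complexity",
    "Strength",
)


def ngtdm_components(q: QuantizedRoi):
    """Amadasun–King NGTDM restricted to in-mask 26-neighborhoods.

    Returns (n_i, p_i, s_i) over levels 1..Ng: counts, probabilities and
    summed absolute differences between each voxel's level and the mean
    level of its in-mask neighbors. Voxels with no in-mask neighbor are
    excluded.
    """
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    maskf = q.mask.astype(float)
    nb_sum = ndimage.convolve(q.levels * maskf, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.convolve(maskf, kernel, mode="constant", cval=0.0)
    valid = q.mask & (nb_cnt > 0)
    if not valid.any():
        raise ValueError("no voxel has an in-mask neighbor")
    lev = q.levels[valid].astype(float)
    abar = nb_sum[valid] / nb_cnt[valid]
    diff = np.abs(lev - abar)
    ng = q.n_levels
    n_i = np.bincount(q.levels[valid] - 1, minlength=ng).astype(float)
    s_i = np.bincount(q.levels[valid] - 1, weights=diff, minlength=ng)
    p_i = n_i / n_i.sum()
    return n_i, p_i, s_i


def ngtdm_features(q: QuantizedRoi) -> dict[str, float]:
    """Five neighborhood gray-tone difference features.

    Degenerate fallbacks: coarseness is capped at 1e6 when
    sum(p_i s_i) = 0; contrast/busyness/complexity/strength are 0 when
    fewer than two levels occur (or their denominators vanish).
    """
    n_i, p_i, s_i = ngtdm_components(q)
    n_valid = n_i.sum()
    ng = len(p_i)
    occ = p_i > 0
    ngp = int(occ.sum())
    i = np.arange(1, ng + 1, dtype=float)

    ps = float((p_i * s_i).sum())
    if ps > 0:
        coarseness = 1.0 / ps
        if coarseness > COARSENESS_CAP:
            coarseness = COARSENESS_CAP
    else:
        logger.debug("NGTDM sum(p_i s_i)=0: coarseness capped")
        coarseness = COARSENESS_CAP

    if ngp > 1:
        pi_o = p_i[occ]
        ii_o = i[occ]
        dif2 = (ii_o[:, None] - ii_o[None, :]) ** 2
        contrast = float(
            (pi_o[:, None] * pi_o[None, :] * dif2).sum()
            / (ngp * (ngp - 1))
            * (s_i.sum() / n_valid)
        )
        denom = float(np.abs(ii_o[:, None] * pi_o[:, None] - ii_o[None, :] * pi_o[None, :]).sum())
        busyness = ps / denom if denom > 0 else 0.0
        psum = pi_o[:, None] + pi_o[None, :]
        complexity = float(
            (
                np.abs(ii_o[:, None] - ii_o[None, :])
                * (pi_o[:, None] * s_i[occ][:, None] + pi_o[None, :] * s_i[occ][None, :])
                / psum
            ).sum()
            / n_valid
        )
        strength_num = float((psum * dif2).sum())
        strength = strength_num / s_i.sum() if s_i.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast_NGTDM": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
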