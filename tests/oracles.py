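"""Naive enumeration oracles for the texture matrices and AUC.

Everything here is deliberately brute-force (voxel-by-voxel loops,
flood fill, all-pairs counting) and shares no code with the package's
vectorized implementations.
"""

from __future__ import annotations

import numpy as np

OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _in_bounds(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def naive_glcm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence counts via per-voxel 26-neighbor loops."""
    counts = np.zeros((n_levels, n_levels), dtype=np.int64)
    shape = levels.shape
    for p in np.argwhere(mask):
        for d in OFFSETS_26:
            q = tuple(p + d)
            if _in_bounds(shape, q) and mask[q]:
                counts[levels[tuple(p)] - 1, levels[q] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def naive_glrlm(levels: np.ndarray, mask: np.ndarray, n_levels: int, directions) -> np.ndarray:
    """Run-length counts by walking every maximal run voxel by voxel."""
    shape = levels.shape
    max_len = int(np.ceil(np.sqrt(sum(s**2 for s in shape)))) + 1
    mat = np.zeros((n_levels, max_len), dtype=np.int64)
    for d in directions:
        d = np.asarray(d)
        for p in np.argwhere(mask):
            prev = tuple(p - d)
            lev = levels[tuple(p)]
            # only count a run once, from its first voxel
            if _in_bounds(shape, prev) and mask[prev] and levels[prev] == lev:
                continue
            length = 1
            q = p + d
            while _in_bounds(shape, tuple(q)) and mask[tuple(q)] and levels[tuple(q)] == lev:
                length += 1
                q = q + d
            mat[lev - 1, length - 1] += 1
    return mat


def flood_fill_zones(levels: np.ndarray, mask: np.ndarray) -> list[tuple[int, int]]:
    """26-connected equal-level zones via breadth-first flood fill.

    Returns one (level, size) pair per zone.
    """
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        lev = levels[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for d in OFFSETS_26:
                q = tuple(np.asarray(p) + d)
                if (
                    _in_bounds(shape, q)
                    and mask[q]
                    and not seen[q]
                    and levels[q] == lev
                ):
                    seen[q] = True
                    stack.append(q)
        zones.append((int(lev), size))
    return zones


def naive_glszm(levels: np.ndarray, mask: np.ndarray, n_levels: int) -> np.ndarray:
    zones = flood_fill_zones(levels, mask)
    max_size = max(s for _, s in zones)
    mat = np.zeros((n_levels, max_size), dtype=np.int64)
    for lev, size in zones:
        mat[lev - 1, size - 1] += 1
    return mat


def naive_ngtdm(levels: np.ndarray, mask: np.ndarray, n_levels: int):
    """(n_i, p_i, s_i) via per-voxel neighborhood means."""
    shape = levels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    for p in np.argwhere(mask):
        p = tuple(p)
        neigh = [
            levels[tuple(np.asarray(p) + d)]
            for d in OFFSETS_26
            if _in_bounds(shape, tuple(np.asarray(p) + d)) and mask[tuple(np.asarray(p) + d)]
        ]
        if not neigh:
            continue
        lev = levels[p]
        n_i[lev - 1] += 1
        s_i[lev - 1] += abs(lev - float(np.mean(neigh)))
    p_i = n_i / n_i.sum() if n_i.sum() else n_i
    return n_i, p_i, s_i


def pairwise_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic over all positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))
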