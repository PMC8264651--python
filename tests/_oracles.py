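"""Independent brute-force oracles for texture features and statistics.

Everything here is written as plain nested loops over voxels, deliberately
avoiding the vectorized construction used by the package, so the two paths
can be compared exactly on small blocks.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

DIRECTIONS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _inb(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def glcm_oracle(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Count every ordered same/opposite neighbor pair over the 26 offsets
    (equivalent to symmetric accumulation over 13 directions)."""
    counts = np.zeros((n_bins, n_bins))
    shape = levels.shape
    for p in product(*map(range, shape)):
        a = levels[p]
        if a == 0:
            continue
        for off in OFFSETS_26:
            q = tuple(c + o for c, o in zip(p, off))
            if not _inb(shape, q):
                continue
            b = levels[q]
            if b == 0:
                continue
            counts[a - 1, b - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def glrlm_oracle(levels: np.ndarray, n_bins: int, directions=None) -> np.ndarray:
    """Explicit run scanner: walk every line in every direction."""
    if directions is None:
        directions = DIRECTIONS_13
    shape = levels.shape
    max_len = max(shape)
    rlm = np.zeros((n_bins, max_len))
    for d in directions:
        for p in product(*map(range, shape)):
            if levels[p] == 0:
                continue
            prev = tuple(c - o for c, o in zip(p, d))
            if _inb(shape, prev) and levels[prev] == levels[p]:
                continue  # not a run start
            length = 1
            q = tuple(c + o for c, o in zip(p, d))
            while _inb(shape, q) and levels[q] == levels[p]:
                length += 1
                q = tuple(c + o for c, o in zip(q, d))
            rlm[levels[p] - 1, length - 1] += 1
    return rlm


def _flood_zones(levels: np.ndarray):
    """26-connected equal-level components via explicit flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for p in product(*map(range, shape)):
        if levels[p] == 0 or seen[p]:
            continue
        lv = levels[p]
        stack = [p]
        seen[p] = True
        members = []
        while stack:
            cur = stack.pop()
            members.append(cur)
            for off in OFFSETS_26:
                q = tuple(c + o for c, o in zip(cur, off))
                if _inb(shape, q) and not seen[q] and levels[q] == lv:
                    seen[q] = True
                    stack.append(q)
        zones.append((int(lv), members))
    return zones


def _border_distance(levels: np.ndarray) -> np.ndarray:
    """Chebyshev distance (in voxels) to the nearest outside-the-VOI voxel,
    the image edge included; computed by brute-force nearest search."""
    shape = levels.shape
    inmask = levels > 0
    outside = []
    for p in product(*map(range, shape)):
        if not inmask[p]:
            outside.append(p)
    dist = np.zeros(shape, dtype=int)
    for p in product(*map(range, shape)):
        if not inmask[p]:
            continue
        # distance to image edge (stepping out of the array counts)
        edge = min(min(c + 1, n - c) for c, n in zip(p, shape))
        d = edge
        for q in outside:
            d = min(d, max(abs(a - b) for a, b in zip(p, q)))
        dist[p] = d
    return dist


def glszm_oracle(levels: np.ndarray) -> dict[tuple[int, int], float]:
    out: dict[tuple[int, int], float] = {}
    for lv, members in _flood_zones(levels):
        key = (lv, len(members))
        out[key] = out.get(key, 0.0) + 1.0
    return out


def gldzm_oracle(levels: np.ndarray) -> dict[tuple[int, int], float]:
    dist = _border_distance(levels)
    out: dict[tuple[int, int], float] = {}
    for lv, members in _flood_zones(levels):
        dmin = min(int(dist[m]) for m in members)
        key = (lv, dmin)
        out[key] = out.get(key, 0.0) + 1.0
    return out


def ngldm_oracle(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Per-voxel neighbor scan; j = dependent-neighbor count + 1."""
    shape = levels.shape
    mat = np.zeros((n_bins, 27))
    for p in product(*map(range, shape)):
        if levels[p] == 0:
            continue
        k = 0
        for off in OFFSETS_26:
            q = tuple(c + o for c, o in zip(p, off))
            if _inb(shape, q) and levels[q] == levels[p]:
                k += 1
        mat[levels[p] - 1, k] += 1
    return mat


def ngtdm_coarseness_oracle(levels: np.ndarray, eps: float = 1e-6) -> float:
    shape = levels.shape
    diffs: dict[int, list[float]] = {}
    n_total = 0
    for p in product(*map(range, shape)):
        if levels[p] == 0:
            continue
        nb = []
        for off in OFFSETS_26:
            q = tuple(c + o for c, o in zip(p, off))
            if _inb(shape, q) and levels[q] > 0:
                nb.append(levels[q])
        if not nb:
            continue
        n_total += 1
        diffs.setdefault(int(levels[p]), []).append(
            abs(levels[p] - sum(nb) / len(nb))
        )
    acc = 0.0
    for lv, dlist in diffs.items():
        acc += (len(dlist) / n_total) * sum(dlist)
    return 1.0 / (eps + acc)


def sphere_voxels_1mm(center, radius_mm, shape):
    """Voxel coordinates (1 mm grid) whose centers lie within radius_mm."""
    r = math.floor(radius_mm)
    out = []
    for off in product(range(-r, r + 1), repeat=3):
        if sum(o * o for o in off) <= radius_mm**2 + 1e-9:
            q = tuple(c + o for c, o in zip(center, off))
            if _inb(shape, q):
                out.append(q)
    return out


def icc_a1_oracle(x: np.ndarray) -> float:
    """ICC(A,1) from two-way ANOVA mean squares, coded independently."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    mean = x.mean()
    ms_rows = k * sum((x[i].mean() - mean) ** 2 for i in range(n)) / (n - 1)
    ms_cols = n * sum((x[:, j].mean() - mean) ** 2 for j in range(k)) / (k - 1)
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + mean) ** 2
        for i in range(n)
        for j in range(k)
    )
    ms_err = sse / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    )


def fisher_oracle(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def hyper(x):
        return (
            math.comb(r1, x)
            * math.comb(r2, c1 - x)
            / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = hyper(a)
    return sum(hyper(x) for x in range(lo, hi + 1) if hyper(x) <= p_obs * (1 + 1e-7))
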