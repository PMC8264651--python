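"""Gray-level texture matrix construction and family features.

All matrices are built on the discretized VOI (integer levels 1..N_g inside
the mask, 0 outside) with a single set of conventions, pinned by brute-force
oracles in the test suite:

* GLCM: symmetric co-occurrences over all 13 unique 3D directions at Chebyshev
  distance 1, merged into one matrix before normalization.
* GLRLM: run-length matrices over the 13 directions, merged before feature
  computation; out-of-mask voxels break runs.
* GLSZM: zones are 26-connected components of equal level.
* GLDZM: zone distance is the minimum, over the zone, of the Chebyshev
  distance (in voxels) to the VOI border; a voxel adjacent to outside has
  distance 1 and the image edge counts as outside.
* NGLDM: 26-neighborhood, dependence threshold alpha = 0 (neighbors count as
  dependent when their level is equal); dependence size j = k + 1 where k is
  the dependent-neighbor count.
* NGTDM: 26-neighborhood average level difference; coarseness uses a 1e-6
  guard so a perfectly flat VOI maps to 1e6 instead of infinity.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# The 13 unique direction vectors of the 26-neighborhood (one per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

_COARSENESS_EPS = 1e-6


def _shift_slices(shape, d):
    """Slices (src, dst) with dst = src + d, both within bounds."""
    src, dst = [], []
    for n, off in zip(shape, d):
        if off >= 0:
            src.append(slice(0, n - off))
            dst.append(slice(off, n))
        else:
            src.append(slice(-off, n))
            dst.append(slice(0, n + off))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(levels: np.ndarray, n_bins: int, directions=DIRECTIONS_13) -> np.ndarray:
    """Merged symmetric co-occurrence probability matrix p(i, j), shape (Ng, Ng)."""
    counts = np.zeros((n_bins, n_bins), dtype=np.float64)
    for d in directions:
        src, dst = _shift_slices(levels.shape, d)
        a = levels[src].ravel()
        b = levels[dst].ravel()
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        flat = (a[valid] - 1) * n_bins + (b[valid] - 1)
        c = np.bincount(flat, minlength=n_bins * n_bins).reshape(n_bins, n_bins)
        counts += c + c.T
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def glcm_features(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i = np.arange(1, n + 1)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    joint_average = float((i[:, None] * p).sum())
    # p_{x+y}(k), k = i + j in 2..2n
    k = i[:, None] + i[None, :]
    sum_average = float((k * p).sum())
    autocorr = float((i[:, None] * i[None, :] * p).sum())

    def _ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    hx, hy = _ent(px), _ent(py)
    hxy = _ent(p.ravel())
    pxpy = px[:, None] * py[None, :]
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    return {
        "GLCM_JointAverage": joint_average,
        "GLCM_SumAverage": sum_average,
        "GLCM_AutoCorrelation": autocorr,
        "GLCM_InformationMeasureCor1": imc1,
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(levels: np.ndarray, n_bins: int, directions=DIRECTIONS_13) -> np.ndarray:
    """Merged run-length matrix r(i, l): runs of level i with length l.

    Shape (Ng, L_max).  Run lengths are computed per direction by fixed-point
    iteration on L(x) = 1 + L(x + d) over same-level in-mask neighbors.
    """
    inmask = levels > 0
    max_len = max(levels.shape)
    rlm = np.zeros((n_bins, max_len), dtype=np.float64)
    for d in directions:
        src, dst = _shift_slices(levels.shape, d)
        same_next = np.zeros(levels.shape, dtype=bool)
        same_next[src] = inmask[src] & inmask[dst] & (levels[src] == levels[dst])
        length = inmask.astype(np.int64)
        while True:
            nxt = np.zeros(levels.shape, dtype=np.int64)
            nxt[src] = length[dst]
            new = inmask.astype(np.int64) + np.where(same_next, nxt, 0)
            if np.array_equal(new, length):
                break
            length = new
        same_prev = np.zeros(levels.shape, dtype=bool)
        same_prev[dst] = same_next[src]
        starts = inmask & ~same_prev
        lv = levels[starts] - 1
        ln = length[starts] - 1
        np.add.at(rlm, (lv, ln), 1.0)
    return rlm


def glrlm_features(rlm: np.ndarray, n_voxels: int, n_directions: int = 13) -> dict[str, float]:
    n_runs = rlm.sum()
    if n_runs == 0:
        return {k: 0.0 for k in (
            "GLRLM_ShortRunEmphasis", "GLRLM_LongRunEmphasis", "GLRLM_HighGLRunEmpha",
            "GLRLM_ShortRunHighGLEmpha", "GLRLM_LongRunHighGLEmpha",
            "GLRLM_GLNonuniformity", "GLRLM_RLNonuniformity", "GLRLM_RunPercentage")}
    i = np.arange(1, rlm.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, rlm.shape[1] + 1, dtype=np.float64)
    ri = rlm.sum(axis=1)
    rj = rlm.sum(axis=0)
    return {
        "GLRLM_ShortRunEmphasis": float((rj / j**2).sum() / n_runs),
        "GLRLM_LongRunEmphasis": float((rj * j**2).sum() / n_runs),
        "GLRLM_HighGLRunEmpha": float((ri * i**2).sum() / n_runs),
        "GLRLM_ShortRunHighGLEmpha": float(
            ((i[:, None] ** 2 / j[None, :] ** 2) * rlm).sum() / n_runs
        ),
        "GLRLM_LongRunHighGLEmpha": float(
            ((i[:, None] ** 2 * j[None, :] ** 2) * rlm).sum() / n_runs
        ),
        "GLRLM_GLNonuniformity": float((ri**2).sum() / n_runs),
        "GLRLM_RLNonuniformity": float((rj**2).sum() / n_runs),
        # merged convention: normalized by voxel count and direction count
        "GLRLM_RunPercentage": float(n_runs / (n_voxels * n_directions)),
    }


# ---------------------------------------------------------------------------
# GLSZM / GLDZM
# ---------------------------------------------------------------------------

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def _zones(levels: np.ndarray, n_bins: int):
    """Yield (level, zone_sizes, zone_min_border_distance) per gray level."""
    inmask = levels > 0
    padded = np.pad(inmask, 1)
    # Chebyshev (chessboard) distance to outside-the-VOI; edge voxels get 1.
    dist = ndimage.distance_transform_cdt(padded, metric="chessboard")[
        1:-1, 1:-1, 1:-1
    ]
    for level in range(1, n_bins + 1):
        binary = levels == level
        if not binary.any():
            continue
        lab, n_zones = ndimage.label(binary, structure=_STRUCT_26)
        sizes = ndimage.sum_labels(binary, lab, index=np.arange(1, n_zones + 1))
        dmins = ndimage.minimum(dist, lab, index=np.arange(1, n_zones + 1))
        yield level, sizes.astype(np.int64), np.asarray(dmins, dtype=np.int64)


def glszm_gldzm_matrices(levels: np.ndarray, n_bins: int):
    """Size-zone matrix s(i, z) and distance-zone matrix d(i, dist) as dicts
    {(level, size): count} / {(level, distance): count}."""
    szm: dict[tuple[int, int], float] = {}
    dzm: dict[tuple[int, int], float] = {}
    for level, sizes, dmins in _zones(levels, n_bins):
        for s in sizes:
            szm[(level, int(s))] = szm.get((level, int(s)), 0.0) + 1.0
        for d in dmins:
            dzm[(level, int(d))] = dzm.get((level, int(d)), 0.0) + 1.0
    return szm, dzm


def glszm_features(szm: dict[tuple[int, int], float]) -> dict[str, float]:
    n_zones = sum(szm.values())
    if n_zones == 0:
        return {"GLSZM_LargeZoneHighGLEmpha": 0.0, "GLSZM_GLNonuniformity": 0.0}
    lzhge = sum(c * (i**2) * (z**2) for (i, z), c in szm.items()) / n_zones
    per_level: dict[int, float] = {}
    for (i, _z), c in szm.items():
        per_level[i] = per_level.get(i, 0.0) + c
    gln = sum(v**2 for v in per_level.values()) / n_zones
    return {
        "GLSZM_LargeZoneHighGLEmpha": float(lzhge),
        "GLSZM_GLNonuniformity": float(gln),
    }


def gldzm_features(dzm: dict[tuple[int, int], float]) -> dict[str, float]:
    n_zones = sum(dzm.values())
    if n_zones == 0:
        return {"GLDZM_GLNonuniformity": 0.0, "GLDZM_ZDNonuniformity": 0.0}
    per_level: dict[int, float] = {}
    per_dist: dict[int, float] = {}
    for (i, d), c in dzm.items():
        per_level[i] = per_level.get(i, 0.0) + c
        per_dist[d] = per_dist.get(d, 0.0) + c
    gln = sum(v**2 for v in per_level.values()) / n_zones
    zdn = sum(v**2 for v in per_dist.values()) / n_zones
    return {
        "GLDZM_GLNonuniformity": float(gln),
        "GLDZM_ZDNonuniformity": float(zdn),
    }


# ---------------------------------------------------------------------------
# NGLDM / NGTDM
# ---------------------------------------------------------------------------

def ngldm_matrix(levels: np.ndarray, n_bins: int) -> np.ndarray:
    """Dependence matrix s(i, j): voxels of level i with j = (dependent
    neighbor count) + 1, 26-neighborhood, alpha = 0 (equal levels depend)."""
    inmask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in _OFFSETS_26:
        src, dst = _shift_slices(levels.shape, d)
        eq = inmask[src] & inmask[dst] & (levels[src] == levels[dst])
        dep[src] += eq
    max_j = 27  # 26 neighbors + self
    mat = np.zeros((n_bins, max_j), dtype=np.float64)
    lv = levels[inmask] - 1
    jj = dep[inmask]  # j - 1 = dependent count
    np.add.at(mat, (lv, jj), 1.0)
    return mat


def ngldm_features(mat: np.ndarray) -> dict[str, float]:
    n_s = mat.sum()
    if n_s == 0:
        return {k: 0.0 for k in (
            "NGLD_HighGLCountEmpha", "NGLD_HighDepenHighFLEmpha",
            "NGLD_GLNonuniformity", "NGLD_DepCountNonuniformity")}
    i = np.arange(1, mat.shape[0] + 1, dtype=np.float64)
    j = np.arange(1, mat.shape[1] + 1, dtype=np.float64)
    si = mat.sum(axis=1)
    sj = mat.sum(axis=0)
    return {
        "NGLD_HighGLCountEmpha": float((si * i**2).sum() / n_s),
        "NGLD_HighDepenHighFLEmpha": float(
            ((i[:, None] ** 2 * j[None, :] ** 2) * mat).sum() / n_s
        ),
        "NGLD_GLNonuniformity": float((si**2).sum() / n_s),
        "NGLD_DepCountNonuniformity": float((sj**2).sum() / n_s),
    }


def ngtdm_coarseness(levels: np.ndarray, n_bins: int) -> float:
    """NGTDM coarseness 1 / (eps + sum_i p_i s_i) with eps = 1e-6.

    s_i sums |i - A(x)| over in-mask voxels of level i, where A(x) is the mean
    level of the in-mask 26-neighbors of x; voxels without any in-mask
    neighbor are excluded.
    """
    inmask = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.float64)
    for d in _OFFSETS_26:
        src, dst = _shift_slices(levels.shape, d)
        valid = inmask[src] & inmask[dst]
        nb_sum[src] += np.where(valid, levels[dst], 0)
        nb_cnt[src] += valid
    considered = inmask & (nb_cnt > 0)
    if not considered.any():
        return 1.0 / _COARSENESS_EPS
    avg = nb_sum[considered] / nb_cnt[considered]
    lv = levels[considered].astype(np.float64)
    n_total = considered.sum()
    acc = 0.0
    for level in np.unique(lv):
        sel = lv == level
        s_i = float(np.abs(level - avg[sel]).sum())
        acc += (sel.sum() / n_total) * s_i
    return 1.0 / (_COARSENESS_EPS + acc)
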