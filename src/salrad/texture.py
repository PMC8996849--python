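"""3D texture-matrix features on discretized gray levels.

All families operate on a :class:`~salrad.features.DiscretizedROI` (levels
1..n_bins inside the mask, 0 outside) and aggregate over the 13 unique 3D
directions by merging pair/run counts into a single matrix before computing
features (merged-direction aggregation). Zone families (GLSZM, GLDZM) use
26-connected components; neighborhood families (NGTDM, NGLDM) use the full
26-neighborhood.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "gldzm_matrix",
    "gldzm_features",
    "ngtdm_table",
    "ngtdm_features",
    "ngldm_matrix",
    "ngldm_features",
]

# 13 unique direction vectors covering the 26-neighborhood up to sign
DIRECTIONS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _offset_slices(shape, off):
    """Slices (a, b) such that arr[a] and arr[b] are voxel pairs v, v+off."""
    a, b = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            a.append(slice(0, n - o))
            b.append(slice(o, n))
        else:
            a.append(slice(-o, n))
            b.append(slice(0, n + o))
    return tuple(a), tuple(b)


# ------------------------------------------------------------------- GLCM

def glcm_matrix(roi, distance: int = 1) -> np.ndarray:
    """Symmetric gray-level co-occurrence matrix merged over 13 directions."""
    lev, mask, nb = roi.level_volume, roi.mask, roi.n_bins
    counts = np.zeros((nb, nb), dtype=np.float64)
    for off in DIRECTIONS_13:
        off = tuple(o * distance for o in off)
        a, b = _offset_slices(lev.shape, off)
        valid = mask[a] & mask[b]
        la = lev[a][valid] - 1
        lb = lev[b][valid] - 1
        np.add.at(counts, (la, lb), 1.0)
        np.add.at(counts, (lb, la), 1.0)
    return counts


def glcm_features(roi, distance: int = 1) -> dict[str, float]:
    counts = glcm_matrix(roi, distance)
    total = counts.sum()
    if total == 0:  # single-voxel-per-direction degenerate ROI
        return {k: 0.0 for k in _GLCM_KEYS}
    p = counts / total
    nb = p.shape[0]
    i = np.arange(1, nb + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu_i = (ii * p).sum()
    mu_j = (jj * p).sum()
    sd_i = np.sqrt((((ii - mu_i) ** 2) * p).sum())

    k_diff = np.arange(nb, dtype=np.float64)  # |i-j| = 0..nb-1
    p_diff = np.zeros(nb)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * nb + 1, dtype=np.float64)
    p_sum = np.zeros(2 * nb - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())

    nz = p > 0
    ent = float(-(p[nz] * np.log2(p[nz])).sum())
    diff_avg = float((k_diff * p_diff).sum())
    sum_avg = float((k_sum * p_sum).sum())
    dnz = p_diff > 0
    snz = p_sum > 0

    out: dict[str, float] = {
        "joint_max": float(p.max()),
        "joint_average": float(mu_i),
        "joint_variance": float((((ii - mu_i) ** 2) * p).sum()),
        "joint_entropy": ent,
        "difference_average": diff_avg,
        "difference_variance": float((((k_diff - diff_avg) ** 2) * p_diff).sum()),
        "difference_entropy": float(-(p_diff[dnz] * np.log2(p_diff[dnz])).sum()),
        "sum_average": sum_avg,
        "sum_variance": float((((k_sum - sum_avg) ** 2) * p_sum).sum()),
        "sum_entropy": float(-(p_sum[snz] * np.log2(p_sum[snz])).sum()),
        "angular_second_moment": float((p ** 2).sum()),
        "contrast": float((((ii - jj) ** 2) * p).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "inverse_difference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "inverse_difference_norm": float((p / (1.0 + np.abs(ii - jj) / nb)).sum()),
        "inverse_difference_moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "inverse_difference_moment_norm": float((p / (1.0 + ((ii - jj) / nb) ** 2)).sum()),
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float((((ii + jj - mu_i - mu_j) ** 2) * p).sum()),
        "cluster_shade": float((((ii + jj - mu_i - mu_j) ** 3) * p).sum()),
        "cluster_prominence": float((((ii + jj - mu_i - mu_j) ** 4) * p).sum()),
    }
    # inverse variance over off-diagonal entries
    off_diag = ii != jj
    out["inverse_variance"] = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum())
    # correlation (symmetric matrix: mu_i == mu_j, sd_i == sd_j)
    if sd_i > 0:
        out["correlation"] = float((((ii - mu_i) * (jj - mu_j) * p).sum()) / sd_i ** 2)
    else:
        out["correlation"] = 1.0
    # information measures of correlation
    pxi = px[:, None] * px[None, :]
    pnz = pxi > 0
    hxy1 = float(-(p[pnz] * np.log2(pxi[pnz])).sum())
    hxy2 = float(-(pxi[pnz] * np.log2(pxi[pnz])).sum())
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    out["information_corr1"] = (ent - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - ent))
    out["information_corr2"] = float(np.sqrt(max(arg, 0.0)))
    return out


_GLCM_KEYS = [
    "joint_max", "joint_average", "joint_variance", "joint_entropy",
    "difference_average", "difference_variance", "difference_entropy",
    "sum_average", "sum_variance", "sum_entropy", "angular_second_moment",
    "contrast", "dissimilarity", "inverse_difference", "inverse_difference_norm",
    "inverse_difference_moment", "inverse_difference_moment_norm",
    "autocorrelation", "cluster_tendency", "cluster_shade", "cluster_prominence",
    "inverse_variance", "correlation", "information_corr1", "information_corr2",
]


# ------------------------------------------------------------------ GLRLM

def glrlm_matrix(roi) -> np.ndarray:
    """Run-length matrix merged over 13 directions (rows: level, cols: length)."""
    lev, mask, nb = roi.level_volume, roi.mask, roi.n_bins
    shape = lev.shape
    max_len = int(np.ceil(np.linalg.norm(shape))) + 1
    counts = np.zeros((nb, max_len), dtype=np.float64)
    lev_m = np.where(mask, lev, 0)
    for off in DIRECTIONS_13:
        # same[v] == True when v and v+off are both in-mask with equal level
        same = np.zeros(shape, dtype=bool)
        a, b = _offset_slices(shape, off)
        same[a] = (lev_m[a] == lev_m[b]) & mask[a] & mask[b]
        # suffix run length via reverse sweep along the direction's first
        # nonzero axis: R[v] = 1 + R[v+off] if same[v] else 1
        run = np.ones(shape, dtype=np.int32)
        axis = next(k for k, o in enumerate(off) if o != 0)
        step = off[axis]
        order = range(shape[axis] - 1, -1, -1) if step > 0 else range(shape[axis])
        for t in order:
            tn = t + step
            if tn < 0 or tn >= shape[axis]:
                continue
            sl = [slice(None)] * 3
            sl[axis] = t
            sl = tuple(sl)
            sln = [slice(None)] * 3
            sln[axis] = tn
            # shift the remaining axes of the neighbor plane by the offset
            plane_next = run[tuple(sln)]
            rem = [k for k in range(3) if k != axis]
            for k, rk in enumerate(rem):
                o = off[rk]
                if o:
                    plane_next = _shift2(plane_next, k, -o)
            run[sl] = np.where(same[sl], plane_next + 1, 1)
        # run starts: in-mask voxels whose predecessor v-off is not part of the run
        prev_same = np.zeros(shape, dtype=bool)
        prev_same[b] = same[a]
        starts = mask & ~prev_same
        lv = lev_m[starts] - 1
        rl = run[starts] - 1  # length-1 as column index
        np.add.at(counts, (lv, np.minimum(rl, max_len - 1)), 1.0)
    used = np.flatnonzero(counts.sum(axis=0))
    return counts[:, : (used[-1] + 1)] if used.size else counts[:, :1]


def _shift2(arr: np.ndarray, axis: int, shift: int) -> np.ndarray:
    """Shift a 2D array filling with 0 (runs cannot continue off-grid)."""
    out = np.zeros_like(arr)
    if shift > 0:
        idx_dst = [slice(None)] * 2
        idx_src = [slice(None)] * 2
        idx_dst[axis] = slice(shift, None)
        idx_src[axis] = slice(0, -shift)
        out[tuple(idx_dst)] = arr[tuple(idx_src)]
    elif shift < 0:
        idx_dst = [slice(None)] * 2
        idx_src = [slice(None)] * 2
        idx_dst[axis] = slice(0, shift)
        idx_src[axis] = slice(-shift, None)
        out[tuple(idx_dst)] = arr[tuple(idx_src)]
    else:
        out = arr.copy()
    return out


# generic keys produced by _run_type_features, in order; each family maps
# them onto its conventional abbreviations
_GENERIC_KEYS = ("short_emph", "long_emph", "low_gl_emph", "high_gl_emph",
                 "short_low_gl", "short_high_gl", "long_low_gl", "long_high_gl",
                 "glnu", "glnu_norm", "lnu", "lnu_norm", "percentage",
                 "gl_variance", "len_variance", "entropy")

_FAMILY_KEYS = {
    "glrlm": ("sre", "lre", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
              "glnu", "glnu_norm", "rlnu", "rlnu_norm", "run_percentage",
              "gl_variance", "rl_variance", "run_entropy"),
    "glszm": ("sae", "lae", "lgze", "hgze", "salge", "sahge", "lalge", "lahge",
              "glnu", "glnu_norm", "zsnu", "zsnu_norm", "zone_percentage",
              "gl_variance", "zs_variance", "zone_entropy"),
    "gldzm": ("sde", "lde", "lgze", "hgze", "sdlge", "sdhge", "ldlge", "ldhge",
              "glnu", "glnu_norm", "zdnu", "zdnu_norm", "zone_percentage",
              "gl_variance", "zd_variance", "zd_entropy"),
    "ngldm": ("lde", "hde", "lgce", "hgce", "ldlge", "ldhge", "hdlge", "hdhge",
              "glnu", "glnu_norm", "dcnu", "dcnu_norm", "dependence_percentage",
              "gl_variance", "dc_variance", "dc_entropy"),
}


def _rekey(feats: dict[str, float], family: str) -> dict[str, float]:
    return dict(zip(_FAMILY_KEYS[family], feats.values()))


def _run_type_features(counts: np.ndarray, n_voxels: float) -> dict[str, float]:
    """Shared feature set for run/zone/dependence style matrices.

    ``counts`` rows index gray level (1..Ng), columns index run length /
    zone size / zone distance / dependence count (1..L). Keys are generic
    (:data:`_GENERIC_KEYS`); callers re-map them per family.
    """
    total = counts.sum()
    if total == 0:
        return {k: 0.0 for k in _GENERIC_KEYS}
    p = counts / total
    ng, nl = counts.shape
    g = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    l = np.arange(1, nl + 1, dtype=np.float64)[None, :]
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_g = (g[:, 0] * pg).sum()
    mu_l = (l[0] * pl).sum()
    nz = p > 0
    return {
        "short_emph": float((p / l ** 2).sum()),
        "long_emph": float((p * l ** 2).sum()),
        "low_gl_emph": float((p / g ** 2).sum()),
        "high_gl_emph": float((p * g ** 2).sum()),
        "short_low_gl": float((p / (g ** 2 * l ** 2)).sum()),
        "short_high_gl": float((p * g ** 2 / l ** 2).sum()),
        "long_low_gl": float((p * l ** 2 / g ** 2).sum()),
        "long_high_gl": float((p * g ** 2 * l ** 2).sum()),
        "glnu": float((counts.sum(axis=1) ** 2).sum() / total),
        "glnu_norm": float((pg ** 2).sum()),
        "lnu": float((counts.sum(axis=0) ** 2).sum() / total),
        "lnu_norm": float((pl ** 2).sum()),
        "percentage": float(total / n_voxels),
        "gl_variance": float((((g[:, 0] - mu_g) ** 2) * pg).sum()),
        "len_variance": float((((l[0] - mu_l) ** 2) * pl).sum()),
        "entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
    }


def glrlm_features(roi) -> dict[str, float]:
    counts = glrlm_matrix(roi)
    # merged over 13 directions: each voxel can appear in 13 runs
    return _rekey(_run_type_features(counts, 13.0 * roi.mask.sum()), "glrlm")


# ------------------------------------------------------------------ GLSZM

def _zones(roi):
    """26-connected zones of constant gray level: (level, size, zone_slices)."""
    lev, mask, nb = roi.level_volume, roi.mask, roi.n_bins
    out = []
    for g in np.unique(lev[mask]):
        lab, n = ndimage.label((lev == g) & mask, structure=_STRUCT26)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        out.append((int(g), sizes, lab, n))
    return out


def glszm_matrix(roi) -> np.ndarray:
    lev, mask, nb = roi.level_volume, roi.mask, roi.n_bins
    max_size = int(mask.sum())
    counts = np.zeros((nb, max_size), dtype=np.float64)
    for g, sizes, _, _ in _zones(roi):
        for s in sizes:
            counts[g - 1, s - 1] += 1.0
    used = np.flatnonzero(counts.sum(axis=0))
    return counts[:, : (used[-1] + 1)] if used.size else counts[:, :1]


def glszm_features(roi) -> dict[str, float]:
    counts = glszm_matrix(roi)
    return _rekey(_run_type_features(counts, float(roi.mask.sum())), "glszm")


# ------------------------------------------------------------------ GLDZM

def gldzm_matrix(roi) -> np.ndarray:
    """Gray-level distance-zone matrix: zone distance is the minimum
    city-block distance of any zone voxel to the ROI edge (edge voxels = 1)."""
    lev, mask, nb = roi.level_volume, roi.mask, roi.n_bins
    dist = ndimage.distance_transform_cdt(np.pad(mask, 1), metric="taxicab")
    dist = dist[1:-1, 1:-1, 1:-1]
    max_d = int(dist.max())
    counts = np.zeros((nb, max(max_d, 1)), dtype=np.float64)
    for g, sizes, lab, n in _zones(roi):
        mins = ndimage.minimum(dist, labels=lab, index=np.arange(1, n + 1))
        for dmin in np.atleast_1d(mins):
            counts[g - 1, int(dmin) - 1] += 1.0
    used = np.flatnonzero(counts.sum(axis=0))
    return counts[:, : (used[-1] + 1)] if used.size else counts[:, :1]


def gldzm_features(roi) -> dict[str, float]:
    counts = gldzm_matrix(roi)
    return _rekey(_run_type_features(counts, float(roi.mask.sum())), "gldzm")


# ------------------------------------------------------------------ NGTDM

def ngtdm_table(roi):
    """Per-level (count n_g, probability p_g, absolute deviation s_g)."""
    lev, mask, nb = roi.level_volume, roi.mask, roi.n_bins
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    lev_m = np.where(mask, lev, 0).astype(np.float64)
    nbr_sum = ndimage.correlate(lev_m, kernel, mode="constant")
    nbr_cnt = ndimage.correlate(mask.astype(np.float64), kernel, mode="constant")
    valid = mask & (nbr_cnt > 0)
    avg = np.zeros_like(lev_m)
    avg[valid] = nbr_sum[valid] / nbr_cnt[valid]
    dev = np.abs(lev - avg)
    n_g = np.zeros(nb)
    s_g = np.zeros(nb)
    for g in range(1, nb + 1):
        sel = valid & (lev == g)
        n_g[g - 1] = sel.sum()
        s_g[g - 1] = dev[sel].sum()
    return n_g, n_g / max(n_g.sum(), 1.0), s_g


def ngtdm_features(roi) -> dict[str, float]:
    n_g, p_g, s_g = ngtdm_table(roi)
    nb = len(n_g)
    g = np.arange(1, nb + 1, dtype=np.float64)
    present = p_g > 0
    n_tot = n_g.sum()
    ngp = int(present.sum())  # number of gray levels actually present
    eps = np.finfo(float).eps

    coarseness = 1.0 / max((p_g * s_g).sum(), eps)
    if ngp > 1:
        pi, pj = np.meshgrid(p_g, p_g, indexing="ij")
        gi, gj = np.meshgrid(g, g, indexing="ij")
        both = (pi > 0) & (pj > 0)
        contrast = ((pi * pj * (gi - gj) ** 2)[both].sum() / (ngp * (ngp - 1))
                    * s_g.sum() / n_tot)
        num = (np.abs(gi * pi - gj * pj))[both].sum()
        busyness = (p_g * s_g).sum() / num if num > 0 else 0.0
        si, sj = np.meshgrid(s_g, s_g, indexing="ij")
        ni, nj = np.meshgrid(n_g, n_g, indexing="ij")
        comp_num = (np.abs(gi - gj) * (pi * si + pj * sj))[both]
        complexity = (comp_num / (pi + pj)[both]).sum() / n_tot
        strength_num = ((pi + pj) * (gi - gj) ** 2)[both].sum()
        strength = strength_num / max(s_g.sum(), eps)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "coarseness": float(min(coarseness, 1e6)),
        "contrast": float(contrast),
        "busyness": float(busyness),
        "complexity": float(complexity),
        "strength": float(strength),
    }


# ------------------------------------------------------------------ NGLDM

def ngldm_matrix(roi, alpha: int = 0) -> np.ndarray:
    """Neighboring gray-level dependence matrix (26-neighborhood).

    Dependence of a voxel = number of in-mask neighbors whose level differs
    by at most ``alpha``; matrix rows index level, columns dependence k+1.
    """
    lev, mask, nb = roi.level_volume, roi.mask, roi.n_bins
    shape = lev.shape
    dep = np.zeros(shape, dtype=np.int32)
    for off in DIRECTIONS_13:
        for sgn in (1, -1):
            o = tuple(sgn * x for x in off)
            a, b = _offset_slices(shape, o)
            match = mask[a] & mask[b] & (np.abs(lev[a] - lev[b]) <= alpha)
            dep_a = np.zeros(shape, dtype=np.int32)
            dep_a[a] = match
            dep += dep_a
    counts = np.zeros((nb, 27), dtype=np.float64)
    lv = lev[mask] - 1
    dk = dep[mask]
    np.add.at(counts, (lv, dk), 1.0)
    used = np.flatnonzero(counts.sum(axis=0))
    return counts[:, : (used[-1] + 1)] if used.size else counts[:, :1]


def ngldm_features(roi, alpha: int = 0) -> dict[str, float]:
    counts = ngldm_matrix(roi, alpha)
    return _rekey(_run_type_features(counts, float(roi.mask.sum())), "ngldm")
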