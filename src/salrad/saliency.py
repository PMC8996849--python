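"""Context-aware saliency maps for tumor sub-region (habitat) analysis.

A local–global visual-attention model applied slice by slice to the cropped
tumor box. Each pixel's patch is compared, at several image scales, with its
K most similar patches; a pixel whose patch has no close matches anywhere is
salient. Patch dissimilarity trades intensity difference against positional
proximity,

    d(p_i, p_j) = d_intensity / (1 + c * d_position),

with Euclidean distances and c = 3. Single-scale saliency is
``1 - exp(-mean of the K smallest d)``; per-pixel saliency is averaged over
the image scales r in {1, 0.8, 0.5, 0.3}, then attenuated by the distance to
the nearest attention focus (pixels whose mean saliency exceeds 0.8):
``S = S_mean * (1 - d_foci)``.

The resulting map in [0, 1) drives six per-patient image types: the original
image (Origin), the saliency map itself (SalMap), high-/low-saliency
sub-regions of the tumor at a 0.5 threshold (highSal / lowSal), the
saliency-weighted image (SalxImg), and the sum of the weighted, normalized
PET and CT images (FusedImg).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.transform import resize

from .volume_io import Modality, TumorMask, VolumeImage

__all__ = [
    "SaliencyParams",
    "SaliencyMap",
    "SaliencyProducts",
    "normalize_slice",
    "normalize_volume",
    "patch_dissimilarity",
    "single_scale_saliency",
    "single_scale_saliency_bruteforce",
    "mean_saliency",
    "foci_weighting",
    "compute_saliency_slice",
    "compute_saliency_volume",
    "derive_products",
]

MIN_SUBREGION_VOXELS = 2


@dataclass(frozen=True)
class SaliencyParams:
    """Parameters of the context-aware saliency model.

    Defaults follow the published setting without tuning: c = 3 weighting
    position against intensity, four image scales for the query patch with
    patch edges 7/5/3/3, candidate patches drawn at relative scales
    {1, 1/2, 1/4} of the query-scale image, K = 64 most similar patches,
    attention-foci cutoff 0.8 on mean saliency, and a 0.5 split between
    high- and low-saliency sub-regions.
    """

    c: float = 3.0
    scales_r: tuple[float, ...] = (1.0, 0.8, 0.5, 0.3)
    patch_sizes: tuple[int, ...] = (7, 5, 3, 3)
    scales_s_rel: tuple[float, ...] = (1.0, 0.5, 0.25)
    K: int = 64
    foci_threshold: float = 0.8
    subregion_threshold: float = 0.5
    pool_scales: bool = True  # pool candidates across s-scales before taking K smallest

    def __post_init__(self) -> None:
        if len(self.scales_r) != len(self.patch_sizes):
            raise ValueError("scales_r and patch_sizes must have equal length")
        if any(not 0 < r <= 1 for r in self.scales_r):
            raise ValueError("scaling ratios must lie in (0, 1]")
        if any(not 0 < s <= 1 for s in self.scales_s_rel):
            raise ValueError("relative candidate scales must lie in (0, 1]")
        if any(p < 1 or p % 2 == 0 for p in self.patch_sizes):
            raise ValueError("patch sizes must be odd and positive")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (0 < self.foci_threshold < 1 and 0 < self.subregion_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class SaliencyMap:
    """Per-pixel saliency congruent with its source slice or volume."""

    values: np.ndarray
    params: SaliencyParams
    source_modality: Modality = Modality.DERIVED

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(vals)):
            raise ValueError("saliency values must be finite")
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("saliency values must lie in [0, 1]")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class SaliencyProducts:
    """The six image types derived for one modality of one patient."""

    origin: VolumeImage
    sal_map: SaliencyMap
    high_mask: TumorMask | None
    low_mask: TumorMask | None
    sal_x_img: VolumeImage
    high_usable: bool
    low_usable: bool


def normalize_slice(arr: np.ndarray) -> np.ndarray:
    """Min–max rescale to [0, 1]; a constant slice maps to all zeros."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi - lo <= 0:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def normalize_volume(img: VolumeImage) -> VolumeImage:
    """Min–max rescale a whole volume to [0, 1] (for weighting and fusion)."""
    return replace(img, voxels=normalize_slice(img.voxels), modality=Modality.DERIVED)


def patch_dissimilarity(pi: np.ndarray, pj: np.ndarray,
                        pos_i: np.ndarray, pos_j: np.ndarray, c: float = 3.0) -> float:
    """Dissimilarity of two flattened patches at diagonal-normalized positions."""
    pi = np.asarray(pi, dtype=np.float64).ravel()
    pj = np.asarray(pj, dtype=np.float64).ravel()
    if pi.shape != pj.shape:
        raise ValueError(f"patch length mismatch: {pi.shape} vs {pj.shape}")
    d_int = float(np.linalg.norm(pi - pj))
    d_pos = float(np.linalg.norm(np.asarray(pos_i, float) - np.asarray(pos_j, float)))
    return d_int / (1.0 + c * d_pos)


def _rescale(arr: np.ndarray, ratio: float) -> np.ndarray:
    if ratio == 1.0:
        return arr.astype(np.float64, copy=True)
    shape = tuple(max(1, int(np.floor(n * ratio + 0.5))) for n in arr.shape)
    return resize(arr, shape, order=1, mode="edge", anti_aliasing=False,
                  preserve_range=True).astype(np.float64)


def _patch_grid(img: np.ndarray, patch: int):
    """All fully-contained patches (stride 1) and their diagonal-normalized
    center positions. Returns (n, patch*patch) matrix, (n, 2) positions, and
    the shape of the interior grid of patch centers."""
    h, w = img.shape
    half = patch // 2
    gh, gw = h - 2 * half, w - 2 * half
    if gh < 1 or gw < 1:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(img, (patch, patch))
    vecs = windows.reshape(gh * gw, patch * patch)
    diag = float(np.hypot(h, w))
    rr, cc = np.meshgrid(np.arange(gh) + half, np.arange(gw) + half, indexing="ij")
    pos = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(np.float64) / diag
    return vecs, pos, (gh, gw)


def _fill_borders(core: np.ndarray, shape: tuple[int, int], half: int) -> np.ndarray:
    """Embed the interior grid of computed values into the full slice shape,
    border pixels inheriting the nearest computed value (edge replication)."""
    gh, gw = core.shape
    pad = ((half, shape[0] - gh - half), (half, shape[1] - gw - half))
    return np.pad(core, pad, mode="edge")


def single_scale_saliency(slice_01: np.ndarray, r: float,
                          params: SaliencyParams | None = None,
                          patch: int | None = None) -> np.ndarray | None:
    """Saliency of every pixel at one image scale r (vectorized).

    The slice (already in [0, 1]) is rescaled by r; query patches p_i are
    taken densely from that image. Candidate patches p_j come from the
    query-scale image further rescaled by each relative ratio in
    ``scales_s_rel``, compared at the same pixel patch size. For each query
    the K smallest dissimilarities (pooled over candidate scales, the query
    patch itself excluded) are averaged into ``1 - exp(-mean)``; the map is
    upsampled bilinearly to the input shape. Returns None when the patch no
    longer fits at this scale.
    """
    params = params or SaliencyParams()
    if patch is None:
        patch = params.patch_sizes[params.scales_r.index(r)]
    base = _rescale(np.asarray(slice_01, dtype=np.float64), r)
    query = _patch_grid(base, patch)
    if query is None:
        warnings.warn(f"patch {patch} does not fit slice scaled by {r}; scale skipped")
        return None
    q_vecs, q_pos, grid_shape = query

    cand_blocks = []
    for idx, s_rel in enumerate(params.scales_s_rel):
        cand_img = _rescale(base, s_rel)
        cand = _patch_grid(cand_img, patch)
        if cand is None:
            continue
        c_vecs, c_pos, _ = cand
        d_int = cdist(q_vecs, c_vecs)
        d_pos = cdist(q_pos, c_pos)
        d = d_int / (1.0 + params.c * d_pos)
        if s_rel == 1.0:
            # exclude the query patch itself from its own candidate pool
            np.fill_diagonal(d, np.inf)
        cand_blocks.append(d)
    if not cand_blocks:
        warnings.warn(f"no candidate scale fits slice scaled by {r}; scale skipped")
        return None

    if params.pool_scales:
        pooled = np.concatenate(cand_blocks, axis=1)
        core = 1.0 - np.exp(-_mean_k_smallest(pooled, params.K))
    else:
        per_scale = [1.0 - np.exp(-_mean_k_smallest(b, params.K)) for b in cand_blocks]
        core = np.mean(per_scale, axis=0)

    core = core.reshape(grid_shape)
    full = _fill_borders(core, base.shape, patch // 2)
    if full.shape != slice_01.shape:
        full = resize(full, slice_01.shape, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    return np.clip(full, 0.0, 1.0)


def _mean_k_smallest(d: np.ndarray, k: int) -> np.ndarray:
    """Row-wise mean of the k smallest finite entries (all if fewer)."""
    finite = np.isfinite(d)
    n_finite = finite.sum(axis=1)
    k_eff = min(k, int(n_finite.min()))
    if k_eff < 1:
        return np.zeros(d.shape[0])
    part = np.partition(d, k_eff - 1, axis=1)[:, :k_eff]
    out = part.mean(axis=1)
    # rows with fewer than k finite candidates: average all finite ones
    short = n_finite < k
    if short.any():
        dd = np.where(finite, d, 0.0)
        out[short] = dd[short].sum(axis=1) / n_finite[short]
    return out


def single_scale_saliency_bruteforce(slice_01: np.ndarray, r: float,
                                     params: SaliencyParams | None = None,
                                     patch: int | None = None) -> np.ndarray | None:
    """Naive all-pairs reference for :func:`single_scale_saliency`.

    Loops over every query/candidate patch pair with
    :func:`patch_dissimilarity`. Intended for small slices in tests only.
    """
    params = params or SaliencyParams()
    if patch is None:
        patch = params.patch_sizes[params.scales_r.index(r)]
    base = _rescale(np.asarray(slice_01, dtype=np.float64), r)
    query = _patch_grid(base, patch)
    if query is None:
        return None
    q_vecs, q_pos, grid_shape = query

    cands = []  # (vec, pos, is_self_scale, index)
    for s_rel in params.scales_s_rel:
        cand = _patch_grid(_rescale(base, s_rel), patch)
        if cand is None:
            continue
        c_vecs, c_pos, _ = cand
        for j in range(c_vecs.shape[0]):
            cands.append((c_vecs[j], c_pos[j], s_rel == 1.0, j))
    if not cands:
        return None

    core = np.empty(q_vecs.shape[0])
    for i in range(q_vecs.shape[0]):
        dists = [patch_dissimilarity(q_vecs[i], v, q_pos[i], p, params.c)
                 for v, p, self_scale, j in cands
                 if not (self_scale and j == i)]
        dists.sort()
        take = dists[: params.K] if len(dists) >= params.K else dists
        core[i] = 1.0 - np.exp(-float(np.mean(take)))
    core = core.reshape(grid_shape)
    full = _fill_borders(core, base.shape, patch // 2)
    if full.shape != slice_01.shape:
        full = resize(full, slice_01.shape, order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    return np.clip(full, 0.0, 1.0)


def mean_saliency(maps: list[np.ndarray]) -> np.ndarray:
    """Pixelwise arithmetic mean over the per-scale saliency maps."""
    if not maps:
        raise ValueError("no saliency maps to average")
    stack = np.stack([np.asarray(m, dtype=np.float64) for m in maps])
    return stack.mean(axis=0)


def foci_weighting(mean_map: np.ndarray, foci_threshold: float = 0.8) -> np.ndarray:
    """Attenuate mean saliency by distance to the nearest attention focus.

    Foci are pixels with mean saliency above the threshold; when none
    exceed it the argmax pixel(s) serve as foci so the weighting stays
    defined. Distances are Euclidean in pixels, normalized by the slice
    diagonal, giving S = S_mean * (1 - d_foci).
    """
    m = np.asarray(mean_map, dtype=np.float64)
    foci = m > foci_threshold
    if not foci.any():
        foci = m >= m.max()
    d = ndimage.distance_transform_edt(~foci)
    d /= float(np.hypot(*m.shape))
    return m * (1.0 - d)


def compute_saliency_slice(raw_slice: np.ndarray,
                           params: SaliencyParams | None = None) -> np.ndarray:
    """Full 2D pipeline: normalize, multi-scale saliency, mean, foci weighting."""
    params = params or SaliencyParams()
    norm = normalize_slice(raw_slice)
    per_scale = []
    for r, patch in zip(params.scales_r, params.patch_sizes):
        m = single_scale_saliency(norm, r, params, patch)
        if m is not None:
            per_scale.append(m)
    if not per_scale:
        return np.zeros_like(norm)
    return foci_weighting(mean_saliency(per_scale), params.foci_threshold)


def compute_saliency_volume(img: VolumeImage, mask: TumorMask,
                            params: SaliencyParams | None = None) -> SaliencyMap:
    """Slice-by-slice saliency over the cropped tumor box.

    Axial slices (fixed z) with no tumor voxel are set to zero; the others
    run the full 2D pipeline on the raw slice intensities.
    """
    params = params or SaliencyParams()
    if img.shape != mask.shape:
        raise ValueError("image and mask must be congruent")
    if not mask.voxels.any():
        raise ValueError("empty tumor mask")
    out = np.zeros(img.shape, dtype=np.float64)
    for z in range(img.shape[2]):
        if not mask.voxels[:, :, z].any():
            continue
        out[:, :, z] = compute_saliency_slice(img.voxels[:, :, z], params)
    return SaliencyMap(out, params, img.modality)


def _split_masks(sal: SaliencyMap, mask: TumorMask, thr: float):
    high = mask.voxels & (sal.values > thr)
    low = mask.voxels & ~high
    def as_mask(m, tag):
        return TumorMask(m, mask.spacing, label=f"{mask.label}_{tag}") if m.any() else None
    return as_mask(high, "highSal"), as_mask(low, "lowSal"), high.sum(), low.sum()


def derive_products(img: VolumeImage, sal: SaliencyMap, mask: TumorMask,
                    params: SaliencyParams | None = None) -> SaliencyProducts:
    """Derive one modality's image types from its saliency map.

    high/low sub-region masks partition the tumor mask at the sub-region
    threshold; SalxImg multiplies the [0,1]-normalized image by the map.
    Sub-regions smaller than two voxels are flagged unusable for feature
    extraction rather than silently dropped.
    """
    params = params or sal.params
    if img.shape != sal.values.shape or img.shape != mask.shape:
        raise ValueError("image, saliency map and mask must be congruent")
    high, low, n_hi, n_lo = _split_masks(sal, mask, params.subregion_threshold)
    norm = normalize_volume(img)
    weighted = replace(norm, voxels=norm.voxels * sal.values)
    return SaliencyProducts(
        origin=img, sal_map=sal, high_mask=high, low_mask=low,
        sal_x_img=weighted,
        high_usable=n_hi >= MIN_SUBREGION_VOXELS,
        low_usable=n_lo >= MIN_SUBREGION_VOXELS,
    )


def fuse_images(pet_products: SaliencyProducts, ct_products: SaliencyProducts) -> VolumeImage:
    """Fused PET-CT image: sum of the saliency-weighted, normalized modalities."""
    if pet_products.sal_x_img.shape != ct_products.sal_x_img.shape:
        raise ValueError("PET and CT grids must be congruent for fusion")
    fused = pet_products.sal_x_img.voxels + ct_products.sal_x_img.voxels
    return replace(pet_products.sal_x_img, voxels=fused, modality=Modality.DERIVED)
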