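"""IBSI-style radiomics feature extraction.

Features are computed on an isotropic grid from the in-mask voxels of one
image type. Intensities are discretized with a fixed bin number (default 64)
before any texture matrix is built. The default configuration covers
morphology, intensity statistics, the intensity histogram, and the 3D
merged-direction texture families (GLCM, GLRLM, GLSZM, GLDZM, NGTDM, NGLDM).

Feature names are ``family.feature`` (e.g. ``glcm.contrast``); the name
order is fixed by the configuration so vectors from different patients
align column-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import ConvexHull
from skimage import measure

from . import texture
from .volume_io import TumorMask, VolumeImage

__all__ = [
    "FeatureConfig",
    "DiscretizedROI",
    "FeatureVector",
    "discretize_fbn",
    "extract_features",
    "feature_names",
]

ALL_FAMILIES = ("morph", "stat", "ih", "glcm", "glrlm", "glszm", "gldzm", "ngtdm", "ngldm")
MIN_MASK_VOXELS = 2


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature families to compute and how to discretize."""

    n_bins: int = 64
    families: tuple[str, ...] = ALL_FAMILIES

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        unknown = set(self.families) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")


@dataclass(frozen=True)
class DiscretizedROI:
    """Integer gray levels 1..n_bins over the mask voxels.

    ``level_volume`` is the full grid with 0 outside the mask, which is what
    the texture-matrix builders consume; ``levels`` is the flat in-mask
    vector.
    """

    level_volume: np.ndarray
    mask: np.ndarray
    n_bins: int
    bin_edges: np.ndarray

    @property
    def levels(self) -> np.ndarray:
        return self.level_volume[self.mask]


@dataclass(frozen=True)
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray
    missing: bool = False

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature names must be unique")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if len(self.names) != self.values.size:
            raise ValueError("names/values length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def discretize_fbn(img: VolumeImage, mask: TumorMask, n_bins: int = 64) -> DiscretizedROI:
    """Fixed-bin-number discretization of in-mask intensities.

    level = min(n_bins, floor(n_bins * (x - min) / (max - min)) + 1); a
    constant ROI maps to level 1 everywhere.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if img.shape != mask.shape:
        raise ValueError("image and mask must be congruent")
    m = mask.voxels
    vals = img.voxels[m]
    lo, hi = float(vals.min()), float(vals.max())
    lev = np.zeros(img.shape, dtype=np.int32)
    if hi - lo <= 0:
        lev[m] = 1
        edges = np.array([lo, hi])
    else:
        lev[m] = np.minimum(n_bins, np.floor(n_bins * (img.voxels[m] - lo) / (hi - lo)).astype(np.int64) + 1)
        edges = np.linspace(lo, hi, n_bins + 1)
    return DiscretizedROI(lev, m, n_bins, edges)


# ---------------------------------------------------------------- morphology

def _morphology(mask: TumorMask) -> dict[str, float]:
    m = mask.voxels
    sp = np.asarray(mask.spacing)
    n = int(m.sum())
    voxel_vol = float(np.prod(sp))
    volume = n * voxel_vol

    coords = np.argwhere(m) * sp  # physical mm
    out: dict[str, float] = {"volume": volume, "voxel_count": float(n)}

    # surface area from a triangulated mesh of the padded mask
    padded = np.pad(m.astype(np.float64), 1)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(sp))
        area = float(measure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        # degenerate mask (e.g. single voxel plane); fall back to voxel faces
        area = _voxel_surface_area(m, sp)
    out["surface_area"] = area
    out["surface_to_volume"] = area / volume
    out["sphericity"] = (36.0 * np.pi * volume ** 2) ** (1.0 / 3.0) / area
    out["compactness2"] = 36.0 * np.pi * volume ** 2 / area ** 3
    out["spherical_disproportion"] = area / (36.0 * np.pi * volume ** 2) ** (1.0 / 3.0)

    # maximum 3D diameter via convex hull vertices
    if n >= 5 and not _coplanar(coords):
        try:
            hull_pts = coords[ConvexHull(coords).vertices]
        except Exception:
            hull_pts = coords
    else:
        hull_pts = coords
    d = np.linalg.norm(hull_pts[:, None, :] - hull_pts[None, :, :], axis=2)
    out["max_diameter_3d"] = float(d.max())

    # principal axes from the voxel-coordinate covariance
    if n >= 2:
        cov = np.cov(coords.T, bias=False)
        eig = np.sort(np.maximum(np.linalg.eigvalsh(np.atleast_2d(cov)), 0.0))[::-1]
    else:
        eig = np.zeros(3)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    out["major_axis_length"] = major
    out["minor_axis_length"] = minor
    out["least_axis_length"] = least
    out["elongation"] = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    out["flatness"] = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0
    return out


def _coplanar(coords: np.ndarray) -> bool:
    return any((coords[:, ax] == coords[0, ax]).all() for ax in range(coords.shape[1]))


def _voxel_surface_area(m: np.ndarray, sp: np.ndarray) -> float:
    face_areas = [sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1]]
    total = 0.0
    for ax in range(3):
        shifted = np.zeros_like(m)
        diff = np.diff(m.astype(np.int8), axis=ax, prepend=0, append=0)
        total += np.abs(diff).sum() * face_areas[ax]
    return float(total)


# ---------------------------------------------------- intensity statistics

def _intensity_stats(vals: np.ndarray, voxel_vol: float) -> dict[str, float]:
    n = vals.size
    mean = float(vals.mean())
    var = float(vals.var())  # population variance
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(vals, [10, 25, 50, 75, 90])
    out = {
        "mean": mean,
        "variance": var,
        "skewness": float(stats.skew(vals)) if sd > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(vals)) if sd > 0 else 0.0,
        "median": float(p50),
        "minimum": float(vals.min()),
        "p10": float(p10),
        "p90": float(p90),
        "maximum": float(vals.max()),
        "interquartile_range": float(p75 - p25),
        "range": float(vals.max() - vals.min()),
        "mean_absolute_deviation": float(np.abs(vals - mean).mean()),
        "energy": float((vals ** 2).sum()),
        "root_mean_square": float(np.sqrt((vals ** 2).mean())),
    }
    sub = vals[(vals >= p10) & (vals <= p90)]
    out["robust_mean_absolute_deviation"] = (
        float(np.abs(sub - sub.mean()).mean()) if sub.size else 0.0)
    out["coefficient_of_variation"] = sd / mean if mean != 0 else 0.0
    out["quartile_coefficient_of_dispersion"] = (
        float((p75 - p25) / (p75 + p25)) if (p75 + p25) != 0 else 0.0)
    out["total_energy"] = out["energy"] * voxel_vol
    return out


# ---------------------------------------------------- intensity histogram

def _intensity_histogram(roi: DiscretizedROI) -> dict[str, float]:
    lev = roi.levels
    nb = roi.n_bins
    counts = np.bincount(lev, minlength=nb + 1)[1:].astype(np.float64)
    p = counts / counts.sum()
    g = np.arange(1, nb + 1, dtype=np.float64)
    mean = float((g * p).sum())
    var = float(((g - mean) ** 2 * p).sum())
    sd = np.sqrt(var)
    nz = p > 0
    out = {
        "mean": mean,
        "variance": var,
        "skewness": float((((g - mean) / sd) ** 3 * p).sum()) if sd > 0 else 0.0,
        "kurtosis": float((((g - mean) / sd) ** 4 * p).sum() - 3.0) if sd > 0 else 0.0,
        "median": float(np.median(lev)),
        "minimum": float(lev.min()),
        "p10": float(np.percentile(lev, 10)),
        "p90": float(np.percentile(lev, 90)),
        "maximum": float(lev.max()),
        "mode": float(np.argmax(counts) + 1),
        "interquartile_range": float(np.percentile(lev, 75) - np.percentile(lev, 25)),
        "range": float(lev.max() - lev.min()),
        "mean_absolute_deviation": float(np.abs(lev - mean).mean()),
        "entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "uniformity": float((p ** 2).sum()),
    }
    grad = np.gradient(counts) if nb > 1 else np.zeros(1)
    out["max_gradient"] = float(grad.max())
    out["max_gradient_level"] = float(np.argmax(grad) + 1)
    out["min_gradient"] = float(grad.min())
    out["min_gradient_level"] = float(np.argmin(grad) + 1)
    return out


# ------------------------------------------------------------ orchestration

def feature_names(config: FeatureConfig | None = None) -> tuple[str, ...]:
    """The fixed, ordered feature-name list for a configuration."""
    config = config or FeatureConfig()
    dummy_img = VolumeImage(np.arange(27, dtype=float).reshape(3, 3, 3), (1, 1, 1))
    dummy_mask = TumorMask(np.ones((3, 3, 3), bool), (1, 1, 1))
    return extract_features(dummy_img, dummy_mask, config).names


def extract_features(img: VolumeImage, mask: TumorMask,
                     config: FeatureConfig | None = None) -> FeatureVector:
    """Extract the configured feature families from one ROI.

    A mask below two voxels cannot support texture statistics; the vector is
    returned all-NaN with ``missing=True`` so tabulation stays aligned.
    """
    config = config or FeatureConfig()
    if img.shape != mask.shape:
        raise ValueError("image and mask must be congruent")
    if mask.n_voxels < MIN_MASK_VOXELS:
        names = feature_names(config)
        return FeatureVector(names, np.full(len(names), np.nan), missing=True)

    vals = img.voxels[mask.voxels]
    roi = discretize_fbn(img, mask, config.n_bins)
    voxel_vol = float(np.prod(mask.spacing))

    blocks: dict[str, dict[str, float]] = {}
    for fam in config.families:
        if fam == "morph":
            blocks[fam] = _morphology(mask)
        elif fam == "stat":
            blocks[fam] = _intensity_stats(vals, voxel_vol)
        elif fam == "ih":
            blocks[fam] = _intensity_histogram(roi)
        elif fam == "glcm":
            blocks[fam] = texture.glcm_features(roi)
        elif fam == "glrlm":
            blocks[fam] = texture.glrlm_features(roi)
        elif fam == "glszm":
            blocks[fam] = texture.glszm_features(roi)
        elif fam == "gldzm":
            blocks[fam] = texture.gldzm_features(roi)
        elif fam == "ngtdm":
            blocks[fam] = texture.ngtdm_features(roi)
        elif fam == "ngldm":
            blocks[fam] = texture.ngldm_features(roi)

    names: list[str] = []
    values: list[float] = []
    for fam in config.families:
        for k, v in blocks[fam].items():
            names.append(f"{fam}.{k}")
            values.append(v)
    return FeatureVector(tuple(names), np.array(values))
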