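"""Volume I/O and preprocessing for paired PET/CT tumor analysis.

Volumes are held as :class:`VolumeImage` — a 3D array indexed ``(x, y, z)``
with per-axis voxel spacing in mm, matching the NIfTI header order. PET
voxels are standardized uptake values (SUV) after :func:`to_suv`; CT voxels
are Hounsfield units, truncated to the soft-tissue window (-200, 300) HU by
:func:`truncate_ct` to suppress air and bone before saliency computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Modality",
    "VolumeImage",
    "TumorMask",
    "SuvParams",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "to_suv",
    "truncate_ct",
    "crop_to_bbox",
    "resample_isotropic",
]

CT_WINDOW = (-200.0, 300.0)


class Modality(str, Enum):
    PET = "PET"
    CT = "CT"
    DERIVED = "DERIVED"


class VolumeFormatError(ValueError):
    """Raised for inputs that are not usable 3D volumes."""


@dataclass(frozen=True)
class VolumeImage:
    """A 3D scalar volume with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities: SUV for PET, HU for CT, arbitrary for derived
        images (saliency maps, weighted or fused images).
    spacing : tuple of float
        Voxel edge lengths in mm along (x, y, z); strictly positive.
    modality : Modality
    origin : tuple of float
        Physical offset in mm, carried through but never interpreted.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality = Modality.DERIVED
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=np.float64)
        if vox.ndim != 3:
            raise VolumeFormatError(f"expected a 3D volume, got ndim={vox.ndim}")
        if not np.all(np.isfinite(vox)):
            raise VolumeFormatError("volume contains non-finite voxels")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise VolumeFormatError(f"spacing must be 3 positive floats, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class TumorMask:
    """Binary tumor mask congruent with its VolumeImage."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    label: str = "GTV"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels) > 0
        if vox.ndim != 3:
            raise VolumeFormatError(f"mask must be 3D, got ndim={vox.ndim}")
        if not vox.any():
            raise VolumeFormatError("mask has no nonzero voxel")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class SuvParams:
    """Decay-corrected body-weight SUV normalization parameters.

    injected_dose in Bq, body_weight in kg, decay_interval (injection to
    acquisition) and half_life in seconds.
    """

    injected_dose: float
    body_weight: float
    decay_interval: float = 0.0
    half_life: float = 6586.2  # 18F

    def __post_init__(self) -> None:
        if self.injected_dose <= 0 or self.body_weight <= 0 or self.half_life <= 0:
            raise ValueError("SUV parameters must be positive")
        if self.decay_interval < 0:
            raise ValueError("decay interval must be nonnegative")


def read_volume(path: str | Path, modality: Modality | str = Modality.DERIVED) -> VolumeImage:
    """Read a 3D NIfTI volume; spacing comes from the header zooms.

    The array is indexed (x, y, z) in the header's on-disk order.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D data, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: missing or invalid voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VolumeImage(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms),
                       Modality(modality), origin)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(img: VolumeImage, path: str | Path) -> None:
    nii = nib.Nifti1Image(img.voxels.astype(np.float32), _affine(img.spacing, img.origin))
    nii.header.set_zooms(img.spacing)
    nib.save(nii, str(path))


def read_mask(path: str | Path, label: str = "GTV") -> TumorMask:
    vol = read_volume(path, Modality.DERIVED)
    return TumorMask(vol.voxels > 0.5, vol.spacing, label=label)


def write_mask(mask: TumorMask, path: str | Path) -> None:
    nii = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing, (0, 0, 0)))
    nii.header.set_zooms(mask.spacing)
    nib.save(nii, str(path))


def to_suv(pet: VolumeImage, params: SuvParams) -> VolumeImage:
    """Convert PET activity concentration (Bq/mL) to body-weight SUV.

    SUV = activity * body_weight[g] / (injected_dose * 2^(-dt / T_half)),
    i.e. the injected dose is decay-corrected to acquisition time. Assumes
    tissue density 1 g/mL so SUV is dimensionless.
    """
    if pet.modality is not Modality.PET:
        raise ValueError(f"to_suv expects a PET volume, got {pet.modality}")
    decayed_dose = params.injected_dose * 2.0 ** (-params.decay_interval / params.half_life)
    suv = pet.voxels * (params.body_weight * 1000.0) / decayed_dose
    suv = np.maximum(suv, 0.0)
    return replace(pet, voxels=suv)


def truncate_ct(ct: VolumeImage, window: tuple[float, float] = CT_WINDOW) -> VolumeImage:
    """Clip CT Hounsfield units to the (-200, 300) soft-tissue window."""
    if ct.modality is not Modality.CT:
        raise ValueError(f"truncate_ct expects a CT volume, got {ct.modality}")
    lo, hi = window
    return replace(ct, voxels=np.clip(ct.voxels, lo, hi))


def bbox_slices(mask_voxels: np.ndarray, margin: int = 0) -> tuple[slice, slice, slice]:
    """Minimal axis-aligned bounding box of the nonzero voxels, expanded by
    ``margin`` voxels per side and clipped to the array bounds."""
    if not mask_voxels.any():
        raise ValueError("empty mask has no bounding box")
    slc = []
    for ax in range(3):
        proj = np.any(mask_voxels, axis=tuple(a for a in range(3) if a != ax))
        idx = np.flatnonzero(proj)
        lo = max(0, int(idx[0]) - margin)
        hi = min(mask_voxels.shape[ax], int(idx[-1]) + 1 + margin)
        slc.append(slice(lo, hi))
    return tuple(slc)


def crop_to_bbox(img: VolumeImage, mask: TumorMask, margin: int = 0) -> tuple[VolumeImage, TumorMask]:
    """Crop image and mask to the smallest box covering the tumor."""
    if img.shape != mask.shape:
        raise ValueError(f"image shape {img.shape} != mask shape {mask.shape}")
    slc = bbox_slices(mask.voxels, margin)
    return (replace(img, voxels=img.voxels[slc].copy()),
            TumorMask(mask.voxels[slc].copy(), mask.spacing, label=mask.label))


def _resampled_shape(shape, spacing, target: float) -> tuple[int, ...]:
    # round-half-up of physical extent / target spacing, at least 1 voxel
    return tuple(max(1, int(math.floor(n * s / target + 0.5))) for n, s in zip(shape, spacing))


def resample_isotropic(img: VolumeImage, mask: TumorMask | None = None,
                       target: float = 1.0) -> tuple[VolumeImage, TumorMask | None]:
    """Resample to an isotropic grid: trilinear for the image, nearest
    neighbor for the mask. Output spacing is (target, target, target)."""
    if target <= 0:
        raise ValueError("target spacing must be positive")
    new_shape = _resampled_shape(img.shape, img.spacing, target)
    if new_shape == img.shape and all(abs(s - target) < 1e-12 for s in img.spacing):
        return (replace(img, spacing=(target,) * 3),
                None if mask is None else TumorMask(mask.voxels.copy(), (target,) * 3, mask.label))

    def sample_coords(n_old: int, n_new: int) -> np.ndarray:
        # align grids by physical extent: new voxel centers mapped into old index space
        scale = n_old / n_new
        return (np.arange(n_new) + 0.5) * scale - 0.5

    grids = np.meshgrid(*[sample_coords(o, n) for o, n in zip(img.shape, new_shape)],
                        indexing="ij")
    coords = np.stack([g.ravel() for g in grids])
    new_vox = ndimage.map_coordinates(img.voxels, coords, order=1, mode="nearest")
    out_img = replace(img, voxels=new_vox.reshape(new_shape), spacing=(target,) * 3)
    out_mask = None
    if mask is not None:
        if mask.shape != img.shape:
            raise ValueError("mask not congruent with image")
        m = ndimage.map_coordinates(mask.voxels.astype(np.float64), coords, order=0,
                                    mode="nearest")
        out_mask = TumorMask(m.reshape(new_shape) > 0.5, (target,) * 3, mask.label)
    return out_img, out_mask
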