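"""Image preprocessing for PET (SUV) and contrast-enhanced T1-w MRI.

Pipeline order for MRI: bias correction -> soft-tissue masking -> z-score
normalisation inside the mask.  PET: SUV truncation to [0, 10] followed by
scaling to [0, 1].  Both modalities are then resampled to isotropic
spacing (trilinear for images, nearest-neighbour for masks) before LoG
filtering, feature extraction or patch extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature as skfeature

from .volume import RoiMask, Volume

__all__ = [
    "PreprocessConfig",
    "pet_normalize",
    "soft_tissue_mask",
    "bias_correct",
    "zscore_in_mask",
    "resample_trilinear",
    "resample_mask_nearest",
    "log_filter",
    "extract_patch",
]


@dataclass
class PreprocessConfig:
    suv_trunc_range: tuple[float, float] = (0.0, 10.0)
    pet_target_spacing_mm: float = 2.0
    mri_target_spacing_mm: float = 1.0
    dl_spacing_mm: float = 2.0
    patch_shape: tuple[int, int, int] = (60, 60, 44)
    log_sigma_pet_mm: float = 2.0
    log_sigma_mri_mm: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.suv_trunc_range
        if lo >= hi:
            raise ValueError("suv_trunc_range must satisfy low < high")
        for s in (self.pet_target_spacing_mm, self.mri_target_spacing_mm,
                  self.dl_spacing_mm):
            if s <= 0:
                raise ValueError("target spacings must be positive")


def pet_normalize(pet: Volume, cfg: PreprocessConfig | None = None) -> Volume:
    """Truncate SUV to the configured range and scale to [0, 1]."""
    cfg = cfg or PreprocessConfig()
    lo, hi = cfg.suv_trunc_range
    data = np.clip(pet.data, lo, hi)
    return pet.copy_with((data - lo) / (hi - lo))


def soft_tissue_mask(mri: Volume, canny_sigma_vox: float = 1.0) -> RoiMask:
    """Head/soft-tissue mask via per-axial-slice Canny edges.

    Edges are detected slice by slice (sigma = 1 voxel, hysteresis
    thresholds at 10%/20% of the slice maximum gradient response), the
    edge contours are closed and hole-filled per slice, and the largest
    3-D connected component is kept.  On an edge-free (constant) volume
    the fallback is the full grid.
    """
    data = mri.data
    if not np.any(data):
        raise ValueError("cannot mask an all-zero volume")
    edges = np.zeros(data.shape, dtype=bool)
    for k in range(data.shape[2]):
        sl = data[:, :, k]
        if np.ptp(sl) <= 0:
            continue
        # rescale the slice to [0,1] so the 10%/20% hysteresis thresholds
        # refer to the slice maximum rather than absolute units
        edges[:, :, k] = skfeature.canny(
            (sl - sl.min()) / np.ptp(sl), sigma=canny_sigma_vox,
            low_threshold=0.10, high_threshold=0.20, mode="constant", cval=0.0)
    if not edges.any():
        return RoiMask(np.ones(data.shape, dtype=bool), mri.spacing, mri.origin)
    filled = np.zeros_like(edges)
    for k in range(data.shape[2]):
        filled[:, :, k] = ndimage.binary_fill_holes(
            ndimage.binary_closing(edges[:, :, k], structure=np.ones((3, 3), bool)))
    labels, n = ndimage.label(filled)
    if n == 0:
        return RoiMask(np.ones(data.shape, dtype=bool), mri.spacing, mri.origin)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return RoiMask(labels == int(np.argmax(counts)), mri.spacing, mri.origin)


_POLY2_POWERS = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)
                 if i + j + k <= 2]


def _poly2_design(shape, mask):
    coords = [(np.arange(n) - (n - 1) / 2.0) / max(n - 1, 1) for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    cols = [(x**i) * (y**j) * (z**k) for i, j, k in _POLY2_POWERS]
    full = np.stack([c.ravel() for c in cols], axis=1)
    return full, np.stack([c[mask] for c in cols], axis=1)


def bias_correct(mri: Volume, mask: RoiMask, min_voxels: int = 10
                 ) -> tuple[Volume, Volume]:
    """Estimate and divide out a smooth multiplicative intensity field.

    The log-intensity inside the mask is fitted with a degree-2 polynomial
    by least squares; the exponentiated fit (normalised to unit geometric
    mean inside the mask) is the field estimate, which is strictly
    positive.  Returns ``(corrected, field)``.  This is a deliberately
    simple smooth-field estimator adequate for low-order phantom fields;
    it can be bypassed entirely by skipping the call.
    """
    if mask.n_voxels < min_voxels:
        raise ValueError(f"mask has {mask.n_voxels} voxels; need >= {min_voxels}")
    m = mask.data
    data = mri.data
    pos_floor = max(np.percentile(data[m], 1) * 1e-3, 1e-6)
    logv = np.log(np.maximum(data, pos_floor))
    full_design, masked_design = _poly2_design(data.shape, m)
    coef, *_ = np.linalg.lstsq(masked_design, logv[m], rcond=None)
    log_field = (full_design @ coef).reshape(data.shape)
    log_field -= log_field[m].mean()    # unit geometric mean in mask
    fld = np.exp(log_field)
    return mri.copy_with(data / fld), mri.copy_with(fld)


def zscore_in_mask(mri: Volume, mask: RoiMask) -> Volume:
    """Zero-mean/unit-SD (population SD) inside the mask; zero outside."""
    m = mask.data
    if m.sum() < 2:
        raise ValueError("mask must contain at least 2 voxels")
    vals = mri.data[m]
    sd = vals.std()  # population SD
    if sd == 0:
        raise ValueError("zero intensity variance inside the mask")
    out = np.zeros_like(mri.data)
    out[m] = (vals - vals.mean()) / sd
    return mri.copy_with(out)


def _resample(data, spacing, target_spacing, order):
    target = np.asarray(target_spacing, dtype=float)
    if np.any(target <= 0):
        raise ValueError("target spacing must be positive")
    old = np.asarray(spacing, dtype=float)
    extent = (np.asarray(data.shape) - 1) * old
    if np.any(target > extent + 1e-9):
        raise ValueError("target spacing exceeds the volume extent")
    new_shape = np.floor(extent / target + 1e-9).astype(int) + 1
    grids = np.meshgrid(*[np.arange(n) * t / o
                          for n, t, o in zip(new_shape, target, old)],
                        indexing="ij")
    return ndimage.map_coordinates(data.astype(float), np.stack(grids),
                                   order=order, mode="nearest")


def resample_trilinear(vol: Volume, target_spacing_mm) -> Volume:
    """Resample to new spacing with trilinear interpolation.

    Voxel centres sit at ``index * spacing``; the first centre is shared
    and the world extent is preserved to within one voxel.
    """
    t = np.broadcast_to(np.asarray(target_spacing_mm, dtype=float), (3,))
    out = _resample(vol.data, vol.spacing, t, order=1)
    return Volume(out, tuple(t), vol.origin)


def resample_mask_nearest(mask: RoiMask, target_spacing_mm) -> RoiMask:
    t = np.broadcast_to(np.asarray(target_spacing_mm, dtype=float), (3,))
    out = _resample(mask.data.astype(float), mask.spacing, t, order=0)
    return RoiMask(out > 0.5, tuple(t), mask.origin)


def log_filter(vol: Volume, sigma_mm: float) -> Volume:
    """3-D Laplacian-of-Gaussian response; sigma given in millimetres."""
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    if not vol.isotropic:
        raise ValueError("LoG filtering requires an isotropically resampled volume")
    sigma_vox = sigma_mm / vol.spacing[0]
    # filter the mean-removed image: analytically identical (the Laplacian
    # of a constant is zero) but immune to DC leakage from kernel truncation
    mu = vol.data.mean()
    return vol.copy_with(ndimage.gaussian_laplace(vol.data - mu,
                                                  sigma=sigma_vox,
                                                  mode="nearest"))


def roi_centre_of_mass_voxel(ctv: RoiMask) -> tuple[int, int, int]:
    com = ndimage.center_of_mass(ctv.data)
    # round half toward the lower index for determinism
    return tuple(int(np.floor(c + 0.5 - 1e-9)) for c in com)


def extract_patch(vol: Volume, ctv: RoiMask, patch_shape=(60, 60, 44)) -> Volume:
    """Fixed-size patch centred on the CTV centre of mass, zero-padded."""
    if ctv.is_empty():
        raise ValueError("CTV mask is empty")
    centre = roi_centre_of_mass_voxel(ctv)
    out = np.zeros(tuple(patch_shape), dtype=float)
    src_slices, dst_slices = [], []
    for ax, (p, c, n) in enumerate(zip(patch_shape, centre, vol.shape)):
        start = c - p // 2
        src_lo, src_hi = max(start, 0), min(start + p, n)
        if src_lo >= src_hi:
            return Volume(out, vol.spacing)
        dst_lo = src_lo - start
        dst_slices.append(slice(dst_lo, dst_lo + (src_hi - src_lo)))
        src_slices.append(slice(src_lo, src_hi))
    out[tuple(dst_slices)] = vol.data[tuple(src_slices)]
    return Volume(out, vol.spacing)
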