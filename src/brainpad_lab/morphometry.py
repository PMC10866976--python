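"""Deterministic image operators for VBM-style tissue maps.

Implements the post-segmentation steps of a voxel-based morphometry
pipeline on tissue probability (density) maps: Gaussian smoothing,
volume-preserving block-average downsampling, total tissue-volume
summaries, and the striatal binding ratio (SBR) formula used for
dopamine-transporter SPECT.

Maps live on a regular grid with an RAS+ affine; values are tissue
probabilities in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelGrid",
    "VolumeSummary",
    "smooth",
    "resample",
    "tissue_volumes",
    "sbr",
    "FWHM_TO_SIGMA",
]

#: conversion factor from a Gaussian kernel's full width at half maximum
#: to its standard deviation: sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

TISSUES = ("GM", "WM", "CSF")


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


@dataclass
class VoxelGrid:
    """A single tissue probability map on a regular 3-D grid.

    Parameters
    ----------
    values : (nx, ny, nz) array of tissue probability in [0, 1].
    spacing : voxel size in mm per axis.
    mask : boolean array, same shape, True inside the brain.
    tissue : one of ``GM``, ``WM``, ``CSF``.
    affine : 4x4 voxel-to-world (mm, RAS+) map.  Defaults to a diagonal
        affine built from ``spacing``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray
    tissue: str = "GM"
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if self.mask.shape != self.values.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {self.tissue!r}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValueError("affine must be 4x4")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.affine)

    @classmethod
    def from_nifti(
        cls, img: nib.Nifti1Image, mask: np.ndarray, tissue: str = "GM"
    ) -> "VoxelGrid":
        zooms = img.header.get_zooms()[:3]
        return cls(
            values=np.asanyarray(img.dataobj, dtype=float),
            spacing=tuple(float(z) for z in zooms),
            mask=mask,
            tissue=tissue,
            affine=np.asarray(img.affine, dtype=float),
        )


@dataclass(frozen=True)
class VolumeSummary:
    """Total tissue volumes in millilitres; TIV is their sum."""

    gm_ml: float
    wm_ml: float
    csf_ml: float

    @property
    def tiv_ml(self) -> float:
        return self.gm_ml + self.wm_ml + self.csf_ml


def smooth(grid: VoxelGrid, fwhm_mm: float) -> VoxelGrid:
    """Gaussian-smooth a tissue map with an isotropic FWHM given in mm.

    The kernel standard deviation per axis is ``fwhm / (2*sqrt(2 ln 2))``
    divided by the voxel spacing on that axis.  Convolution is zero-padded
    (tissue probability outside the head is zero), so total tissue mass
    over the full array is conserved for interior signal.  ``fwhm_mm = 0``
    is the identity.  The mask is unchanged.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return replace(grid, values=grid.values.copy())
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in grid.spacing]
    out = ndimage.gaussian_filter(grid.values, sigma=sigma_vox, mode="constant", cval=0.0)
    return replace(grid, values=out)


def _block_factors(grid: VoxelGrid, target_spacing_mm: float) -> tuple[int, int, int]:
    factors = []
    for s in grid.spacing:
        if target_spacing_mm < s - 1e-9:
            raise ValueError(
                f"target spacing {target_spacing_mm} mm is finer than source "
                f"{s} mm; upsampling is unsupported"
            )
        f = target_spacing_mm / s
        fi = int(round(f))
        if abs(f - fi) > 1e-6:
            raise ValueError(
                f"target spacing {target_spacing_mm} mm is not an integer "
                f"multiple of source spacing {s} mm"
            )
        factors.append(fi)
    return tuple(factors)  # type: ignore[return-value]


def resample(grid: VoxelGrid, target_spacing_mm: float) -> VoxelGrid:
    """Downsample to a coarser isotropic spacing by block averaging.

    Each coarse voxel is the (volume-weighted) mean of its children, which
    preserves the mean tissue density and hence total modulated volume.
    The target spacing must be an integer multiple of the source spacing
    on every axis; equal spacing is the identity.  The mask is resampled
    by majority vote (a coarse voxel is in-mask when at least half of its
    children are).  The affine is updated so that world coordinates of
    voxel centres remain consistent.
    """
    fx, fy, fz = _block_factors(grid, target_spacing_mm)
    if (fx, fy, fz) == (1, 1, 1):
        return replace(grid, values=grid.values.copy(), mask=grid.mask.copy())

    vals = grid.values
    mask = grid.mask
    # zero-pad to a multiple of the block size; padded voxels are out-of-mask
    pads = [(0, (-n) % f) for n, f in zip(vals.shape, (fx, fy, fz))]
    vals = np.pad(vals, pads, mode="constant")
    mask = np.pad(mask, pads, mode="constant", constant_values=False)

    nx, ny, nz = (n // f for n, f in zip(vals.shape, (fx, fy, fz)))
    blocks = vals.reshape(nx, fx, ny, fy, nz, fz)
    out = blocks.mean(axis=(1, 3, 5))
    mblocks = mask.reshape(nx, fx, ny, fy, nz, fz)
    frac = mblocks.mean(axis=(1, 3, 5))
    out_mask = frac >= 0.5

    # coarse voxel (0,0,0) is centred on the mean of its children's centres
    scale = np.diag([fx, fy, fz, 1.0]).astype(float)
    scale[:3, 3] = [(fx - 1) / 2.0, (fy - 1) / 2.0, (fz - 1) / 2.0]
    new_affine = grid.affine @ scale
    new_spacing = tuple(f * s for f, s in zip((fx, fy, fz), grid.spacing))
    return VoxelGrid(
        values=out,
        spacing=new_spacing,
        mask=out_mask,
        tissue=grid.tissue,
        affine=new_affine,
    )


def tissue_volumes(gm: VoxelGrid, wm: VoxelGrid, csf: VoxelGrid) -> VolumeSummary:
    """Total GM/WM/CSF volumes (ml) over the mask, and TIV as their sum.

    Each tissue volume is the sum of in-mask probabilities times the voxel
    volume, i.e. the expected tissue volume under the probabilistic
    segmentation.
    """
    grids = (gm, wm, csf)
    shapes = {g.values.shape for g in grids}
    spacings = {g.spacing for g in grids}
    if len(shapes) != 1 or len(spacings) != 1:
        raise ValueError(
            f"tissue grids must share shape and spacing; got shapes {shapes}, "
            f"spacings {spacings}"
        )
    vols = [float(g.masked_values().sum()) * g.voxel_volume_ml for g in grids]
    return VolumeSummary(gm_ml=vols[0], wm_ml=vols[1], csf_ml=vols[2])


def sbr(target_mean: float, reference_mean: float) -> float:
    """Striatal binding ratio: target over reference uptake, minus one."""
    if reference_mean <= 0:
        raise ValueError(f"reference_mean must be > 0, got {reference_mean}")
    return float(target_mean) / float(reference_mean) - 1.0
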