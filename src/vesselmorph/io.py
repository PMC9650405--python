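"""Volumetric binary-mask I/O and preprocessing.

A segmentation mask is represented by :class:`VolumeMask`: a strictly binary
3D voxel grid together with anisotropic voxel spacing (mm) and a physical
origin.  All downstream geometry works in physical millimetres; the voxel at
0-based index ``(i, j, k)`` has its *center* at ``origin + (i*sx, j*sy, k*sz)``.

Masks are stored on disk as NIfTI-1 (``.nii`` / ``.nii.gz``).  Masks are used
in their stored axis order; no reorientation to anatomical axes is attempted —
anatomical anchoring is supplied explicitly by the caller (see
:mod:`vesselmorph.centerline`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = ["VolumeMask", "read_mask", "write_mask", "largest_component"]


@dataclass(frozen=True)
class VolumeMask:
    """A binary 3D segmentation with voxel-center physical coordinates.

    Parameters
    ----------
    voxels
        3D array of {0, 1}; stored as ``uint8``.
    spacing_mm
        Positive voxel edge lengths ``(sx, sy, sz)`` in millimetres.
    origin_mm
        Physical coordinate of the center of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"non-3D volume: got {vox.ndim} dimensions")
        uniq = np.unique(vox)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("voxels must be strictly binary (0/1)")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"non-positive spacing: {self.spacing_mm}")
        origin = tuple(float(o) for o in self.origin_mm)
        object.__setattr__(self, "voxels", vox.astype(np.uint8))
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin_mm", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world(self, idx: np.ndarray) -> np.ndarray:
        """Physical mm coordinates of (fractional) voxel indices, shape (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def index(self, points_mm: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of physical points, shape (..., 3)."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def foreground_volume_mm3(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume_mm3

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing_mm
        aff[:3, 3] = self.origin_mm
        return aff


def read_mask(path: str | Path) -> VolumeMask:
    """Load a NIfTI volume as a binary mask.

    Float or integer voxel values are binarized at 0.5.  Spacing is taken from
    the header zooms, origin from the affine translation.  Only 3D volumes are
    accepted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3D volume: {path} has {data.ndim} dimensions")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"non-positive spacing in header of {path}: {spacing}")
    origin = tuple(float(t) for t in img.affine[:3, 3])
    voxels = (np.asarray(data, dtype=float) >= 0.5).astype(np.uint8)
    return VolumeMask(voxels, spacing, origin)


def write_mask(mask: VolumeMask, path: str | Path) -> Path:
    """Write a mask as NIfTI-1; the result round-trips through :func:`read_mask`."""
    path = Path(path)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))
    return path


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def largest_component(mask: VolumeMask, connectivity: int = 26) -> VolumeMask:
    """Retain only the largest 3D connected foreground component.

    ``connectivity`` is the 3D neighbourhood: 6 (faces), 18 (faces+edges) or
    26 (faces+edges+corners).  A warning is logged when more than one
    component existed.  An empty mask is rejected.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    if mask.voxels.sum() == 0:
        raise ValueError("empty segmentation")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    labels, ncomp = ndimage.label(mask.voxels, structure=structure)
    if ncomp == 1:
        return mask
    log.warning("mask has %d connected components; keeping the largest", ncomp)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = int(np.argmax(counts))  # ties broken toward the smallest label
    return VolumeMask(
        (labels == keep).astype(np.uint8), mask.spacing_mm, mask.origin_mm
    )
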