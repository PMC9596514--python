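"""Standardized shell volume of interest around the tooth roots.

The roots are cut 30 voxels apical to the CEJ plane, their canals are
filled, the filled roots are grown by 100 µm (exact Euclidean distance),
and the original roots are subtracted, leaving a 100 µm-thick shell that
follows the root surface — the reference volume in which the bone
fraction is quantified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .volume_io import LabelMap

__all__ = [
    "RootMask",
    "VOIShell",
    "crop_roots",
    "fill_holes_3d",
    "fill_root_canals",
    "dilate_by_radius",
    "build_shell",
    "build_voi",
]


@dataclass
class RootMask:
    """Filled root voxels apical of the crop plane."""

    mask: np.ndarray
    crop_offset_voxels: int
    voxel_size_um: float


@dataclass
class VOIShell:
    """Shell mask = (roots dilated by ``dilation_radius_um``) minus roots."""

    mask: np.ndarray
    dilation_radius_um: float
    voxel_size_um: float
    crop_offset_voxels: int | None = None


def crop_roots(
    aligned_tooth: LabelMap | np.ndarray,
    cej_z_um: float = 0.0,
    offset_voxels: int = 30,
    tooth_label: str = "tooth",
) -> tuple[np.ndarray, int]:
    """Tooth voxels at z-index >= CEJ index + offset (half-open crop).

    The crop plane slice itself is excluded from the root.  Requires an
    aligned map (apical = +z, CEJ plane at ``cej_z_um``).  Returns the
    binary root mask on the same grid plus the first root slice index.
    """
    if isinstance(aligned_tooth, LabelMap):
        tooth = np.zeros(aligned_tooth.shape, dtype=bool)
        for lid in aligned_tooth.tooth_ids() or [aligned_tooth.id_of(tooth_label)]:
            tooth |= aligned_tooth.labels == lid
        vs = aligned_tooth.voxel_size_um
        origin_z = aligned_tooth.origin_um[2]
    else:
        tooth = np.asarray(aligned_tooth, dtype=bool)
        vs = 1.0
        origin_z = 0.0
    cej_index = int(round((cej_z_um - origin_z) / vs))
    z0 = cej_index + int(offset_voxels)
    nz = tooth.shape[2]
    if z0 >= nz:
        raise ValueError(f"crop plane (slice {z0}) lies beyond the volume extent ({nz} slices)")
    root = tooth.copy()
    root[:, :, : max(z0, 0)] = False
    if not root.any():
        raise ValueError("crop produced an empty root mask")
    return root, z0


def fill_holes_3d(mask: np.ndarray) -> np.ndarray:
    """Fill background components not 6-connected to the volume border."""
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool))


def fill_root_canals(root_mask: np.ndarray, crop_z_index: int | None = None) -> np.ndarray:
    """Fill canals, treating the cropped cervical face as closed.

    Root canals open onto the crop plane, so plain hole filling would see
    them as border-connected background.  The crop face is capped with a
    one-slice solid plate, holes are filled in 3D, and the cap removed —
    canals then count as holes while the surrounding air does not.
    """
    mask = np.asarray(root_mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    z0 = int(np.flatnonzero(mask.any(axis=(0, 1)))[0]) if crop_z_index is None else int(crop_z_index)
    sub = mask[:, :, z0:]
    cap = np.ones(sub.shape[:2] + (1,), dtype=bool)
    filled = ndi.binary_fill_holes(np.concatenate([cap, sub], axis=2))[:, :, 1:]
    out = mask.copy()
    out[:, :, z0:] = filled
    return out


def dilate_by_radius(mask: np.ndarray, radius_um: float, voxel_size_um: float) -> np.ndarray:
    """Voxels whose center lies within ``radius_um`` of the mask.

    Computed from the exact Euclidean distance transform (center-to-center
    distances), not an iterated structuring element, so a physical radius
    such as 100 µm needs no rounding to a whole voxel count.  Warns if the
    dilated mask touches the volume border (truncated VOI).
    """
    if radius_um <= 0:
        raise ValueError(f"radius_um must be positive, got {radius_um}")
    mask = np.asarray(mask, dtype=bool)
    dist = ndi.distance_transform_edt(~mask, sampling=voxel_size_um)
    out = dist <= radius_um
    border = np.zeros_like(out)
    border[0, :, :] = border[-1, :, :] = True
    border[:, 0, :] = border[:, -1, :] = True
    border[:, :, 0] = border[:, :, -1] = True
    if bool((out & border & ~mask).any()):
        warnings.warn("dilation reaches the volume border; VOI is truncated", stacklevel=2)
    return out


def build_shell(
    filled_root: np.ndarray,
    dilated_root: np.ndarray,
    dilation_radius_um: float,
    voxel_size_um: float,
    crop_offset_voxels: int | None = None,
) -> VOIShell:
    """Shell = dilated roots AND NOT filled roots."""
    filled = np.asarray(filled_root, dtype=bool)
    dilated = np.asarray(dilated_root, dtype=bool)
    if filled.shape != dilated.shape:
        raise ValueError("filled and dilated masks must share a grid")
    if bool((filled & ~dilated).any()):
        raise ValueError("filled roots are not a subset of the dilated roots")
    return VOIShell(dilated & ~filled, dilation_radius_um, voxel_size_um, crop_offset_voxels)


def build_voi(
    aligned: LabelMap,
    cej_z_um: float = 0.0,
    crop_offset_voxels: int = 30,
    dilation_radius_um: float = 100.0,
) -> tuple[RootMask, VOIShell]:
    """Crop, fill, dilate and subtract in one call."""
    root, z0 = crop_roots(aligned, cej_z_um, crop_offset_voxels)
    filled = fill_root_canals(root, z0)
    dilated = dilate_by_radius(filled, dilation_radius_um, aligned.voxel_size_um)
    shell = build_shell(filled, dilated, dilation_radius_um, aligned.voxel_size_um, crop_offset_voxels)
    return RootMask(filled, crop_offset_voxels, aligned.voxel_size_um), shell
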