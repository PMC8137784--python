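"""Volume conditioning: co-registration, reorientation, cropping, gating.

The chain mirrors the processing applied to reconstructed first-pass
volumes before blood-pool analysis: the ES volume is co-registered onto the
ED volume (translation only — the phantom is rigid and motionless), both
are reoriented so the slice axis coincides with the cardiac short-axis
stacking direction, centre-cropped from the reconstruction matrix (220^3)
to the analysis matrix (128^3) at unchanged voxel size, and finally each
static volume is replicated to fabricate an 8-phase gated series: the first
half of the phases are ED copies, the second half ES copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import GatedSeries, KIND_LABEL, VoxelGrid

__all__ = [
    "RigidTransform",
    "coregister_translation",
    "apply_transform",
    "crop_center",
    "crop_slices",
    "assemble_gated",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees about slice, row, col axes — applied in that order)
    followed by an integer voxel translation."""

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_voxels: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        for r in self.rotation_deg:
            if not (-180.0 < r <= 180.0):
                raise ValueError(f"rotation {r} outside (-180, 180]")
        for t in self.translation_voxels:
            if int(t) != t:
                raise ValueError(f"translation must be integral, got {t}")

    @property
    def is_identity(self) -> bool:
        return all(r == 0 for r in self.rotation_deg) and all(
            t == 0 for t in self.translation_voxels
        )

    def rotation_matrix(self) -> np.ndarray:
        """3x3 matrix acting on (slice, row, col) coordinate vectors."""
        mats = []
        for axis, deg in enumerate(self.rotation_deg):
            th = math.radians(deg)
            c, s = math.cos(th), math.sin(th)
            idx = [i for i in range(3) if i != axis]
            m = np.eye(3)
            m[idx[0], idx[0]] = c
            m[idx[0], idx[1]] = -s
            m[idx[1], idx[0]] = s
            m[idx[1], idx[1]] = c
            mats.append(m)
        # applied in declared order: slice-axis rotation first
        return mats[2] @ mats[1] @ mats[0]


def coregister_translation(moving: VoxelGrid, fixed: VoxelGrid) -> RigidTransform:
    """Integer-voxel translation aligning intensity-weighted centroids.

    Rotation is zero; the translation is the centroid difference rounded to
    whole voxels, so after shifting, the moving centroid lands within half a
    voxel of the fixed one on every axis.
    """
    if moving.shape != fixed.shape:
        raise ValueError(f"shape mismatch: {moving.shape} vs {fixed.shape}")
    if moving.voxel_size_mm != fixed.voxel_size_mm:
        raise ValueError("voxel size mismatch between moving and fixed grids")
    for name, g in (("moving", moving), ("fixed", fixed)):
        if g.total() <= 0:
            raise ValueError(f"{name} grid is all zero: centroid undefined")
    com_m = np.array(ndimage.center_of_mass(moving.data))
    com_f = np.array(ndimage.center_of_mass(fixed.data))
    t = np.rint(com_f - com_m).astype(int)
    return RigidTransform(translation_voxels=tuple(int(v) for v in t))


def apply_transform(
    grid: VoxelGrid, t: RigidTransform, interpolation: str = "trilinear"
) -> VoxelGrid:
    """Resample the grid under a rigid transform (rotation about the grid
    centre, then translation).  Output shape and voxel size are unchanged;
    voxels mapped from outside the field are 0.

    ``nearest`` is for label grids (exact voxel permutation under integer
    translation and right-angle rotation), ``trilinear`` for count grids.
    """
    orders = {"nearest": 0, "trilinear": 1}
    if interpolation not in orders:
        raise ValueError(f"interpolation must be one of {sorted(orders)}")
    if t.is_identity:
        return grid.with_data(grid.data.copy())
    order = orders[interpolation]
    data = grid.data.astype(np.float64, copy=False)
    trans = np.asarray(t.translation_voxels, dtype=float)
    if all(r == 0 for r in t.rotation_deg):
        out = ndimage.shift(data, trans, order=order, mode="constant", cval=0.0)
    else:
        rot = t.rotation_matrix()
        center = (np.asarray(grid.shape, dtype=float) - 1.0) / 2.0
        # output voxel x maps back to input voxel R^-1 (x - c - t) + c
        inv = rot.T
        offset = center - inv @ (center + trans)
        out = ndimage.affine_transform(
            data, inv, offset=offset, order=order, mode="constant", cval=0.0
        )
    if grid.value_kind == KIND_LABEL:
        out = np.rint(out).astype(grid.data.dtype)
    else:
        np.clip(out, 0.0, None, out=out)
    return grid.with_data(out)


def crop_slices(shape, target_shape) -> tuple[slice, ...]:
    """Per-axis central slices; an odd surplus drops the extra high-index voxel."""
    sl = []
    for n, m in zip(shape, target_shape):
        if m > n:
            raise ValueError(f"target shape {tuple(target_shape)} exceeds grid shape {tuple(shape)}")
        lo = (n - m) // 2
        sl.append(slice(lo, lo + m))
    return tuple(sl)


def crop_center(grid: VoxelGrid, target_shape) -> VoxelGrid:
    """Centre crop at unchanged voxel size (e.g. 220^3 -> 128^3 keeps 46..173)."""
    target_shape = tuple(int(m) for m in target_shape)
    sl = crop_slices(grid.shape, target_shape)
    return grid.with_data(grid.data[sl].copy())


def assemble_gated(
    ed: VoxelGrid,
    es: VoxelGrid,
    n_phases: int = 8,
    phase_duration_s: float = 1.0,
) -> GatedSeries:
    """Fabricate a gated series from two static volumes by replication.

    The first ``n_phases/2`` frames are the ED volume, the last half the ES
    volume — the gating structure of a cine built from a motionless
    phantom pair.
    """
    if n_phases < 2 or n_phases % 2 != 0:
        raise ValueError(f"n_phases must be a positive even integer, got {n_phases}")
    if ed.shape != es.shape:
        raise ValueError(f"ED/ES shape mismatch: {ed.shape} vs {es.shape}")
    half = n_phases // 2
    frames = [ed] * half + [es] * half
    return GatedSeries(frames=list(frames), phase_duration_s=phase_duration_s, modality_tag="NM")
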