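"""Volume file round-trips (NIfTI via nibabel, MetaImage via SimpleITK).

Arrays keep the package's (slice, row, col) index order on disk and back;
voxel sizes land in the format's spacing metadata.  Label grids are stored
as unsigned 8-bit integers, everything else as float.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from ..grids import KIND_COUNTS, KIND_LABEL, VoxelGrid

__all__ = ["write_volume", "read_volume"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def _format_of(path: Path) -> str:
    name = path.name.lower()
    if any(name.endswith(s) for s in _NIFTI_SUFFIXES):
        return "nifti"
    if any(name.endswith(s) for s in _META_SUFFIXES):
        return "meta"
    raise ValueError(
        f"unsupported volume format {path.name!r} (use .nii/.nii.gz or .mha/.mhd)"
    )


def write_volume(path, grid: VoxelGrid) -> None:
    path = Path(path)
    data = grid.data
    if grid.value_kind == KIND_LABEL:
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float64)
    fmt = _format_of(path)
    if fmt == "nifti":
        # nibabel's fastest axis is the first: store transposed so that the
        # on-disk (x, y, z) maps back to (slice, row, col) on read
        affine = np.diag([*grid.voxel_size_mm[::-1], 1.0])
        img = nib.Nifti1Image(np.asfortranarray(data.T), affine)
        img.header.set_zooms(grid.voxel_size_mm[::-1])
        nib.save(img, str(path))
    else:
        img = sitk.GetImageFromArray(data)
        img.SetSpacing(tuple(float(v) for v in grid.voxel_size_mm[::-1]))
        sitk.WriteImage(img, str(path))


def read_volume(path, value_kind: str = KIND_COUNTS) -> VoxelGrid:
    """Read a NIfTI or MetaImage volume.

    ``value_kind`` declares what the voxels mean (the formats do not record
    it); missing spacing metadata falls back to 1 mm with a warning.
    """
    path = Path(path)
    fmt = _format_of(path)
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj).T
        zooms = img.header.get_zooms()[:3]
        if not zooms or any(z == 0 for z in zooms):
            warnings.warn("NIfTI header lacks voxel sizes; assuming 1 mm", stacklevel=2)
            zooms = (1.0, 1.0, 1.0)
        voxel = tuple(float(z) for z in zooms[::-1])
    else:
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)
        voxel = tuple(float(v) for v in img.GetSpacing()[::-1])
    if value_kind == KIND_LABEL:
        data = data.astype(np.uint8)
    return VoxelGrid(data=data, voxel_size_mm=voxel, value_kind=value_kind)
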