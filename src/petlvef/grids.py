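"""Core in-memory containers: voxel grids, planar images, gated series.

Conventions used throughout the package:

* 3D arrays are indexed ``(slice, row, col)``, 0-based; the voxel with index
  ``i`` spans ``[i * voxel_size, (i + 1) * voxel_size)`` mm and its centre
  sits at ``(i + 0.5) * voxel_size`` mm.
* After reorientation the slice axis coincides with the left-ventricular
  long axis, so stacking along axis 0 walks through short-axis slices.
* Label grids use ``0`` background, ``1`` LV cavity, ``2`` RV cavity,
  ``3`` myocardium.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence, Union

import numpy as np

# compartment labels
LABEL_BACKGROUND = 0
LABEL_LV = 1
LABEL_RV = 2
LABEL_MYOCARDIUM = 3
VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_LV, LABEL_RV, LABEL_MYOCARDIUM})
LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_LV: "LV cavity",
    LABEL_RV: "RV cavity",
    LABEL_MYOCARDIUM: "myocardium",
}

# value kinds a VoxelGrid can carry
KIND_LABEL = "label"
KIND_CONCENTRATION = "concentration_kBq_per_mL"
KIND_COUNTS = "counts"
VALID_KINDS = (KIND_LABEL, KIND_CONCENTRATION, KIND_COUNTS)

# cardiac projection axes; numbers are the numpy axis summed over when the
# volume is short-axis oriented (slice axis == LV long axis)
SHORT_AXIS = "short_axis"
HORIZONTAL_LONG_AXIS = "horizontal_long_axis"
VERTICAL_LONG_AXIS = "vertical_long_axis"
PROJECTION_AXES = {SHORT_AXIS: 0, HORIZONTAL_LONG_AXIS: 1, VERTICAL_LONG_AXIS: 2}

AXIS_ORDER = ("slice", "row", "col")


def _as_triple(value) -> tuple[float, float, float]:
    t = tuple(float(v) for v in np.atleast_1d(value).ravel())
    if len(t) == 1:
        t = t * 3
    if len(t) != 3:
        raise ValueError(f"expected a scalar or length-3 sequence, got {value!r}")
    return t


@dataclass
class VoxelGrid:
    """A 3D scalar field with its voxel size and a declared value kind."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    value_kind: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid data must be 3D, got ndim={self.data.ndim}")
        self.voxel_size_mm = _as_triple(self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        if self.value_kind not in VALID_KINDS:
            raise ValueError(
                f"value_kind must be one of {VALID_KINDS}, got {self.value_kind!r}"
            )
        if self.value_kind == KIND_LABEL:
            present = set(np.unique(self.data).tolist())
            extra = present - VALID_LABELS
            if extra:
                raise ValueError(
                    f"label grid contains values outside {sorted(VALID_LABELS)}: "
                    f"{sorted(extra)}"
                )
        else:
            if np.any(self.data < 0):
                raise ValueError(f"{self.value_kind} grid contains negative values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def voxel_volume_mL(self) -> float:
        # 1 mL == 1 cm^3 == 1000 mm^3
        return self.voxel_volume_mm3 / 1000.0

    def total(self) -> float:
        return float(self.data.sum())

    def with_data(self, data: np.ndarray, value_kind: str | None = None) -> "VoxelGrid":
        return VoxelGrid(
            data=data,
            voxel_size_mm=self.voxel_size_mm,
            value_kind=self.value_kind if value_kind is None else value_kind,
        )


@dataclass
class PlanarImage:
    """A 2D summed-count image tagged with the cardiac axis it was summed along."""

    data: np.ndarray
    pixel_size_mm: tuple[float, float]
    projection_axis: str
    phase_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"PlanarImage data must be 2D, got ndim={self.data.ndim}")
        self.pixel_size_mm = tuple(float(v) for v in self.pixel_size_mm)  # type: ignore[assignment]
        if len(self.pixel_size_mm) != 2 or any(v <= 0 for v in self.pixel_size_mm):
            raise ValueError(f"pixel sizes must be two positive reals, got {self.pixel_size_mm}")
        if self.projection_axis not in PROJECTION_AXES:
            raise ValueError(
                f"projection_axis must be one of {sorted(PROJECTION_AXES)}, "
                f"got {self.projection_axis!r}"
            )
        if np.any(self.data < 0):
            raise ValueError("PlanarImage contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def total(self) -> float:
        return float(self.data.sum())


Frame = Union[VoxelGrid, PlanarImage]


@dataclass
class GatedSeries:
    """An ordered list of equally shaped frames, one per cardiac phase."""

    frames: list[Frame]
    phase_duration_s: float
    modality_tag: str = "NM"

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("GatedSeries needs at least one frame")
        if self.phase_duration_s <= 0:
            raise ValueError("phase_duration_s must be positive")
        first = self.frames[0]
        for f in self.frames[1:]:
            if type(f) is not type(first):
                raise ValueError("all frames must share one type (all 3D or all 2D)")
            if f.shape != first.shape:
                raise ValueError(
                    f"frame shape mismatch: {f.shape} vs {first.shape}"
                )

    @property
    def n_phases(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self):
        return self.frames[0].shape

    def is_planar(self) -> bool:
        return isinstance(self.frames[0], PlanarImage)

    def totals(self) -> list[float]:
        return [f.total() for f in self.frames]
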