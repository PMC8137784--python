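"""Digital end-diastole / end-systole heart-phantom pair.

The phantom is a parametric stand-in for a 3D-printed anthropomorphic pair:
the LV cavity is an ellipsoid whose long axis runs along the slice axis, the
myocardium is the shell between the cavity surface and the same ellipsoid
with every semi-axis enlarged by the wall thickness, and an optional RV
cavity ellipsoid sits on the septal side.  End-diastole and end-systole are
two static geometries; ground-truth cavity volumes come from voxel counting
(the digital analogue of weighing a water-filled cavity at 1 g/cm^3).

Voxel membership is decided by voxel-centre inclusion with centres at
``(index + 0.5) * voxel_size``; there is no partial-volume weighting, and
the voxel-counted volume converges to the analytic ellipsoid volume
``4/3 * pi * a * b * c`` as the voxel size shrinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._util import round_half_up
from .grids import (
    KIND_LABEL,
    LABEL_LV,
    LABEL_MYOCARDIUM,
    LABEL_NAMES,
    LABEL_RV,
    VoxelGrid,
    _as_triple,
)

__all__ = [
    "RvSpec",
    "PhantomSpec",
    "PhantomPair",
    "default_phantom_spec",
    "semi_axes_for_volume",
    "analytic_ellipsoid_volume_cm3",
    "build_phantom_pair",
    "ground_truth_volumes",
]


def analytic_ellipsoid_volume_cm3(semi_axes_mm) -> float:
    a, b, c = _as_triple(semi_axes_mm)
    return 4.0 / 3.0 * math.pi * a * b * c / 1000.0


def semi_axes_for_volume(volume_cm3: float, elongation: float = 2.0) -> tuple[float, float, float]:
    """Semi-axes ``(a, b, b)`` of a prolate ellipsoid of the requested volume.

    ``elongation`` is the ratio of the long (slice-axis) semi-axis to the two
    equal short semi-axes; 2.0 is a typical LV long-to-short axis ratio.
    """
    if volume_cm3 <= 0 or elongation <= 0:
        raise ValueError("volume and elongation must be positive")
    b = (3.0 * volume_cm3 * 1000.0 / (4.0 * math.pi * elongation)) ** (1.0 / 3.0)
    return (elongation * b, b, b)


@dataclass(frozen=True)
class RvSpec:
    """Right-ventricle cavity: an ellipsoid placed beside the LV.

    ``center_mm`` is absolute in grid coordinates.  ED and ES semi-axes are
    given separately so the RV can contract with the LV.
    """

    ed_semi_axes_mm: tuple[float, float, float]
    es_semi_axes_mm: tuple[float, float, float]
    center_mm: tuple[float, float, float]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of the ED/ES phantom pair."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    lv_ed_semi_axes_mm: tuple[float, float, float]
    lv_es_semi_axes_mm: tuple[float, float, float]
    lv_center_mm: tuple[float, float, float]
    wall_thickness_mm: float = 10.0
    rv_spec: Optional[RvSpec] = None
    seed: int = 0

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive integers, got {self.grid_shape}")
        if any(v <= 0 for v in _as_triple(self.voxel_size_mm)):
            raise ValueError("voxel sizes must be positive")
        for name, axes in (("ED", self.lv_ed_semi_axes_mm), ("ES", self.lv_es_semi_axes_mm)):
            if any(s <= 0 for s in _as_triple(axes)):
                raise ValueError(f"{name} semi-axes must be strictly positive")
        if self.wall_thickness_mm <= 0:
            raise ValueError("wall_thickness_mm must be strictly positive")
        if analytic_ellipsoid_volume_cm3(self.lv_es_semi_axes_mm) > analytic_ellipsoid_volume_cm3(
            self.lv_ed_semi_axes_mm
        ) * (1 + 1e-12):
            raise ValueError(
                "end-systolic ellipsoid volume exceeds end-diastolic volume"
            )
        # every ellipsoid (plus wall for the LV) must fit inside the grid
        extent = [n * v for n, v in zip(self.grid_shape, _as_triple(self.voxel_size_mm))]
        wall = self.wall_thickness_mm
        checks = [
            ("LV ED outer wall", self.lv_center_mm, [s + wall for s in _as_triple(self.lv_ed_semi_axes_mm)]),
            ("LV ES outer wall", self.lv_center_mm, [s + wall for s in _as_triple(self.lv_es_semi_axes_mm)]),
        ]
        if self.rv_spec is not None:
            checks.append(("RV ED", self.rv_spec.center_mm, _as_triple(self.rv_spec.ed_semi_axes_mm)))
            checks.append(("RV ES", self.rv_spec.center_mm, _as_triple(self.rv_spec.es_semi_axes_mm)))
        for name, center, semi in checks:
            for ax in range(3):
                lo = center[ax] - semi[ax]
                hi = center[ax] + semi[ax]
                if lo < 0 or hi > extent[ax]:
                    raise ValueError(
                        f"{name} exceeds grid bounds on the {('slice', 'row', 'col')[ax]} "
                        f"axis: [{lo:.1f}, {hi:.1f}] mm vs grid extent [0, {extent[ax]:.1f}] mm"
                    )


@dataclass
class PhantomPair:
    """ED and ES label grids with voxel-counting ground truth."""

    ed: VoxelGrid
    es: VoxelGrid
    edv_cm3: float
    esv_cm3: float
    reference_lvef_pct: float
    spec: Optional[PhantomSpec] = None


def default_phantom_spec(
    edv_cm3: float = 110.0,
    esv_cm3: float = 62.0,
    grid_shape: tuple[int, int, int] = (220, 220, 220),
    voxel_size_mm: float | tuple[float, float, float] = 1.65,
    wall_thickness_mm: float = 10.0,
    elongation: float = 2.0,
    with_rv: bool = True,
    seed: int = 0,
) -> PhantomSpec:
    """The study geometry: LV cavities calibrated to the target ED/ES volumes.

    ED semi-axes solve the analytic ellipsoid volume for ``edv_cm3``; ES
    semi-axes are the ED ones scaled isotropically by ``(esv/edv)^(1/3)``.
    The default grid is 220^3 at 1.65 mm isotropic, the reconstruction
    geometry of the ultra-sensitive digital PET system being emulated.  The
    RV, when present, is a smaller ellipsoid on the +col (septal) side,
    contracting by the same factor.
    """
    vox = _as_triple(voxel_size_mm)
    ed_axes = semi_axes_for_volume(edv_cm3, elongation)
    k = (esv_cm3 / edv_cm3) ** (1.0 / 3.0)
    es_axes = tuple(s * k for s in ed_axes)
    center = tuple(n * v / 2.0 for n, v in zip(grid_shape, vox))
    rv = None
    if with_rv:
        rv_ed = (0.8 * ed_axes[0], 20.0, 15.0)
        rv_es = tuple(s * k for s in rv_ed)
        gap = 5.0  # mm of cold space beyond the LV wall
        offset = ed_axes[2] + wall_thickness_mm + gap + rv_ed[2]
        rv = RvSpec(
            ed_semi_axes_mm=rv_ed,
            es_semi_axes_mm=rv_es,  # type: ignore[arg-type]
            center_mm=(center[0], center[1], center[2] + offset),
        )
    return PhantomSpec(
        grid_shape=tuple(int(n) for n in grid_shape),  # type: ignore[arg-type]
        voxel_size_mm=vox,
        lv_ed_semi_axes_mm=ed_axes,
        lv_es_semi_axes_mm=es_axes,  # type: ignore[arg-type]
        lv_center_mm=center,  # type: ignore[arg-type]
        wall_thickness_mm=wall_thickness_mm,
        rv_spec=rv,
        seed=seed,
    )


def _ellipsoid_mask(shape, voxel_size_mm, center_mm, semi_axes_mm) -> np.ndarray:
    """Boolean mask of voxels whose centres lie inside the ellipsoid."""
    vox = _as_triple(voxel_size_mm)
    semi = _as_triple(semi_axes_mm)
    coords = [
        ((np.arange(n) + 0.5) * v - c) / s
        for n, v, c, s in zip(shape, vox, center_mm, semi)
    ]
    zz = coords[0][:, None, None] ** 2
    yy = coords[1][None, :, None] ** 2
    xx = coords[2][None, None, :] ** 2
    return zz + yy + xx <= 1.0


def _phase_labels(spec: PhantomSpec, lv_semi, rv_semi) -> np.ndarray:
    wall = spec.wall_thickness_mm
    outer = [s + wall for s in _as_triple(lv_semi)]
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    myo = _ellipsoid_mask(spec.grid_shape, spec.voxel_size_mm, spec.lv_center_mm, outer)
    labels[myo] = LABEL_MYOCARDIUM
    cav = _ellipsoid_mask(spec.grid_shape, spec.voxel_size_mm, spec.lv_center_mm, lv_semi)
    labels[cav] = LABEL_LV
    if spec.rv_spec is not None:
        rv = _ellipsoid_mask(
            spec.grid_shape, spec.voxel_size_mm, spec.rv_spec.center_mm, rv_semi
        )
        labels[rv & (labels == 0)] = LABEL_RV
    return labels


def build_phantom_pair(spec: PhantomSpec) -> PhantomPair:
    """Voxelize the ED and ES geometries and compute ground-truth volumes.

    Deterministic: the same spec always yields bit-identical label grids.
    """
    spec.validate()
    rv_ed = spec.rv_spec.ed_semi_axes_mm if spec.rv_spec else None
    rv_es = spec.rv_spec.es_semi_axes_mm if spec.rv_spec else None
    ed = VoxelGrid(
        _phase_labels(spec, spec.lv_ed_semi_axes_mm, rv_ed), spec.voxel_size_mm, KIND_LABEL
    )
    es = VoxelGrid(
        _phase_labels(spec, spec.lv_es_semi_axes_mm, rv_es), spec.voxel_size_mm, KIND_LABEL
    )
    edv, esv = ground_truth_volumes_from_grids(ed, es)
    lvef = round_half_up((edv - esv) / edv * 100.0, 1)
    return PhantomPair(ed=ed, es=es, edv_cm3=edv, esv_cm3=esv, reference_lvef_pct=lvef, spec=spec)


def _lv_volume_cm3(grid: VoxelGrid) -> float:
    if grid.value_kind != KIND_LABEL:
        raise ValueError("ground-truth volumes require a label grid")
    n = int(np.count_nonzero(grid.data == LABEL_LV))
    if n == 0:
        raise ValueError(
            f"label grid contains no '{LABEL_NAMES[LABEL_LV]}' (label {LABEL_LV}) voxels"
        )
    return n * grid.voxel_volume_mm3 / 1000.0


def ground_truth_volumes_from_grids(ed: VoxelGrid, es: VoxelGrid) -> tuple[float, float]:
    return _lv_volume_cm3(ed), _lv_volume_cm3(es)


def ground_truth_volumes(pair: PhantomPair) -> tuple[float, float]:
    """LV cavity volumes (cm^3) by voxel counting, the reference for LVEF."""
    return ground_truth_volumes_from_grids(pair.ed, pair.es)
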