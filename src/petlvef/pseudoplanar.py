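"""Pseudo-planar summed projections.

A pseudo-planar image collapses a short-axis-oriented 3D count volume into
a 2D image by summing every voxel stack along a cardiac axis: all slices at
the same in-plane coordinates (x, y) sum to a single pixel.  The operation
conserves counts exactly, so count-based ejection-fraction analysis on the
2D image sees the same events as the 3D volume — mimicking a planar
gamma-camera view at PET resolution.

Axis conventions (volume reoriented so axis 0 is the LV long axis):

* ``short_axis`` — sum along axis 0, image indexed (row, col);
* ``horizontal_long_axis`` — sum along axis 1, image indexed (slice, col);
* ``vertical_long_axis`` — sum along axis 2, image indexed (slice, row);
  provided for completeness, unused by the standard analysis.
"""

from __future__ import annotations

from typing import Iterable

from .grids import (
    GatedSeries,
    PROJECTION_AXES,
    PlanarImage,
    VoxelGrid,
)

__all__ = ["project_sum", "pseudo_planar_series"]


def project_sum(volume: VoxelGrid, projection_axis: str, phase_index: int = 0) -> PlanarImage:
    """Sum the volume along a cardiac axis into a 2D planar image.

    Exact: the image total equals the volume total (integer in, integer out).
    """
    if projection_axis not in PROJECTION_AXES:
        raise ValueError(
            f"projection_axis must be one of {sorted(PROJECTION_AXES)}, got {projection_axis!r}"
        )
    axis = PROJECTION_AXES[projection_axis]
    data = volume.data.sum(axis=axis)
    in_plane = tuple(v for i, v in enumerate(volume.voxel_size_mm) if i != axis)
    return PlanarImage(
        data=data,
        pixel_size_mm=in_plane,  # type: ignore[arg-type]
        projection_axis=projection_axis,
        phase_index=phase_index,
    )


def pseudo_planar_series(
    gated: GatedSeries, axes: Iterable[str]
) -> dict[str, GatedSeries]:
    """Project every phase of a gated 3D series along each requested axis.

    Returns one 2D gated series per axis, phase order preserved, tagged
    ``NM`` after the gated planar acquisitions such series emulate.
    """
    axes = list(axes)
    if not axes:
        raise ValueError("at least one projection axis is required")
    if gated.is_planar():
        raise ValueError("pseudo_planar_series needs 3D count frames")
    out: dict[str, GatedSeries] = {}
    for ax in axes:
        frames = [
            project_sum(frame, ax, phase_index=i)  # type: ignore[arg-type]
            for i, frame in enumerate(gated.frames)
        ]
        out[ax] = GatedSeries(
            frames=frames,
            phase_duration_s=gated.phase_duration_s,
            modality_tag="NM",
        )
    return out
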