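"""LV segmentation and ejection-fraction quantification.

LVEF is the volumetric fraction of blood ejected per beat,

    LVEF (%) = (EDV - ESV) / EDV x 100,

where EDV and ESV are the end-diastolic and end-systolic LV measures.  The
formula applies identically to cavity volumes (cm^3, from 3D segmentation)
and to event counts in an LV region of interest: at uniform tracer
concentration the counts in the cavity are proportional to its blood
volume, so the ratio cancels concentration, sensitivity and frame duration.

Three routes are provided:

* ``lvef_from_measures`` — the bare formula, on volumes or counts;
* ``count_lvef`` + ``segment_lv_2d`` — count-based LVEF on (pseudo-)planar
  images, with automated threshold/connected-component LV isolation;
* ``segment_lv_3d`` — threshold segmentation of the 3D volume for the
  volumetric route;
* ``measure_lvef_pipeline`` — the end-to-end simulated measurement with
  replicate statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from ._util import round_half_up
from .acquisition import (
    AcquisitionConfig,
    DoseModel,
    activity_map,
    first_pass_blood_concentration,
    simulate_frame,
)
from .geometry import apply_transform, assemble_gated, coregister_translation, crop_center
from .grids import (
    KIND_COUNTS,
    LABEL_LV,
    LABEL_MYOCARDIUM,
    LABEL_RV,
    PROJECTION_AXES,
    SHORT_AXIS,
    PlanarImage,
    VoxelGrid,
)
from .phantom import PhantomPair
from .pseudoplanar import project_sum

__all__ = [
    "RoiMask",
    "LvefResult",
    "ReplicateStats",
    "NegativeEjectionWarning",
    "PipelineError",
    "lvef_from_measures",
    "segment_lv_2d",
    "segment_lv_3d",
    "count_lvef",
    "measure_lvef_pipeline",
    "threshold_sweep",
]

METHOD_COUNTS_2D = "counts_2d"
METHOD_VOLUMETRIC_3D = "volumetric_3d"

_SEPTAL_VECTORS = {
    "+row": (1.0, 0.0),
    "-row": (-1.0, 0.0),
    "+col": (0.0, 1.0),
    "-col": (0.0, -1.0),
}


class NegativeEjectionWarning(UserWarning):
    """ES measure exceeded ED measure: the computed LVEF is negative."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RoiMask:
    """Binary region of interest over an image or volume."""

    data: np.ndarray
    label: str = "LV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)

    @property
    def size(self) -> int:
        return int(self.data.sum())


@dataclass
class ReplicateStats:
    mean: float
    sd: float
    values: list[float]


@dataclass
class LvefResult:
    method: str
    ed_measure: float
    es_measure: float
    lvef_pct: float
    segmentation: str = "automated"
    axis: Optional[str] = None
    replicate_stats: Optional[ReplicateStats] = None
    negative: bool = False


def lvef_from_measures(ed: float, es: float) -> float:
    """(ED - ES)/ED x 100, rounded half-up to one decimal.

    Accepts volumes or counts.  ``es > ed`` yields the (negative) computed
    value with a :class:`NegativeEjectionWarning` rather than clipping.
    """
    if ed <= 0:
        raise ValueError(f"end-diastolic measure must be positive, got {ed}")
    if es < 0:
        raise ValueError(f"end-systolic measure must be nonnegative, got {es}")
    value = (ed - es) / ed * 100.0
    if es > ed:
        warnings.warn(
            f"ES measure {es} exceeds ED measure {ed}: LVEF is negative",
            NegativeEjectionWarning,
            stacklevel=2,
        )
    return round_half_up(value, 1)


def _septal_vector(septal_side) -> np.ndarray:
    if isinstance(septal_side, str):
        try:
            return np.asarray(_SEPTAL_VECTORS[septal_side], dtype=float)
        except KeyError:
            raise ValueError(
                f"septal_side must be one of {sorted(_SEPTAL_VECTORS)} or a 2-vector"
            ) from None
    v = np.asarray(septal_side, dtype=float)
    if v.shape != (2,) or not np.any(v):
        raise ValueError("septal_side vector must be a nonzero (row, col) pair")
    return v / np.linalg.norm(v)


def _pick_lv_component(labels: np.ndarray, image: np.ndarray, septal: np.ndarray) -> np.ndarray:
    """Among labelled components, keep the one opposite the septal direction
    relative to the intensity centroid of the whole image."""
    ids = [i for i in np.unique(labels) if i != 0]
    com = np.array(ndimage.center_of_mass(image))
    scores = []
    for i in ids:
        c = np.array(ndimage.center_of_mass(labels == i))
        scores.append(float(np.dot(c - com, septal)))
    order = np.argsort(scores)
    if len(ids) > 1 and abs(scores[order[0]] - scores[order[1]]) < 1e-9:
        raise ValueError(
            "ambiguous LV selection: two components tie along the septal axis"
        )
    return labels == ids[order[0]]


def segment_lv_2d(
    image: PlanarImage,
    threshold_fraction: float = 0.5,
    septal_side="+col",
) -> RoiMask:
    """Automated LV isolation on a (pseudo-)planar blood-pool image.

    Binarize at ``threshold_fraction x max``, take 8-connected components;
    with several components the LV is the one opposite ``septal_side`` of
    the image intensity centroid (the RV sits on the septal side).  A single
    component is split once by a watershed along the count valley between
    its two strongest peaks; if no second peak exists the whole component is
    the LV (no RV in view).
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    data = np.asarray(image.data, dtype=float)
    mx = data.max()
    if mx <= 0:
        raise ValueError("image has no positive pixel to threshold")
    septal = _septal_vector(septal_side)
    binary = data > threshold_fraction * mx
    if not binary.any():
        raise ValueError("no pixel above threshold")
    labels = skmeasure.label(binary, connectivity=2)
    n = labels.max()
    if n == 1:
        # try a single watershed split along the count valley
        peaks = peak_local_max(
            data, min_distance=3, num_peaks=2, labels=labels, exclude_border=False
        )
        if len(peaks) == 2:
            markers = np.zeros_like(labels)
            markers[tuple(peaks[0])] = 1
            markers[tuple(peaks[1])] = 2
            split = watershed(-data, markers=markers, mask=binary)
            if len(np.unique(split)) > 2:  # background + two regions
                return RoiMask(_pick_lv_component(split, data, septal), label="LV")
        return RoiMask(labels == 1, label="LV")
    return RoiMask(_pick_lv_component(labels, data, septal), label="LV")


def segment_lv_3d(volume: VoxelGrid, threshold_fraction: float = 0.5) -> RoiMask:
    """Threshold the 3D blood-pool volume and keep the largest 26-connected
    component with internal holes filled.

    Used in place of ellipsoid-model blood-pool tools, which are tuned to
    SPECT resolution and mis-segment high-resolution PET volumes.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    data = np.asarray(volume.data, dtype=float)
    mx = data.max()
    if mx <= 0:
        raise ValueError("volume has no positive voxel to threshold")
    binary = data > threshold_fraction * mx
    if not binary.any():
        raise ValueError("no voxel above threshold")
    labels = skmeasure.label(binary, connectivity=3)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()
    mask = ndimage.binary_fill_holes(mask)
    return RoiMask(mask, label="LV")


def count_lvef(
    ed_image: PlanarImage,
    es_image: PlanarImage,
    ed_mask: RoiMask,
    es_mask: RoiMask,
    background_per_pixel: float = 0.0,
) -> LvefResult:
    """Count-based LVEF: total events inside the LV ROI at ED and ES.

    Optional uniform background is subtracted per ROI pixel (off by
    default — a phantom has no background compartment).
    """
    if background_per_pixel < 0:
        raise ValueError("background_per_pixel must be nonnegative")
    measures = []
    for name, img, mask in (("ED", ed_image, ed_mask), ("ES", es_image, es_mask)):
        if mask.data.shape != img.data.shape:
            raise ValueError(f"{name} mask shape {mask.data.shape} != image shape {img.data.shape}")
        m = float(img.data[mask.data].sum()) - background_per_pixel * mask.size
        if m <= 0:
            raise ValueError(
                f"background subtraction drove the {name} measure to {m:.1f} <= 0"
            )
        measures.append(m)
    ed_counts, es_counts = measures
    lv = lvef_from_measures(ed_counts, es_counts)
    return LvefResult(
        method=METHOD_COUNTS_2D,
        ed_measure=ed_counts,
        es_measure=es_counts,
        lvef_pct=lv,
        axis=ed_image.projection_axis,
        negative=es_counts > ed_counts,
    )


def _footprint_mask(label_grid: VoxelGrid, projection_axis: str) -> RoiMask:
    """Perfect LV ROI: the projected footprint of the LV-cavity label."""
    axis = PROJECTION_AXES[projection_axis]
    fp = (label_grid.data == LABEL_LV).sum(axis=axis) > 0
    return RoiMask(fp, label="LV")


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage '{name}': {exc}") from exc
            return False

    return _Ctx()


def measure_lvef_pipeline(
    pair: PhantomPair,
    dose: DoseModel,
    acq: AcquisitionConfig,
    method: str = METHOD_COUNTS_2D,
    axis: str = SHORT_AXIS,
    n_replicates: int = 1,
    base_seed: int = 0,
    threshold_fraction: float = 0.5,
    septal_side="+col",
    crop_shape: tuple[int, int, int] = (128, 128, 128),
    n_phases: int = 8,
    perfect_masks: bool = False,
) -> LvefResult:
    """End-to-end simulated first-pass LVEF measurement.

    Per replicate ``i`` (seeded ``base_seed + i``): build the first-pass
    activity map (hot LV/RV cavities at the first-pass concentration, cold
    myocardium), simulate one reconstructed count frame per phase geometry,
    co-register ES onto ED, centre-crop to the analysis matrix, assemble the
    8-phase gated series, then either project along ``axis`` and run the
    count-based 2D analysis, or segment the 3D volumes and apply the
    volumetric formula.  ED and ES ROIs are drawn independently.

    Returns the result built from replicate-mean measures, with the
    per-replicate LVEF mean +/- sd in ``replicate_stats``.
    """
    if method not in (METHOD_COUNTS_2D, METHOD_VOLUMETRIC_3D):
        raise ValueError(f"unknown method {method!r}")
    if axis not in PROJECTION_AXES:
        raise ValueError(f"unknown projection axis {axis!r}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")

    with _stage("dose"):
        conc = first_pass_blood_concentration(dose).concentration_kBq_per_mL
        conc_map = {LABEL_LV: conc, LABEL_RV: conc, LABEL_MYOCARDIUM: 0.0}
    with _stage("activity_map"):
        act_ed = activity_map(pair.ed, conc_map)
        act_es = activity_map(pair.es, conc_map)

    if perfect_masks:
        ed_labels_c = crop_center(pair.ed, crop_shape)
        es_labels_c = crop_center(pair.es, crop_shape)

    lvefs: list[float] = []
    ed_measures: list[float] = []
    es_measures: list[float] = []
    for i in range(n_replicates):
        ss = np.random.SeedSequence(base_seed + i)
        rng_ed, rng_es = (np.random.default_rng(c) for c in ss.spawn(2))
        with _stage("simulate_frame"):
            frame_ed = simulate_frame(act_ed, acq, rng=rng_ed)
            frame_es = simulate_frame(act_es, acq, rng=rng_es)
        with _stage("coregister"):
            t = coregister_translation(frame_es, frame_ed)
            frame_es = apply_transform(frame_es, t, interpolation="trilinear")
        with _stage("crop"):
            frame_ed = crop_center(frame_ed, crop_shape)
            frame_es = crop_center(frame_es, crop_shape)
        with _stage("gate"):
            gated = assemble_gated(
                frame_ed, frame_es, n_phases=n_phases, phase_duration_s=acq.frame_duration_s
            )
        ed_phase = gated.frames[0]
        es_phase = gated.frames[n_phases // 2]
        if method == METHOD_COUNTS_2D:
            with _stage("project"):
                img_ed = project_sum(ed_phase, axis, phase_index=0)
                img_es = project_sum(es_phase, axis, phase_index=n_phases // 2)
            with _stage("segment_2d"):
                if perfect_masks:
                    mask_ed = _footprint_mask(ed_labels_c, axis)
                    mask_es = _footprint_mask(es_labels_c, axis)
                else:
                    mask_ed = segment_lv_2d(img_ed, threshold_fraction, septal_side)
                    mask_es = segment_lv_2d(img_es, threshold_fraction, septal_side)
            with _stage("count_lvef"):
                res = count_lvef(img_ed, img_es, mask_ed, mask_es)
            ed_m, es_m, lv = res.ed_measure, res.es_measure, res.lvef_pct
        else:
            with _stage("segment_3d"):
                if perfect_masks:
                    mask_ed = RoiMask(ed_labels_c.data == LABEL_LV)
                    mask_es = RoiMask(es_labels_c.data == LABEL_LV)
                else:
                    mask_ed = segment_lv_3d(ed_phase, threshold_fraction)
                    mask_es = segment_lv_3d(es_phase, threshold_fraction)
            with _stage("volumes"):
                vox_cm3 = ed_phase.voxel_volume_mm3 / 1000.0
                ed_m = mask_ed.size * vox_cm3
                es_m = mask_es.size * vox_cm3
                lv = lvef_from_measures(ed_m, es_m)
        lvefs.append(lv)
        ed_measures.append(ed_m)
        es_measures.append(es_m)

    stats = ReplicateStats(
        mean=float(np.mean(lvefs)),
        sd=float(np.std(lvefs, ddof=1)) if n_replicates > 1 else 0.0,
        values=lvefs,
    )
    ed_mean = float(np.mean(ed_measures))
    es_mean = float(np.mean(es_measures))
    return LvefResult(
        method=method,
        ed_measure=ed_mean,
        es_measure=es_mean,
        lvef_pct=lvef_from_measures(ed_mean, es_mean),
        segmentation="supplied" if perfect_masks else "automated",
        axis=axis if method == METHOD_COUNTS_2D else None,
        replicate_stats=stats,
    )


def threshold_sweep(
    ed_image: PlanarImage,
    es_image: PlanarImage,
    thresholds: Sequence[float] = (0.3, 0.4, 0.5, 0.6, 0.7),
    septal_side="+col",
) -> list[tuple[float, float]]:
    """Diagnostic: count-based LVEF as a function of the segmentation
    threshold fraction.  Returns (threshold, lvef_pct) pairs."""
    out = []
    for thr in thresholds:
        mask_ed = segment_lv_2d(ed_image, thr, septal_side)
        mask_es = segment_lv_2d(es_image, thr, septal_side)
        res = count_lvef(ed_image, es_image, mask_ed, mask_es)
        out.append((float(thr), res.lvef_pct))
    return out
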