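"""YAML configuration for phantom, dose and acquisition parameters."""

from __future__ import annotations

from pathlib import Path

import yaml

from ..acquisition import AcquisitionConfig, DoseModel
from ..phantom import PhantomSpec, RvSpec, default_phantom_spec

__all__ = [
    "default_config",
    "load_config",
    "save_config",
    "phantom_spec_from_config",
    "dose_from_config",
    "acquisition_from_config",
]


def default_config() -> dict:
    """The study defaults: 110/62 cm^3 phantom, 140 MBq first-pass bolus,
    3-s frames with the 2.2-mm post-filter."""
    spec = default_phantom_spec()
    return {
        "phantom": {
            "edv_cm3": 110.0,
            "esv_cm3": 62.0,
            "grid_shape": list(spec.grid_shape),
            "voxel_size_mm": list(spec.voxel_size_mm),
            "wall_thickness_mm": spec.wall_thickness_mm,
            "elongation": 2.0,
            "with_rv": True,
        },
        "dose": {
            "injected_activity_MBq": 140.0,
            "labeling_fraction": 1.0,
            "blood_pool_L": 5.0,
            "cardiac_output_L_per_min": 5.0,
            "bolus_window_s": 8.0,
            "rounding_step_kBq_mL": 10.0,
        },
        "acquisition": {
            "frame_duration_s": 3.0,
            "sensitivity_counts_per_kBq_s": 30.0,
            "psf_fwhm_mm": 2.2,
            "background_concentration_kBq_mL": 0.0,
            "poisson_noise": True,
            "seed": 0,
        },
        "pipeline": {
            "method": "counts_2d",
            "axis": "short_axis",
            "n_replicates": 4,
            "base_seed": 1,
            "threshold_fraction": 0.5,
            "septal_side": "+col",
            "crop_shape": [128, 128, 128],
            "n_phases": 8,
        },
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    base = default_config()
    for section, values in cfg.items():
        if section in base and isinstance(values, dict):
            base[section].update(values)
        else:
            base[section] = values
    return base


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def phantom_spec_from_config(cfg: dict) -> PhantomSpec:
    p = dict(cfg.get("phantom", {}))
    if "lv_ed_semi_axes_mm" in p:
        rv = p.pop("rv", None)
        rv_spec = RvSpec(**rv) if rv else None
        return PhantomSpec(
            grid_shape=tuple(p["grid_shape"]),
            voxel_size_mm=tuple(p["voxel_size_mm"]),
            lv_ed_semi_axes_mm=tuple(p["lv_ed_semi_axes_mm"]),
            lv_es_semi_axes_mm=tuple(p["lv_es_semi_axes_mm"]),
            lv_center_mm=tuple(p["lv_center_mm"]),
            wall_thickness_mm=float(p.get("wall_thickness_mm", 10.0)),
            rv_spec=rv_spec,
            seed=int(p.get("seed", 0)),
        )
    return default_phantom_spec(
        edv_cm3=float(p.get("edv_cm3", 110.0)),
        esv_cm3=float(p.get("esv_cm3", 62.0)),
        grid_shape=tuple(p.get("grid_shape", (220, 220, 220))),
        voxel_size_mm=p.get("voxel_size_mm", 1.65),
        wall_thickness_mm=float(p.get("wall_thickness_mm", 10.0)),
        elongation=float(p.get("elongation", 2.0)),
        with_rv=bool(p.get("with_rv", True)),
        seed=int(p.get("seed", 0)),
    )


def dose_from_config(cfg: dict) -> DoseModel:
    return DoseModel(**cfg.get("dose", {}))


def acquisition_from_config(cfg: dict, noiseless: bool = False, seed=None) -> AcquisitionConfig:
    a = dict(cfg.get("acquisition", {}))
    if noiseless:
        a["poisson_noise"] = False
        a["psf_fwhm_mm"] = 0.0
    if seed is not None:
        a["seed"] = int(seed)
    return AcquisitionConfig(**a)
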