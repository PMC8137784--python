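# petlvef

Desk-scale measurement of **left ventricular ejection fraction (LVEF)** from
simulated **first-pass PET** of a digital heart-phantom pair.

Ultra-sensitive digital PET systems can image the initial transit of an
injected tracer bolus through the cardiac chambers in a ~3-s frame, which
opens a route to LVEF measurement from a standard PET/CT visit.  Validating
such a procedure requires a phantom with exactly known cavity volumes.  This
package provides the complete digital workbench for that validation:

* a **parametric end-diastole / end-systole phantom pair** — ellipsoidal LV
  cavity (default calibration EDV = 110 cm³, ESV = 62 cm³), cold myocardial
  wall, optional RV — with voxel-counting ground truth (the digital analogue
  of weighing a water-filled cavity at 1 g/cm³);
* a **first-pass acquisition simulator**: clinical dose-dilution arithmetic
  (140 MBq in the ~670 mL ejected during an 8-s bolus → ~210 kBq/mL in the
  chambers), Poisson count frames, and the 2.2-mm FWHM Gaussian post-filter;
* the **gated-series geometry chain**: ES→ED centroid co-registration,
  short-axis reorientation, 220³→128³ centre crop, and fabrication of an
  8-phase gated series (4 ED + 4 ES copies) with NM-modality DICOM I/O;
* the **pseudo-planar operator**: all slices of the short-axis-oriented
  volume summed at fixed (x, y) into a 2D image — count-conserving by
  construction — along the short axis and horizontal long axis;
* **LVEF quantification** by the volumetric formula and by event counting
  in an automatically segmented LV region of interest.

The core identity is

```
LVEF (%) = (EDV − ESV) / EDV × 100
```

applied either to cavity volumes (cm³) or to ROI event counts: at uniform
blood-pool tracer concentration, counts are proportional to blood volume,
so the ratio cancels concentration, sensitivity and frame duration.

## Worked example

```python
from petlvef import (AcquisitionConfig, DoseModel, SHORT_AXIS,
                     build_phantom_pair, default_phantom_spec,
                     measure_lvef_pipeline)

pair = build_phantom_pair(default_phantom_spec())
print(f"EDV = {pair.edv_cm3:.1f} cm^3, ESV = {pair.esv_cm3:.1f} cm^3, "
      f"reference LVEF = {pair.reference_lvef_pct}%")

res = measure_lvef_pipeline(pair, DoseModel(140.0), AcquisitionConfig(),
                            method="counts_2d", axis=SHORT_AXIS,
                            n_replicates=4, base_seed=1)
s = res.replicate_stats
print(f"count-based LVEF (short axis, 4 replicates): {s.mean:.1f} +/- {s.sd:.1f} %")
```

prints

```
EDV = 109.6 cm^3, ESV = 62.2 cm^3, reference LVEF = 43.3%
count-based LVEF (short axis, 4 replicates): 43.4 +/- 0.4 %
```

The first line is the ground truth: voxel counting on the calibrated
phantom recovers the 110/62 cm³ targets to a few tenths of a cm³, giving a
reference ejection fraction of 43.3%.  The second line is the simulated
measurement: four independently seeded noisy 3-s acquisitions, each pushed
through co-registration, cropping, gating, pseudo-planar projection and
automated half-maximum LV segmentation, recover that reference to within
half a point with sub-point replicate spread.

The same pipeline is available from the shell:

```
petlvef run --seed 1 --out-dir results/
petlvef lvef --method counts2d --axis short --replicates 4 --seed 1 --out-dir results/
```

See `petlvef --help` for the stage-by-stage subcommands (`phantom`,
`simulate`, `gate`, `project`).

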