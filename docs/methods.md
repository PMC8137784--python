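# Methods

## The measurement problem

Ejection fraction from first-pass imaging rests on one physical fact: while
the bolus is still confined to the cardiac chambers, the tracer
concentration in the blood pool is spatially uniform, so the number of
decays recorded from the LV cavity is proportional to its instantaneous
blood volume.  The package simulates the whole measurement chain on a
phantom whose cavity volumes are known exactly, so every processing choice
can be checked against ground truth.

## Phantom model

The LV cavity is a prolate ellipsoid (long axis along the slice axis,
long-to-short axis ratio 2.0 by default) whose semi-axes are solved from
the target end-diastolic volume via `V = 4/3 π a b c`; end-systole scales
all semi-axes by `(ESV/EDV)^(1/3)`, i.e. a geometrically similar
contraction.  The myocardium is the shell between the cavity surface and
the ellipsoid with each semi-axis enlarged by the wall thickness — a
parametric surrogate for a constant-thickness wall that is exact on the
axes and slightly thicker obliquely; it only needs to be cold and to
separate LV from RV.  The RV is a smaller ellipsoid on the +col (septal)
side, contracting by the same factor, present by default so that 2D LV/RV
separation is actually exercised.

Defaults: 220³ grid at 1.65 mm isotropic voxels (the reconstruction
geometry of the emulated digital PET system), EDV/ESV targets 110/62 cm³,
wall thickness 10 mm, RV ED semi-axes (0.8·a_LV, 20, 15) mm with a 5-mm
cold gap beyond the LV wall.  Wall thickness and RV geometry are free
parameters of the model — chosen as anatomically plausible values, not
calibrated to anything — because only the LV cavity volumes carry the
ground truth.

Voxelization is by voxel-centre inclusion (centres at
`(index + 0.5) × voxel_size`), with no partial-volume weighting.  The
resulting discretization error is quantified by the tested convergence
property (volume error strictly decreasing at 2, 1, 0.5 mm); at 1.65 mm
the calibrated pair lands at 109.6/62.2 cm³, i.e. a voxel-counting
reference LVEF of 43.3% against the 43.6% of the analytic targets.  The
voxel-counting value, not the analytic one, is the reference the pipeline
is judged against, exactly as a weighed phantom — not its CAD model — is
the reference for a physical measurement.

## Dose arithmetic

First-pass: the dilution volume is `cardiac output × bolus window`
(5 L/min × 8 s → 666.7 mL, rounded to the nearest 10 mL → 670 mL) and the
chamber concentration `injected activity / dilution volume` (140 MBq →
208.96, rounded to the 10 kBq/mL step → 210 kBq/mL).  Equilibrium: the
labelled fraction of the injected activity (740 MBq × 0.75 = 555 MBq)
diluted in the 5-L blood pool → 111 → 110 kBq/mL.  Rounding mirrors how
these values are quoted clinically; unrounded intermediates are always
returned, and the rounded concentration is what feeds the simulator.

## Acquisition model

The simulator models the reconstructed image directly rather than the
tomograph: expected counts per voxel are
`concentration × voxel volume (mL) × frame duration × sensitivity`, each
voxel receives an independent Poisson draw, and the count grid is smoothed
with the clinical 2.2-mm FWHM Gaussian post-filter.  Poisson-before-
smoothing reproduces the correlated noise texture of a post-filtered
reconstruction.  Attenuation, scatter, randoms, dead time and decay within
a 3-s ¹⁸F frame are all omitted — the phantom study this emulates used no
attenuating material and full corrections, so the reconstructed image is
well approximated by unattenuated Poisson counts plus blur.

`sensitivity_counts_per_kBq_s` is the one free scalar; the default (30)
puts ~1.8 × 10⁶ counts in the ED LV cavity of a 3-s frame, the order of a
high-sensitivity digital system's first-pass frame.  Count-based LVEF is
provably independent of this scalar in the noiseless limit (tested), so it
only sets the noise level.

## Geometry chain

Co-registration is translation-only: the phantom is rigid, so the
intensity-weighted centroid difference, rounded to whole voxels, aligns
ES to ED within half a voxel without interpolating counts.  Rotations
(slice-, then row-, then col-axis) are supported for reorienting user data;
the built-in phantom is constructed with its long axis already along the
slice axis, so its short-axis reorientation is the identity and is recorded
as such.  Counts are resampled trilinearly, labels by nearest neighbour.
The centre crop 220³ → 128³ keeps indices 46..173 on each axis (an odd
surplus drops the extra high-index voxel).  Gating replicates the two
static volumes into `n` phases, first half ED, second half ES (default 8).

The pseudo-planar operator sums **all** slices of the cropped volume at
fixed in-plane coordinates.  The horizontal-long-axis image is the sum
along the row axis of the short-axis-oriented volume; the third (vertical
long axis) projection exists but is unused by the standard analysis.

## Segmentation and quantification

2D: binarize at `threshold × max` (default 0.5, the half-maximum boundary
conventional for high-contrast blood-pool images), 8-connected components;
with two or more components the LV is the one opposite the septal-side
hint relative to the image intensity centroid; an exact tie is an error,
not a guess.  A single merged component is split once by a watershed along
the count valley between its two strongest peaks; if no second peak exists
the whole component is the LV.  ED and ES ROIs are drawn independently per
phase.  Background-ROI subtraction is available but defaults to zero — the
phantom has no background compartment.

A property worth knowing: for an ellipsoidal cavity the half-maximum
region of a sum-projection covers exactly 3/4 of the cavity footprint
(chord > max/2 ⟺ in-plane normalized radius² < 3/4), and captures 87.5% of
its counts.  Because ED and ES are geometrically similar, the captured
fraction is the *same* at both phases, so the count ratio — and hence the
LVEF — is unbiased by the threshold choice; the threshold-sweep diagnostic
(`threshold_sweep`, thresholds 0.3–0.7) makes this visible on any image
pair.

3D: threshold at the same fraction of the volume maximum, keep the largest
26-connected component, fill internal holes.  Ellipsoid-model blood-pool
tools tuned to ~1-cm SPECT resolution are deliberately not reimplemented;
they are known to mis-segment ~4-mm-resolution PET volumes, and the
thresholding route sidesteps that failure mode.

Reported LVEF is rounded half-up to one decimal.  An ES measure exceeding
ED yields the negative value plus a `NegativeEjectionWarning`, never a
silent clip.

## Problem sizes and determinism

The end-to-end recovery checks run 20 independently seeded replicates of
the full 220³ simulation (per replicate: two Poisson frames, smoothing,
co-registration, crop to 128³, projection, automated segmentation), which
completes in about a minute; unit tests use an ~28-cm³ phantom on an
(80, 64, 64) grid of 2-mm voxels with the same ED→ES contraction.  All
randomness flows through `numpy` `SeedSequence(base_seed + replicate)`
split into per-phase generators, so every result is bit-reproducible given
the base seed.  Hypothesis property tests run derandomized.

## What the phantom does and does not show

Passing these checks shows the *procedure* — gating fabrication,
projection, half-maximum ROI counting — is unbiased under its own
assumptions: uniform cavity concentration, cold myocardium, no motion, no
attenuating tissue, geometrically similar contraction.  Real first-pass
data violate several of these (residual myocardial and lung activity,
cardiac and respiratory motion, non-similar regional contraction, valve
planes and atria adjoining the LV blood pool), so phantom agreement bounds
the algorithmic error only, not the clinical error.  The replicate spread
reported here reflects Poisson noise alone, whereas published variability
on physical phantoms also contains observer variability; the two are of
the same sub-point order but are not the same quantity.

## File formats

Label and count volumes round-trip through NIfTI (nibabel) and MetaImage
(SimpleITK) with voxel sizes in the spacing metadata.  Gated series are
written as single multi-frame NM-modality DICOM objects (pydicom) with
counts rescaled to unsigned 16-bit and the slope recorded; only the
standard attributes blood-pool tools key on (frame count, frame duration,
pixel spacing, rescale) are emitted — vendor private tags are not
reproduced.  Configs are YAML; derived results are JSON and flat CSV.
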