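# Methods

This document describes the forward model, the algorithms, the synthetic
data, and the numerical choices behind `temac`, together with the known
limitations of each.

## Forward model

The scanner is modeled as a stack of independent 2D parallel-beam slices.
For slice geometry `ScannerGeometry(n_angles, n_bins, bin_spacing, n_slices,
slice_spacing, fov_radius)`, the expected counts on each line of response
(LOR) are

```
lambda = a · (P x) + s + r
```

where

- `x` is the activity volume (arbitrary units per voxel),
- `P` is the forward projector (line integrals in mm of the interpolated
  activity),
- `a = exp(-∫ mu dl)` are the attenuation survival factors, computed from a
  µ-map in cm⁻¹ integrated along each LOR (the mm line integral is divided
  by 10),
- `s` and `r` are the scatter and randoms background sinograms (counts).

Measured data are Poisson draws of `lambda`. Attenuation *correction
factors* in the usual sense are `1/a`; the code works with the survival
factors `a` directly.

## Parameters and units

| Quantity | Default | Units |
| --- | --- | --- |
| Voxel grid | 64 × 64 × 40 | voxels |
| Voxel size | 3 × 3 × 3 | mm |
| Projection angles | 96 over 180° | — |
| Radial bins | 96 | 2 mm spacing |
| Total prompts per scan | 5 × 10⁶ | counts |
| Scatter fraction | 0.2 | of total counts |
| Randoms fraction | 0.1 | of total counts |
| Reconstruction | 8 iterations, 6 subsets | — |
| Scatter scale | 1.1 | — |
| µ-map / template blur | 4.5 | mm FWHM |
| Reference smoothing (metrics) | 4.7 | mm FWHM |
| Test median filter (metrics) | 5³ | voxels |
| HU→µ, below 50 HU | µ = 0.096 + 9.6·10⁻⁵·HU | cm⁻¹ |
| HU→µ, at/above 50 HU | µ = 0.092 + 5.11·10⁻⁵·HU | cm⁻¹ |

The two bilinear branches are applied verbatim and do not meet at the
50 HU breakpoint (0.1008 vs 0.09456 cm⁻¹); no smoothing is applied across
the jump, and negative outputs (HU < −1000) are clamped to zero.

## Synthetic data and its scope

`make_head_phantom` builds nested-ellipsoid heads: scalp (0 HU), skull
shell (800 HU), cortical gray matter (40 HU) over a white-matter core
(25 HU, activity ratio 1:3 to gray), air-filled paranasal sinuses
(−1000 HU), and a neck stub. A watershed over seeded points partitions the
brain into `n_vois` contiguous VOIs whose uptake varies by seeded
multiplicative factors (σ = 0.15). Anatomical variation spans three axes:
head tilt, inferior coverage loss (`crop_mm` of the volume replaced by
air — the template failure mode that punches a blank gap into a deformed
µ-map), and sinus size. `make_template_set` always includes at least one
cropped and one large-sinus member.

These phantoms are *structural stand-ins*, not anthropomorphic anatomy:
ellipsoidal compartments, piecewise-constant tissue values, no motion, no
partial-volume bleed beyond the applied Gaussian blurs. Conclusions drawn
from the synthetic grid are about the pipeline's internal consistency
(template vs true-µ correction under identical conditions), not about
clinical accuracy.

## Numerical choices

**Projector.** Each slice's system matrix is a sparse CSR matrix built by
sampling every LOR at half-voxel steps with bilinear interpolation weights;
forward and back projection use the same matrix, so the pair is adjoint to
rounding error. The matrix is cached per (geometry, grid) pair. The
half-voxel quadrature leaves a small angle-dependent ripple (≤ ~3%) in
single-voxel line integrals.

**Reconstruction.** MLEM/OSEM with the additive background inside the
update denominator; subsets visit angles in bit-reversed order. With one
subset the update is exact EM and the Poisson log-likelihood is
non-decreasing (verified over 30 iterations in the test suite); with
multiple subsets monotonicity is not guaranteed, as usual for OSEM.

**Scatter.** The default `oracle` mode takes the known scatter expectation
divided by 1.1 — emulating a single-scatter estimate that misses the
multiple-scatter share — and multiplies by the configured scale of 1.1,
restoring the full background. The alternative `tail_fit` mode fits a
radial Gaussian per slice to the angle-averaged profile of bins outside
the object support. It is accurate when the fit covers the full profile
(pure-scatter acquisitions: within ~2% in our checks) but structurally
biased when fitted only to the tails flanking a real object, because the
true scatter profile is flat-topped rather than Gaussian; in masked-object
checks it stays within a factor of 3. It is therefore not the default.

**Registration.** Coarse-to-fine block matching (3 pyramid levels,
block-mean downsampling): the fixed image is partitioned into 4³-voxel
blocks, the highest-variance half is matched by normalized
cross-correlation over a voxel-quantized search (12/6/3 mm per level), and
a rigid or affine transform is fitted to the displacement field by
least-trimmed-squares (trim fraction 0.5) with a damped update (relaxation
0.5), initialized from the centers of mass. NCC's invariance to local
intensity scaling is what lets an attenuation-corrected template PET
register onto an uncorrected reconstruction. Two stabilizers matter:

- *Sub-voxel parabolic peak refinement is off by default.* The vertex
  offsets of asymmetric NCC peaks carry a systematic radial pattern that an
  affine fit absorbs as spurious scale. Rigid fits are insensitive to it,
  so `prepare_template`'s rigid CT-to-PET alignment opts in, where it
  measurably tightens the cross-modality result.
- *Trailing-iterate averaging.* When the finest level does not converge
  within its iteration budget, the last 10 iterates are averaged, which
  collapses the residual limit-cycle wander of the quantized search.

**µ-map estimation.** `prepare_template` aligns the template CT to the
template PET by registering a mildly blurred (2.5 mm) µ conversion of the
CT — a head-shaped surrogate that correlates with emission far better than
raw HU — then converts and blurs the resampled CT to 4.5 mm. Template
deformation resamples the µ-map trilinearly with zero fill, so incomplete
template coverage propagates as a zero slab in the estimate.

**Metrics.** Relative VOI intensities divide each VOI mean by the mean
over the union of all VOIs (their count-weighted mean is exactly 1 by
construction). Regression is ordinary least squares of test on reference;
Bland–Altman differences are scaled by the pairwise mid-point, with sample
(n−1) SD and 1.96 SD limits. Before metric extraction the noiseless
reference is smoothed to 4.7 mm FWHM and the test image is median-filtered
(5³). On the default grid the median filter compresses VOI contrast enough
to pull regression slopes to ~0.85 *in every arm, including the
patient-specific µ-map arm*; comparisons between arms are unaffected
because all arms share the preprocessing.

## Limitations

- The projector is 2D multi-slice: no oblique LORs, axial blur, or
  detector PSF modeling; no time-of-flight.
- Registration is global rigid/affine only; its accuracy is bounded by the
  finest-level voxel quantization (sub-voxel accuracy comes from the
  trimmed averaging over many blocks, not from interpolated search).
- Scatter correction in the study pipeline uses the oracle mode; the
  tail-fit estimator is provided but biased for realistic objects, as
  described above.
- Randoms are modeled (and estimated) as a uniform sinogram rate.
- The noiseless, true-µ, fully corrected reconstruction of the same
  phantom serves as the reference arm; a real study would compare against
  an independently acquired reference scan.
- Absolute metric values (e.g., the ~0.85 slopes) depend on the synthetic
  preprocessing chain and should not be read as clinical estimates; only
  within-study contrasts between arms are meaningful.
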