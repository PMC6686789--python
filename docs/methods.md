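# Methods

## Problem and scope

`ivdquant` quantifies contrast enhancement of the mouse intervertebral
disc (IVD) from in vivo contrast-enhanced microCT (CEμCT). A nonionic
iodinated contrast agent delivered by tail-vein injection diffuses into
the intradiscal space over tens of minutes and raises disc attenuation a
few percent above its pre-injection baseline; the quantification task is
to segment the disc between the adjacent vertebral bodies, measure its
volume, mean attenuation, post/pre attenuation ratio (DI/DI₀) and
mid-sagittal disc height, and test the factorial effects of age, spinal
level and injection on attenuation. Because no public dataset of such
scans exists, the package ships a synthetic phantom generator whose
ground truth is known in closed form; all validation is against that
generator and independent brute-force oracles.

All volumes are indexed `(z, y, x)` with `z` the scan (cranial–caudal)
axis, isotropic voxels (10 μm default, the acquisition resolution), and
raw intensities on an unsigned 16-bit grayscale. Anisotropic inputs are
rejected rather than resampled: resampling would silently change every
downstream metric.

## Phantom model

The phantom is a vertebra–disc–vertebra segment embedded in soft tissue:
two bone cylinders separated by a thin disc cylinder of the same radius,
with mean grayscale values bone 8000 > disc 3000 > soft tissue 1000
(defaults; the ordering is enforced). Geometry defaults — disc height
200 μm, transverse radius 600 μm at 10 μm voxels — are at the scale of
the mouse disc (reported disc heights of roughly 100–200 μm). The disc
slab occupies voxel centers with `|z'| < h/2` (strict), so on an
even-dimensioned lattice whose center falls between slices the rasterized
slab is exactly `h/voxel_size` slices thick and noiseless height recovery
is exact. An optional tilt rotates the segment axis within the sagittal
plane to exercise the height measurement under malalignment; an optional
Gaussian point-spread blur emulates partial-volume effects (off by
default).

Contrast uptake is a piecewise linear factor on disc attenuation: rise
from 1 at injection to `1 + delta_max` at `t_rise` minutes, plateau until
`t_washout`, then linear decline floored at baseline. Defaults:
`delta_max = 0.10` (mid-range of the observed 3–15% increases),
`t_washout = 120` min (bioavailability declines markedly around two
hours), `washout_rate = 0.002`/min. Per-level plateau onsets follow the
observed kinetics (coccygeal 50, lumbar 30, thoracic 40 minutes), and
cohort generation uses the staggered scan schedule (CC 20/50/80,
L 30/60/90, T 40/70/100 minutes post-injection). The curve is a test
fixture shaped like the reported kinetics, not a pharmacokinetic model:
nothing is claimed about the true inter-timepoint time course.

Noise is additive Gaussian, independent per voxel, default SD 150
grayscale units (5% of the disc mean) — a deliberate simplification of
microCT noise (no streaks, rings, motion or beam hardening). Volumes are
quantized to unsigned 16-bit after blur and noise, as a scanner export
would be; the ground-truth record stores the *quantized* disc intensity
and DI/DI₀ so that noiseless recovery is exact rather than exact-up-to-
rounding. Passing tests on these phantoms therefore demonstrate correct
measurement under idealized geometry and noise, not robustness to motion
artifacts, beam hardening or biological shape variation.

Synthetic cohorts add multiplicative between-animal variation of baseline
disc attenuation (CV 2%) so that ANOVA cells have realistic within-cell
variance, and accept additive group effects on `delta_max` and geometry
keyed by `(age_group, level)` (either may be a wildcard). The default
cohort lattice is 80×96×96 voxels with a 400 μm disc radius — a reduced
transverse extent chosen so that full-cohort pipelines remain fast; the
disc height and voxel size are unchanged.

## Segmentation

1. **Blended median filter** (`weight = 0.8`, `radius = 7` defaults, the
   reference parameters). "Weight" is interpreted as a convex blend,
   `out = w·median + (1−w)·in`, the only reading consistent with a weight
   in [0, 1]: weight 1 is a pure median filter, weight 0 the identity.
   The neighborhood is a cube of edge `2r+1` with edge-replicated
   borders. For 16-bit volumes the median is computed exactly with a
   sliding 65536-bin histogram (Huang's algorithm, numba-compiled) —
   selection-based filtering is prohibitively slow at radius 7 — and is
   verified bit-identical to brute-force medians in the tests.
2. **Contour interpolation.** Disc ROIs are defined by polygons drawn
   around the outer edge of the vertebral bodies on sparse keyframe
   slices (supplied programmatically or from JSON; no GUI). Between
   keyframes the region is interpolated through the signed Euclidean
   distance transforms of the rasterized keyframes: at fractional
   position α the region is `(1−α)d₁ + αd₂ ≤ 0`. This reproduces
   keyframes exactly at their slices, is well defined for polygons with
   different vertex counts, and handles non-star-shaped outlines where
   vertex-correspondence morphing is ill-posed. No extrapolation beyond
   the keyframe span.
3. **Bone exclusion.** Voxels at or above the bone threshold are removed
   from the ROI. The threshold is applied to the filtered volume (the
   filter precedes masking in the processing order) *and* to the raw
   volume: median filtering can flip bone voxels at the disc–bone–soft
   three-material corner below the threshold, and the raw-intensity check
   implements the verification that no voxel containing bone survives.
   Without it, corner bone voxels bias the phantom disc mean by ~0.5%.
   The default threshold is automatic: Otsu's method on ROI intensities,
   returned as the midpoint of the class gap so the result is independent
   of the `>` vs `≥` classification convention; it is advisory and can be
   overridden, mirroring visual threshold verification.
4. **Morphological smoothing.** Opening then closing with a discrete ball
   (default radius 2 voxels) removes specks and fills voids. Border
   handling follows the zero-padding convention of the underlying
   morphology routines; masks in this pipeline never touch the array
   border.

## Metrics

- **Volume**: mask voxel count × voxel volume (mm³).
- **Mean attenuation**: arithmetic mean of *raw* grayscale over the mask.
  Filtering guides segmentation only; measuring on the filtered volume
  would bias intensities at tissue boundaries.
- **DI/DI₀**: post/pre mean-attenuation ratio for the same subject and
  level; baselines are matched by (subject, level).
- **Disc height**: on the sagittal slice through the mask centroid,
  heights are the longest contiguous cranial–caudal runs of mask voxels
  at 5 anterior–posterior positions evenly spaced between the 10th and
  90th percentile of the in-plane extent (the trim avoids degenerate rim
  columns where the chord vanishes); the reported height is their mean.
  Runs rather than per-column counts keep pre-smoothing interior voids
  from inflating height. Under a tilt of θ the measurement overestimates
  the perpendicular height by at most 1/cos θ (asserted on tilted
  phantoms). Empty columns are skipped with a warning.
- **Timepoint maximum**: for staggered multi-timepoint series the
  tabulated value is the scan with maximal mean attenuation; ties go to
  the earliest timepoint, which on a plateaued curve is the plateau
  onset.

## Statistics

`three_way_anova` fits the full factorial fixed-effects model
`attenuation ~ age × level × injection` by ordinary least squares and
partitions sums of squares classically; for balanced tables the
sequential (Type I) partition is used, where all SS types coincide, and
unbalanced tables fall back to Type II. Terms made inestimable by empty
cells are dropped with a warning, three-way interaction first. The
implementation is statsmodels' `anova_lm` behind the package interface;
the tests check it against an independent hand-computed cell-means
partition. Repeated-measures correlation (the same animal appears at
several levels and timepoints) is ignored by design, matching the
fixed-effects convention of the original analysis; a mixed model would
be the natural extension. Simulation utilities estimate the type-I error
and power of the injection term on balanced 2×3×2 Gaussian cohorts.

## Validation problem sizes

The shipped checks use: a 200³-voxel noiseless phantom for exact
end-to-end recovery (mean attenuation and DI/DI₀ exact, volume within 5%
of the analytic cylinder, height within one voxel); 20 noisy phantoms at
80×96×96 with noise SD 5% of the disc mean for parameter recovery
(DI/DI₀ within 1%, height within one voxel, Dice ≥ 0.95); 100 random
12³–20³ volumes/masks for oracle equivalence of the filter and
morphology; 50 random simple polygons for keyframe reproduction; 1000
null and 500 effect replicates for ANOVA calibration and power. These
sizes are the package's own validation choices and are deliberately
modest; nothing prevents running the same checks at full acquisition
scale.

## Known limitations

- The phantom's flat-endplate cylinder ignores endplate curvature,
  nucleus/annulus substructure and endplate porosity; metrics on real
  scans inherit segmentation quality in ways the phantom cannot probe.
- The uptake curve interpolates linearly between observed plateau
  behaviors; real diffusion kinetics are not modeled.
- Gaussian voxel noise understates structured microCT artifacts (motion
  near the thorax in particular).
- DICOM support targets flat single-slice series with standard geometry
  tags; no networking, compression or multi-frame objects.
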