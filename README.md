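# ivdquant

Quantification of contrast-enhanced microCT (CEμCT) scans of the mouse
intervertebral disc (IVD).

The mouse IVD is too small and too soft for most noninvasive imaging:
microCT resolves micrometer-scale structure but soft tissue barely
attenuates X-rays. A biocompatible iodinated contrast agent injected via
the tail vein diffuses into the intradiscal space within tens of minutes
and raises disc attenuation by a few percent, enough to segment and
monitor the disc in vivo at multiple spinal levels (coccygeal CC5/CC6,
lumbar L5/L6, thoracic T12/T13). `ivdquant` implements the desk side of
that experiment for researchers studying disc degeneration in mouse
models:

- **Segmentation** — blended median filter (`out = w·median + (1−w)·in`,
  defaults w = 0.8, radius = 7), keyframe contour interpolation via
  signed-distance transforms, grayscale bone-threshold exclusion (Otsu
  default), morphological open/close smoothing.
- **Metrics** — disc volume `V = N·Δx³`, mean attenuation
  `DI = mean(I[mask])` on the 16-bit grayscale, contrast-uptake ratio
  `DI/DI₀` (post/pre injection), disc height averaged over five evenly
  spaced mid-sagittal points, and the per-level maximum over staggered
  post-injection timepoints.
- **Statistics** — 3-way fixed-effects ANOVA of attenuation on age
  (growing 3 mo vs adult 8 mo), spinal level and injection status, with
  calibration/power simulation utilities.
- **Phantoms** — a synthetic vertebra–disc–vertebra generator with
  closed-form ground truth (geometry, uptake curve, noise), so the whole
  pipeline is testable without animal data.

Volumes are read/written as DICOM series, NIfTI-1 or multi-page TIFF,
indexed `(z, y, x)` with isotropic voxels (10 μm default).

## Worked example

```python
import ivdquant as iq
from ivdquant.cli import quantify_scan, PipelineConfig

# a noisy phantom pair: baseline and 60 min post-injection, 12% plateau uptake
spec = iq.PhantomSpec(shape=(80, 96, 96), disc_radius_um=400,
                      vertebra_radius_um=400, noise_sd=150,
                      uptake=iq.UptakeCurve(delta_max=0.12, t_rise=30), seed=1)
contours = iq.phantom_contours(spec)          # vertebral-body outlines
pre_vol, _ = iq.generate_phantom(spec)        # t=None -> baseline
post_vol, truth = iq.generate_phantom(spec, t=60.0)

config = PipelineConfig()                     # weight .8, radius 7, Otsu
pre, _ = quantify_scan(pre_vol, contours, config)
post, mask = quantify_scan(post_vol, contours, config)

print(f"pre  attenuation: {pre.mean_attenuation:.1f}")
print(f"post attenuation: {post.mean_attenuation:.1f}")
print(f"DI/DI0: {post.mean_attenuation / pre.mean_attenuation:.4f}"
      f"  (truth {truth.true_di_ratio})")
print(f"volume: {post.volume_mm3:.4f} mm^3  (truth {truth.true_disc_volume:.4f})")
print(f"disc height: {post.disc_height_um:.0f} um")
print(f"Dice vs truth: {mask.dice(truth.disc_mask):.3f}")
```

prints

```
pre  attenuation: 2999.7
post attenuation: 3359.7
DI/DI0: 1.1200  (truth 1.12)
volume: 0.0993 mm^3  (truth 0.1005)
disc height: 200 um
Dice vs truth: 0.994
```

i.e. despite 5% voxel noise the pipeline recovers the planted 12%
contrast uptake to four decimals, the disc volume within ~1%, and the
200 μm disc height exactly.

The same pipeline runs from the shell:

```sh
ivdquant phantom  --spec cohort.json --out data/
ivdquant quantify --contours data/contours.json \
    --volume data/scans/... --out metrics.csv
ivdquant stats    --metrics metrics.csv --out stats/
```

Every command writes a `provenance.json` (config, seed, input hashes)
sufficient to reproduce deterministic outputs.

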