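# granametry

Semi-automated morphometry of thylakoid ultrastructure in transmission
electron micrographs.

Chloroplast thylakoids organize into stacked **grana** — cylindrical piles
of membrane discs — connected by unstacked **stroma lamellae**. Their
vertical dimensions respond to illumination on the nanometre scale: the
lumen swells in the light, membranes pull closer together on the stroma
side, and single membranes thin slightly. Quantifying these changes from
TEM images means measuring widths of a few nanometres, often below the
pixel size of the micrograph, from noisy, blurred stripe patterns. This
package provides that measurement pipeline for plant cell biologists and
microscopists, together with a synthetic-micrograph simulator with exact
ground truth so every estimator can be validated end to end.

## What is measured

For a granum stack imaged in **HPF contrast** (high-pressure freezing /
freeze substitution: one bright stripe per disc — two membranes plus lumen,
mutually indistinguishable — separated by dark stromal gaps), two
independent estimators are run per image:

- **Method 1** — the averaged intensity profile along the stacking axis is
  fitted with a sinusoid, *y = offset + A·sin(2πx/P + φ)*; the period *P*
  is the **repeat distance**. Each interior trough is then fitted with a
  Gaussian and the **stromal gap** is its full width at half maximum,
  FWHM = 2√(2 ln 2)·σ. **Lumen+membranes** follows as *lm = P − gap*.
- **Method 2** — the image is binarized, each bright stripe's two borders
  are extracted as sub-pixel polylines (half-level crossing of the
  pre-threshold intensity, linearly interpolated per column), and each
  layer is reduced to its rectangular representation:
  *lm* = mean stripe width, *gap* = mean distance to the next stripe,
  *repeat = lm + gap* exactly.

A granum is **accepted** only when the two repeat estimates deviate by less
than 9 % (|r₁ − r₂| / mean(r₁, r₂) < 0.09); stacks with repeat < 13 nm are
flagged as compressed fixation artifacts. Stroma lamellae are measured as a
single bright band (HPF: total thickness) or, in **microwave-fixation
contrast** (dark membranes, bright lumen, intermediate stroma), by
three-class segmentation yielding lumen width and single-membrane
thickness. Group statistics follow the conventions of the field:
mean ± SEM per condition, Gaussian fits (with R²) to width histograms, and
two-sided Mann–Whitney rank-sum tests for dark-vs-light comparisons.

## Worked example

```python
import granametry as g
from granametry.pipeline import roi_for_record

# a synthetic dark-adapted granum: gap 4.68 nm + lm 12.22 nm = repeat 16.90 nm,
# imaged at 0.5 nm/px with PSF sigma 2 px and SNR 5, tilted by 7 degrees
geom = g.make_grana_truth(gap_nm=4.68, lm_nm=12.22, n_layers=10,
                          diameter_nm=200.0, tilt_deg=7.0)
opts = g.RenderOptions(nm_per_px=0.5, psf_sigma_px=2.0, snr=5.0, seed=42)
image, truth = g.render_grana(geom, opts, condition="dark")

results = g.GranaStackModel(image, roi_for_record(truth, image)).fit()
print(results.summary())
```

prints

```
Grana stack analysis: grana-dark-42
  stacking axis               7.01 deg
                         Method 1    Method 2
  repeat distance (nm)      16.90       16.90
  stromal gap (nm)           4.56        4.83
  lumen+membranes (nm)      12.34       12.06
  n (troughs / layers)          9           8
  sinusoid r^2              0.771
  cross-method deviation    0.01 %  (threshold 9 %)
  gate                   ACCEPTED
```

Both methods recover the commanded 16.90 nm repeat despite noise, blur and
tilt; the Method 1 gap (a raw FWHM of a blurred trough) reads slightly
below the Method 2 rectangular-representation gap, as expected for that
estimator pair, and the 0.01 % cross-method deviation passes the 9 % gate.
`LamellaModel` works the same way for stroma lamellae, and
`results.plot_overlay(image)` draws the extracted borders over the
micrograph for visual inspection.

## Command line

```bash
granametry simulate --out cohort/ --seed 1          # synthetic cohort + manifest
granametry measure  --input cohort/ --out run/      # results.csv, summary.json, overlays
granametry report   --results run/results.csv       # mean ± SEM, Gaussian fits
granametry compare  --results-a dark/results.csv --results-b light/results.csv
```

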