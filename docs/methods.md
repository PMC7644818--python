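# Methods

This note documents the measurement model, the synthetic-data generator,
the numerical choices, and the limitations of `granametry`.

## The measurement problem

A granum stack in an HPF-contrast TEM image is a quasi-periodic lamellar
pattern: bright stripes (two membranes plus lumen, `lm`) alternating with
dark stromal gaps (`gap`). The vertical period — the repeat distance,
measured middle-of-gap to middle-of-gap — equals `gap + lm` by definition.
Typical values (~17–20 nm repeat, ~4–5 nm gap) are only a handful of pixels
at common TEM sampling (0.3–0.5 nm/px), and the light-induced effects of
interest are fractions of a nanometre, so every estimator here works at
sub-pixel precision and is validated against simulations with exact ground
truth.

## Estimators

**Stacking axis.** The axis is the direction of maximal periodic intensity
variation: the dominant off-centre peak of the Hann-windowed 2D power
spectrum, refined by a power-weighted centroid over a 5×5 frequency
neighbourhood. Frequencies below 3 spectrum bins are excluded so the stack
outline cannot masquerade as the stripe period; a peak carrying less than
0.5 % of the off-centre spectral energy raises a detection error (pure
noise peaks at roughly 2·ln N²/N² ≈ 0.02 %, two orders below the
threshold). For single lamellae, which have no repeat to lock onto, the
axis comes from the structure tensor (dominant gradient direction) instead.

**Profile extraction.** The ROI is resampled bilinearly into an
axis-aligned frame; the 1D profile is the mean over a perpendicular band
(default 12 samples, spacing 0.5 px). Averaging across the band suppresses
noise by √band; positions are calibrated to nm, so all downstream outputs
scale exactly with the nm-per-pixel calibration.

**Method 1.** A sinusoid `offset + A·sin(2πx/P + φ)` is least-squares
fitted to the profile. The period is initialized from the dominant discrete
Fourier frequency (parabolically interpolated around the peak bin) and
refined by Levenberg–Marquardt; amplitude and phase start from the linear
solution at the initial period. Fits with r² < 0.5 are rejected — the
quality floor is configurable; the published procedure rejects "poor" fits
without quantifying them, so the floor is this package's choice. Gaps are
measured at the sinusoid's minima: each trough whose full window (0.8
periods wide) lies inside the profile is inverted and fitted with a
Gaussian-plus-baseline; the gap estimate is the mean FWHM (2√(2 ln 2)·σ)
over troughs. Partial edge troughs are excluded because a truncated window
biases the FWHM. The FWHM of a PSF-blurred rectangular gap differs
systematically from the geometric width (for a 4.7 nm gap under a 1 nm-σ
PSF it runs a few percent low, and it reads ~5 % below the Method 2
rectangular representation in our simulations); the raw FWHM is reported
deliberately, without deconvolution, to reproduce the estimator as used in
practice rather than an idealized corrected version. A raw half-depth
crossing mode (`fwhm_mode="crossing"`) is provided for sensitivity checks.

**Method 2.** The axis-aligned ROI is lightly smoothed (σ 1 px) and
thresholded: Otsu's between-class-variance criterion gives the initial
foreground/background split, the plateau gray level of each class is
estimated as the median of class pixels eroded 3 px along the axis (class
*means* would be contaminated by blur-transition pixels and bias every
border), and the final mask is cut at the midpoint of the two plateau
levels, making the pixel mask consistent with the sub-pixel border
definition. Components below 32 px are removed and small holes filled. Per
column, each stripe border is the half-level crossing of the axis-smoothed
intensity, localized by linear interpolation between samples — for a
symmetric PSF this crossing estimates the geometric edge without bias.
Stripes spanning less than half the ROI width are discarded; losing more
than 60 % of foreground area to such fragments raises an extraction error.
Layer accounting: all n−1 adjacent-pair gaps are measured; only interior
stripes (both neighbours present) contribute an `lm` and hence a full layer
row with `repeat = lm + gap` exact, giving N(gap) ≥ N(repeat) ≥ N(lm). Each
gap is attributed to the stripe preceding it along the axis; outer
stripe-to-stroma intervals are never measured.

**Cross-validation gate.** A granum is accepted when
`|r₁ − r₂| / mean(r₁, r₂) < 0.09`. The symmetric denominator is a design
choice — neither method is privileged as reference — and the threshold is
configurable. Stacks with repeat < 13.0 nm (strict inequality) are flagged
compressed: tighter packing cannot accommodate photosystem II's lumenal
protrusion and indicates fixation damage. The tissue/cell/organelle visual
triage that precedes automated analysis in practice is a human step; the
pipeline only records an operator pass/fail field.

**Lamellae.** HPF contrast: the single bright band is measured with the
same sub-pixel border logic; zero or multiple qualifying bands raise a
detection error. Microwave contrast: the column-averaged perpendicular
profile is segmented into three classes (membrane < stroma < lumen) by
two-threshold multi-Otsu; class plateau levels come from run cores (≥3
samples from any class edge); the four band boundaries are half-level
crossings between adjacent class levels. Measuring on the averaged profile
rather than per column is deliberate: membranes are ~5 nm ≈ 17 px at
0.3 nm/px, and per-column noise would dominate sub-band widths. Membrane
thickness is reported as the mean of the two membranes. The profile must
start and end in the stroma class, which rejects two-class (HPF) images
cleanly.

**Statistics.** Groups are summarized as mean ± SEM (sd with n−1
denominator over √n) with the layer/repeat as the sample unit, matching how
such data are conventionally tabulated; per-granum aggregation is available
for sensitivity analysis. Width histograms (default bin 0.5 nm — the
figures this mirrors do not state their binning) are fitted with
`A·exp(−(x−μ)²/2σ²)` and R² is computed on bin counts. Dark-vs-light
comparisons use the two-sided Mann–Whitney rank-sum test: exact null
distribution when n₁·n₂ ≤ 10⁴ and tie-free, tie-corrected normal
approximation otherwise (scipy's implementation; the test suite checks it
against a brute-force enumeration oracle). Method agreement is reported as
the Pearson correlation of paired per-granum repeats.

## Synthetic micrographs

The simulator renders the ideal scene analytically: per pixel, the coverage
of each material interval is computed in closed form (area-weighted
anti-aliasing with the pixel footprint projected onto the stacking axis),
so edges land at exact sub-pixel positions and integer-pixel geometries
produce exactly two-level images. Tilt is applied in scene coordinates
before blurring, keeping the nm ground truth exact. The scene is then
blurred by a Gaussian PSF and noised. Contrast modes: HPF has exactly two
classes (bright stripe 28000, dark surround 8000 in 16-bit gray); microwave
has three (membrane 6000, stroma 18000, lumen 30000). The relative gray
level of stroma vs gap vs lumen in microwave images is not constrained by
published imagery; placing stroma midway between membrane and lumen is an
assumption chosen for separability. SNR is defined as (bright − dark) /
noise SD; the default noise model is Poisson–Gaussian with half the target
variance as shot noise at the mean scene level and half as Gaussian read
noise, at SNR 5.

Cohort generation draws per-image geometries from configured distributions.
The default study conditions are: dark-adapted grana gap 4.68 nm /
lm 12.22 nm, light-adapted 4.20 / 15.68 (rectangular-representation means,
hence repeats 16.90 and 19.88 nm — the generator treats gap and lm as
primary and derives the repeat, keeping `repeat = gap + lm` exact);
lamella totals 15.7 (dark) / 20.9 nm (light); microwave membrane/lumen
5.1/5.0 (dark) and 4.8/9.4 nm (light). Between-image SDs (gap 0.3, lm 0.8,
total 0.8, membrane 0.3, lumen 0.5 nm) are chosen once to match the ~1 nm
spread of observed width histograms; tilt is uniform ±15°, stacks have
8–12 layers and 200 nm diameter, imaged at 0.5 nm/px (0.3 nm/px for
microwave lamellae) with PSF σ 2 px. Per-image render seeds derive
deterministically from the master seed, so cohorts are bit-reproducible.

What the simulator does **not** emulate: curvature of grana margins,
within-stack layer-to-layer width variation (each synthetic stack is
perfectly periodic; variability is between images), staining gradients and
uneven illumination, section-thickness projection effects, membrane
protein texture, and 3D tilt out of the section plane. Recovery on these
cohorts therefore demonstrates correctness of the estimators under the
stated image-formation model, not robustness to every artifact of real
micrographs — which is precisely why the cross-method gate and the manual
quality triage exist in the real workflow.

## Validation problem sizes

The acceptance script uses 100 granum stacks per condition and 50 lamellae
per condition per contrast mode; the test suite uses 25-image cohorts for
the gate/recovery checks and smaller cohorts for unit-level properties.
At these sizes the SEM of each recovered grand mean is well below half the
tolerance it is checked against.

## Known limitations

- Method 1's gap estimate inherits the FWHM-vs-rectangle discrepancy by
  design; do not mix Method 1 and Method 2 gap values in one statistic.
- The half-level border convention assumes a symmetric PSF; strongly
  asymmetric point-spread (astigmatism) would bias borders of both methods
  in the same direction and would not be caught by the gate.
- Microwave three-band analysis needs the membrane dips and the lumen peak
  to be separable after averaging; at SNR well below ~3 or membranes under
  ~2 px the multi-Otsu segmentation degrades before the boundary
  refinement does.
- The axis estimate needs ≥3 stripe periods (grana) or a dominant gradient
  orientation (lamellae); heavily curved stacks violate the single-axis
  assumption and should be cropped to a locally straight ROI.
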