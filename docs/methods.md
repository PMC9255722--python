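# Methods

## The measurement problem

Canine laryngeal paralysis is diagnosed by watching arytenoid abduction
during laryngoscopy under light anesthesia, a subjective call with known
inter-observer disagreement.  An objective alternative measures, per video
frame, the glottal gap area `A` (pixel²) and the long-axis length `L`
(pixel) of the rima glottidis, and tracks the normalized statistic

    A/L   (pixel lengths)

through the respiratory cycle.  `A/L` is the mean width of the gap along
its long axis, so smaller values mean a more elongated, more closed
glottis.  Its key practical property is viewing-angle robustness: a camera
tilt along the glottal long axis scales `A` and `L` by the same factor
`cos θ` and leaves `A/L` unchanged (tilt across the short axis scales it by
`cos θ`).  The per-recording endpoint is the breath cycle with the greatest
`A/L Max − A/L Min` inside the final 30 s of the recording — the lightest
anesthesia, closest to awake function; one unambiguous abduction is
sufficient evidence against paralysis.  glottimetry implements this chain
and the two-period crossover aggregation used to compare anesthetic agents,
plus a synthetic recording generator that provides exact ground truth.

## Synthetic recordings

The generator emulates the optical and kinematic structure the analysis
relies on, not laryngeal photorealism.

**Geometry.**  The gap outline is a symmetric superellipse profile
`w(s) = h·(1 − |2s/L|^p)^{1/p}` with long axis `L` (`length_px`), maximal
half-width `h` and exponent `p` (`shape_exponent`; `p = 2` is an ellipse,
`p < 2` a sharper, vocal-fold-like lens).  Its continuum area is
`c(p)·h·L` with `c(p) = 2∫₀¹(1−u^p)^{1/p}du` (so `c(2) = π/2`), giving the
continuum ratio `A/L = c(p)·h` — the handle used for calibration.

**Kinematics.**  Breathing modulates the half-width,
`h(t) = h·(1 − a·m(t))` with `m(t) ∈ [0, 1]` a raised-cosine (default) or
sinusoid at the respiratory frequency.  Default frequency is 0.3 Hz
(18 breaths/min, a typical light-anesthesia rate that places ~9 cycles in
the 30-s window, comfortably above the 5-cycle expectation); default
amplitude fraction is `a = 0.45`.

**Agent presets.**  Anesthetic effect is a pair of multipliers: the
propofol-like preset is the reference (1.0, 1.0); the alfaxalone-like
preset shrinks the resting half-width (×0.57) and the amplitude (×0.72).
With the default geometry (`h = 45 px`, `p = 2`) the continuum selected-
cycle endpoints are `A/L Max ≈ 70.7`, `Max − Min ≈ 31.8` (propofol-like)
and `≈ 40.3 / 13.1` (alfaxalone-like) — chosen analytically to sit at the
published group means of roughly 70/31 and 40/13 pixel lengths.

**Scene.**  Bright-pink mucosa (RGB 230,150,150) against a dark gap
(25,10,10), a linear illumination ramp (±5% by default) across the frame,
additive Gaussian pixel noise (SD 5 by default), and optional viewing-angle
foreshortening (`cos θ` scaling along a stated axis).  No specular
highlights, no epiglottis occlusion, no endoscope vignetting, and no
paradoxical (out-of-phase) motion — so a perfect score here bounds
real-data performance from above rather than predicting it.

**Subject variability.**  A crossover study draws, per subject, log-normal
multipliers (mean 1) on baseline (`σ_log = 0.35`) and amplitude
(`σ_log = 0.45`), shared across both of the subject's stages — the premise
of a within-subject crossover — plus a smaller per-recording occasion
jitter (`σ_log = 0.15`) and a random breathing phase.  These defaults put
the simulated group SDs near the published ones (≈20 of 31 for
propofol-like) while keeping the paired agent contrast directionally
stable.  Sequence rule: the first half of the subjects receive the
alfaxalone-like agent in stage 1, the second half the propofol-like agent,
mirroring the study's 1:1 allocation; sexes are assigned to reproduce the
published per-cell 3/2–2/3 balance.

**Determinism.**  One master seed; per-frame and per-subject/stage
sub-seeds derive from `numpy` `SeedSequence` keyed on (seed, frame) or
(seed, subject, stage), so output is bit-identical across runs and
independent of generation order.

## Segmentation

Frames are thresholded on a darkness channel — luminance
`0.299R + 0.587G + 0.114B` by default; HSV value and R−G are alternatives —
because the contrast the method exploits is a brightness contrast between
dark gap and bright-pink tissue.  The automatic threshold maximizes Otsu's
between-class variance per frame, then moves to the midpoint between the
two class means: the binned Otsu value is a histogram bin center and can
land inside a very narrow dark mode on near-noiseless images, splitting
the gap itself.  A fixed threshold is available for reproducibility.
Cleaning is morphological opening (radius 1 px), largest 8-connected
component (the rima glottidis is one region in a normal dog), and interior
hole filling.  A mask is invalid — retained but excluded from statistics —
when empty, smaller than `min_area_frac` (default 0.1%) of the frame, or
covering ≥ 25% of the image border (gap truncated off-frame).  These rules
replace the human confirmation step of the original workflow.

## Morphometry

`A` is the raw mask pixel count; `L` is the maximum Feret (caliper)
diameter between mask *pixel centers*, computed exactly as the maximum
pairwise distance over the convex hull of the boundary pixels (a 1×10 line
therefore measures 9.0, and a 50×50 square 49√2).  The Feret definition was
preferred over a fitted-ellipse major axis because it needs no ellipticity
assumption for lens-shaped gaps.  No sub-pixel boundary correction and no
mm calibration are applied: the published endpoints are in pixel lengths
and only within-geometry comparisons are meaningful.

## Cycle analysis

The trailing `round(30·fps)` frames form the analysis window; shorter
recordings are an error.  A moving-median filter (half-width 3 frames,
invalid frames excluded per window) suppresses segmentation jitter before
peak detection; per-cycle extrema are then read from the *raw* series so
smoothing cannot attenuate them.  Peaks are local maxima with prominence
≥ 10% of the window's A/L range — enough to reject residual noise while
staying far below the ~20% change that direct visual observation can
resolve; cycles span trough-to-trough around each peak, with the window
endpoints closing the outer cycles.  A flat series yields zero cycles and
a "no detectable motion" warning; fewer than five cycles warns but
proceeds, since the five-cycle figure describes typical data rather than a
validity gate.  The selected cycle maximizes `Max − Min`, ties broken by
earliest start.

## Study aggregation

Group summaries are the sample mean, SD (n−1), t-based 95% CI, min, max and
range, computed at full precision; rounding to table integers happens only
at report time.  The agent comparison pairs each subject's two `Max − Min`
endpoints and reports a paired t-test and a Wilcoxon signed-rank test, both
two-sided and uncorrected (two pre-specified co-primary analyses), plus the
variability ratio: alfaxalone-group mean `Max − Min` over propofol-group
mean.  Period and carryover effects are not modelled (the design's 14-day
washout is taken as sufficient); stage summaries are descriptive.  An
all-zero difference vector short-circuits to p = 1 rather than relying on
the signed-rank test's undefined behavior there.

`reference.py` ships a clearly-labelled synthetic per-dog table because the
original per-dog values are not available in this repository: five
`(al_min, al_diff)` pairs per stage × agent cell are affine transforms of
fixed orthonormal patterns, with the min–diff correlation per cell solved
from the published SD triple so every published cell mean and SD is
reproduced exactly after rounding.  The published overall table is not
fully self-consistent — its propofol `A/L Min` SD (31) cannot be pooled
from the stage cells (which give ≈ 18) — so only the overall *means* are
reproducible and asserted.  Printed cell integers are treated as
independently rounded (stage-1 propofol prints 84/48/37 although
mean(diff) must equal mean(max) − mean(min)); the unrounded cell means used
here round back to every printed integer.

## Problem sizes and numerical choices

Rendered validation runs use 32-s recordings at 15 frames/s and 320×320 px
(480 frames; ~9000-px gap at full abduction), 20 replicate seeds for the
ground-truth-mask calibration, 8 rendered replicates per agent preset for
full-pipeline recovery, and 50 replicate ten-dog crossover simulations
(analytic kinematics) for the directionality check — sizes at which the
Monte-Carlo error of each reported mean is far below the tolerances being
checked.  Rasterization uses pixel-center sampling; the supersampled-grid
area oracle in the tests agrees within 1% for gaps ≥ 40 px across.
Degenerate inputs (gap < 2 px, single-pixel masks, L = 0, empty groups,
unpaired subjects) raise typed errors or propagate invalid flags rather
than producing numbers.

## Known limitations

- The generator's flat-color optics make segmentation easier than real
  endoscopy (no specular glare, motion blur, mucus, or epiglottis
  occlusion); Dice ≥ 0.98 here does not transfer to clinical video.
- Left/right hemi-glottis lateralization, paradoxical-motion detection and
  mm-calibrated areas are out of scope.
- The two published significance models are substituted by paired
  t + signed-rank; no claim is made of reproducing the original appendix
  statistics.
- The synthetic per-dog table is a reconstruction constrained by published
  summaries, not a recovery of the original measurements.
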