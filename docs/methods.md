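# Methods

This package reimplements, as a tested pipeline over synthetic data, the
analysis chain used in adaptive-optics micro-psychophysics of the human
foveola: cone-mosaic density landmarks, a diffraction-limited cone
light-capture model, fixational-drift statistics relative to those
landmarks, and QUEST-based 4AFC acuity threshold estimation.

Coordinate frame throughout: origin at the retinal image's top-left, x
rightward, y downward, positions in arcmin (1 deg = 60 arcmin), densities in
cones/deg², angles in degrees with counterclockwise positive (so "up" on
the printed image is +90°).

## Cone density mapping and landmarks

A mosaic is a table of cone-center coordinates on a calibrated image
(default pixel scale 0.1 arcmin, i.e. 600 px/deg). Each cone is assigned a
Voronoi patch; the density at an image pixel is k / (summed area of the k
nearest cones' patches), k = 150 by default, converted to cones/deg².

* **Boundary handling.** Raw Voronoi cells at the image edge are unbounded;
  cells are clipped to the image rectangle (implemented by mirroring all
  points across the four edges, which yields exactly-clipped finite cells).
  Clipping approximates the true patch area when the mosaic is labeled to
  the image edge; density values whose nearest-k footprint includes
  boundary cells inherit that approximation. The footprint radius for
  k = 150 at foveolar densities is ≈ 3.5 arcmin, so landmark estimates
  (central by construction) are unaffected. An optional edge margin
  excludes a border band from the map.
* **Landmarks.** PCD is the map argmax (row-major first on exact ties,
  flagged); the CDC is the density-weighted centroid of pixels at or above
  the 80th percentile of map values (percentile taken over pixels, since
  the CDC is defined on the pixel-resolved map). The PRL is an input
  coordinate, not estimated.
* **ICD and Nyquist.** Assuming a perfect hexagonal lattice,
  ICD = sqrt(2 / (√3·ρ)) and the Nyquist half-period implied by cone row
  spacing is N = (√3/2)·ICD. The √3/2 row-spacing factor is exposed as a
  config parameter.
* **Decimation.** The map may be computed on a strided grid for speed;
  landmark invariance to moderate strides follows from the ~arcmin-scale
  smoothness of the nearest-150 map.

## Stimulus optics

Stimuli are dark Snellen Es (standard 5×5 construction, stroke = gap) on a
uniform infrared raster, rendered at whole raster pixels. The retinal image
is the binary decrement bitmap convolved with the incoherent monochromatic
Airy PSF of the given wavelength and pupil (788 nm / 7 mm by default; AO
correction treated as ideal, no Stiles–Crawford apodization). Working in
decrement space makes the infinite uniform background exact under
zero-padding.

The default PSF support spans ~32 Airy radii. The Airy tail converges
slowly (encircled-energy deficit ~1/R); widening the support from 32 to ∞
lowers the 3-px-gap stimulus contrast by about 1.5% — the default is a
deliberate accuracy/cost compromise and the support is an argument.

**Contrast metric.** For a dark letter on a background of intensity 1 with
darkest blurred point I_min, the package reports Michelson contrast
(1 − I_min)/(1 + I_min) by default; Weber decrement contrast
(1 − I_min) = max decrement is available via `metric="weber"`. Michelson
was adopted as the default because it is the definition consistent with the
reported raster-stimulus contrasts of this preparation (≈0.61 and ≈0.80 for
the 18 and 36 arcsec gap sizes at 788 nm / 7 mm); the Weber reading of the
same images is 0.75 and 0.90.

## Cone light capture

Each cone gets a circular Gaussian acceptance aperture: diameter = 48% of
the mean distance to its Delaunay neighbors, and FWHM = diameter
(σ = diameter/2.3548), the common convention in AO microstimulation work;
both the fraction and the width mapping are parameters. A cone's activation
for a stimulus frame is

activation = ∫ G(x)·D(x − p) dx / ∫ G(x) dx ∈ [0, 1],

with G the aperture profile (truncated at 3σ, evaluated on a 4×
supersampled grid), D the decrement map and p the frame's stimulus
position (bilinear interpolation in the map). Activation is 1 when the
aperture is fully covered by a fully dark stimulus.

The frame's **sampling cone density** is (number of cones with activation
above threshold) / (sum of their Voronoi areas). The interaction threshold
is not physiologically constrained; the default 0.01 counts any cone
appreciably touched by the blurred stimulus and is a parameter. A trial's
scalar sampling density is the median over frames of the stimulus window;
frames with no interacting cone are flagged undefined, never zero.

## Drift statistics

Traces are per-trial stimulus trajectories registered to the mosaic, with a
500 ms stimulus window. Metrics use frame-level (30 Hz) motion vectors;
higher-rate strip-level traces are decimated for the path-length metrics.

* **Drift length** = Σ‖frame-to-frame displacement‖ inside the window
  (path length, not net displacement); velocity = length / 0.5 s.
* **Directions.** θ_retina is the onset→offset vector angle; θ_landmark is
  the signed angle between that vector and the onset→landmark line,
  wrapped to (−180°, 180°]. Trials with zero net displacement or onset at
  the landmark are flagged undefined and dropped from directionality.
* **Tuning ratio** = frequency of θ in the landmark quadrant [−45°, 45°)
  over the mean frequency of the other three quadrants (half-open bins);
  all-toward samples return an infinity sentinel with a warning.
* **Rayleigh test** is implemented natively:
  p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)), R = n·R̄.
* **ISOA.** Gaussian KDE (Silverman bandwidth) on a 0.1-arcmin grid,
  contoured at the level enclosing 68.27% of mass; disjoint contours sum.
  KDE smoothing inflates the area of an isotropic Gaussian sample by
  ≈(1 + h²/σ²) with Silverman h ≈ σ·n^(−1/6) — about +8% at n = 2000 —
  which the validation tolerance accommodates. Bandwidth and mass level are
  parameters.
* **Microsaccades/blinks.** The detector is a median-based velocity
  threshold (velocity from a 5-sample moving window; elliptic threshold at
  λ = 6 median-SDs per component; minimum duration 6 ms, with an event's
  duration counted inclusive of its sampling interval so single-frame
  ballistic jumps at 30 Hz qualify). Sample gaps > 50 ms inside the window
  mark a blink. Trials with either inside the stimulus window are excluded.
* **Gains.** Achieved sampling gain = max within-trial sampling density /
  onset sampling density. Potential gain is interpreted as (density-map
  value at the CDC) / onset sampling density — the gain available by
  re-centering on the anatomical center; exploitation = achieved/potential.

## Psychophysics

QUEST (Watson–Pelli): discrete posterior over log₁₀ threshold, Gaussian
prior (SD 0.5 log₁₀ units, centered on 40 arcsec), Weibull trial likelihood
(β = 3.5, δ = 0.01, γ = 0.25), next stimulus at the posterior mode,
quantized to whole raster pixels (6 arcsec at 0.1 arcmin/px). These QUEST
internals are conventional defaults and all configurable. An eye's
threshold pools 5 × 20 trials and fits a maximum-likelihood cumulative
Gaussian on log₁₀ gap size with γ = 0.25 and lapse ∈ [0, 0.06] (multistart
L-BFGS-B); the threshold is the gap where the fitted function crosses
62.5% correct — midway between guessing and perfect — with a 500-resample
nonparametric bootstrap percentile CI. The sigmoid family is pluggable; the
cumulative Gaussian on log size is the default of the standard fitting
packages for such data.

## Synthetic data: what it emulates and what it does not

* **Mosaics.** A hexagonal lattice at the peak spacing is warped radially
  (area-preserving remap) so density follows ρ₀·exp(−g·r) from a known
  peak, then jittered (Gaussian, fraction of local spacing). Defaults:
  ρ₀ = 13,600 cones/deg² (the reported mean central density; envelope
  8,000–20,000), g = 0.02/arcmin (≈40% decline over 25 arcmin, a realistic
  foveolar falloff), jitter 0.10. The exponential isotropic profile is
  adequate for landmark-recovery testing; real mosaics have anisotropy,
  local defects and labeling noise that it does not emulate.
* **Drift traces.** Cumulative random walk at 30 Hz (configurable up to
  strip rate): gamma step lengths (shape 2) scaled so the median 500 ms
  path is 6.5 arcmin, with a lognormal per-trial speed multiplier
  (σ = 0.45) giving a ~2.5–17 arcmin trial range — the reported summary
  statistics. Step directions are von Mises around the bearing to a target
  with concentration κ (κ = 0 isotropic; default 0.5, which reproduces the
  reported directionality regime: ~50–60% of drifts toward the target
  ±45°, tuning ratio ~3–4). By default the bearing is re-aimed at the
  target every step (closed-loop), so biased drift settles near the target
  instead of overshooting — this is what produces the onset→offset
  shrinkage of landing-point isoline areas; an open-loop fixed-bearing mode
  is available and is used for bias-strength monotonicity checks.
  Optional microsaccade injections (20–40 arcmin, 20 ms) are labeled for
  detector validation. The generator is a statistical emulation, not a
  self-avoiding-walk or oculomotor-plant model.
* **Sessions.** QUEST-driven 5 × 20-trial runs against a synthetic observer
  (cumulative-Gaussian psychometric with known 62.5% threshold; optionally
  tied to the eye's Nyquist limit so denser eyes resolve smaller letters),
  with a drift trace per trial starting near the PRL (peak offset by
  (2, 1) arcmin; onset scatter SD 3.6 arcmin, putting the onset isoline
  area in the ~90 arcmin² range typical of foveolar fixation).

A note on exclusions: with closed-loop bias, the coherent convergence
episode early in a trial raises the windowed velocity against the
dithering baseline of the median-based detector, so at 30 Hz a sizable
fraction (~30%) of clean synthetic trials is excluded as
microsaccade-like. The exclusion is conservative and does not bias the
landmark-relative statistics qualitatively; strip-rate (960 Hz) traces do
not show this effect.

## Problem sizes used in validation

The test suite and analysis scripts run at desk scale: 40×40-cone lattices,
~3,500–5,300-cone synthetic eyes on 36–40 arcmin fields with stride-2 to
stride-8 density grids, 150–400 trials for directionality Monte Carlo,
1,000 seeds for the Brownian path-length oracle, 2,000 draws for Rayleigh
calibration, 200 seeded sessions for threshold recovery, and the
light-capture model on ~12 trials per eye. These sizes were chosen so the
whole pipeline validates in minutes while keeping Monte Carlo error well
inside the stated tolerances.

## Known limitations

* Rectangle clipping of boundary Voronoi cells biases edge densities; use
  the margin parameter when edge values matter.
* The PSF is monochromatic and aberration-free; no residual-AO or
  double-pass modeling.
* The cone model has no transduction dynamics or temporal filtering; the
  activation pattern is a purely geometric light-capture snapshot.
* Microsaccade detection at 30 Hz frame rate is at the edge of the
  detector's design regime (built for ≥ 200 Hz data); treat frame-level
  exclusions as conservative.
* The QUEST observer and the fitted psychometric share the same family;
  recovery statistics do not probe family misspecification.
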