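# foveolar

Analysis pipeline for cone-resolved visual acuity studies of the human
foveola: how densely the central retina samples space, and how fixational
eye motion exploits that sampling.

In adaptive-optics scanning laser ophthalmoscopy (AOSLO) experiments, the
foveolar cone mosaic is imaged cell by cell while an observer resolves tiny
Snellen-E optotypes drawn on the imaging raster itself. This package
implements the full analysis chain for such data, exercised end-to-end on
synthetic mosaics, drift traces and simulated observers:

* **Mosaic metrics** — Voronoi tessellation of labeled cone centers, the
  pixel-resolved nearest-150 cone-density map, and its landmarks: peak cone
  density (PCD), cone density centroid (CDC, the density-weighted centroid
  of the top-20% density pixels), inter-cone distance
  ICD = √(2/(√3·ρ)), and the Nyquist limit N = (√3/2)·ICD implied by cone
  row spacing.
* **Stimulus optics** — Snellen-E rendering at the raster pixel scale and
  diffraction-limited retinal images (Airy PSF, e.g. 788 nm / 7 mm pupil),
  with Michelson/Weber contrast of the blurred stimulus.
* **Cone light capture** — Gaussian acceptance apertures (diameter = 48% of
  mean neighbor spacing, FWHM = diameter) sampled against the moving
  retinal image, yielding per-frame cone activation patterns and the
  task-related *sampling cone density*.
* **Drift statistics** — path length of fixational drift, drift direction
  relative to CDC/PRL/PCD, directionality tuning ratio, native Rayleigh
  test, one-SD isoline areas (ISOA) of stimulus landing points,
  convergence ratios, and achieved vs potential sampling gain.
* **Psychophysics** — QUEST (Watson–Pelli) 4AFC staircases, pooled 5×20
  trial maximum-likelihood psychometric fits with the acuity threshold at
  62.5% correct, and threshold/Nyquist comparisons.
* **Synthetic data** — generators for quasi-hexagonal gradient mosaics,
  biased drift traces and whole sessions with known ground truth, so every
  stage is testable without any experimental download.

See `docs/methods.md` for the models, conventions and parameter choices.

## Worked example

Simulate an eye and a full acuity session, then analyze it:

```
foveolar simulate-session --seed 7 --out-dir session
foveolar mosaic-metrics session/cones.csv --stride 4 --out-dir session
foveolar drift-metrics session/traces.csv session/landmarks.json --out-dir session
foveolar acuity-fit session/trials.csv --out session/fit.json
```

which prints, in order:

```
session written to session (100 trials, 6721 cones)
PCD 13034 cones/deg^2 at (25.8, 25.400000000000002); CDC at (25.480349616835905, 25.54575626698453); Nyquist 29.4 arcsec
66 trials analyzed (34 excluded); median drift 5.98 arcmin
threshold 24.1 arcsec [22.4, 25.6] from 100 trials
```

Reading these numbers: the synthetic eye's density map peaks at ~13,000
cones/deg², giving a Nyquist sampling limit of 29.4 arcsec; 34 of 100
trials were excluded for microsaccade-like motion inside the stimulus
window; the remaining trials drifted a median 6.0 arcmin per 500 ms
presentation; and the pooled psychometric fit puts the 62.5%-correct acuity
threshold at 24.1 arcsec (95% CI in brackets) — below the eye's Nyquist
limit, as in the human data this pipeline is built for.

The same steps are available as library calls (`foveolar.generate_session`,
`foveolar.density_map`, `foveolar.trial_drift_metrics`,
`foveolar.fit_psychometric`, ...).

## The analysis scripts

`analysis/01…05_*.py` run the package as a narrative study over two
synthetic eyes spanning the foveolar density range (11,000 and 16,000
cones/deg²), writing tables under `results/` and bulky session bundles
under `scratch/`:

1. `01_simulate_sessions.py` — eyes + QUEST sessions with Nyquist-tied
   observers,
2. `02_mosaic_landmarks.py` — density maps and landmarks
   (`results/mosaic_landmarks.csv`),
3. `03_stimulus_optics.py` — blurred-stimulus contrasts and Airy geometry
   (`results/optics_contrast.csv`),
4. `04_drift_analysis.py` — drift lengths, CDC-relative directionality,
   ISOA shrinkage, sampling gains (`results/drift_summary.csv`),
5. `05_acuity_fit.py` — thresholds vs Nyquist limits
   (`results/acuity_summary.csv`).

On the default seeds the synthetic eyes drift ~6–7 arcmin per trial, direct
~57% of drifts toward the CDC ±45° (tuning ratio ≈ 4, Rayleigh p < 1e-7),
shrink their landing-point ISOA from ~86 to ~65 arcmin², and the denser eye
resolves smaller letters (21.4 vs 27.7 arcsec), both below their Nyquist
limits.

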