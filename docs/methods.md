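# Methods

`filamap` quantifies how proteins are arranged along filamentous
structures — the motivating system is neutrophil extracellular traps
(NETs), extracellular DNA filaments decorated with proteins such as
neutrophil elastase (NE), cathepsin G (CATG) and nucleosomes — from
multichannel super-resolution fluorescence images (SIM, STED, or rendered
SMLM data).  This note documents the model, the estimators, the defaults,
and the limits of what the synthetic validation shows.

## Pipeline model

1. **Preprocessing.**  Images are calibrated stacks `(channel, z, y, x)`
   in µm; physical coordinates are pixel-center, `x_µm = (i + 0.5)·px`.
   Optional z maximum-intensity projection; optional global integer-pixel
   channel alignment (translation only, exhaustive search within a window,
   correlation scored on the overlap); background correction by grey-scale
   opening with a disk (rolling-ball equivalent) and clipping at zero.
   The opening uses a decomposed footprint for radii above 3 px, which is
   ~20× faster at SMLM pixel sizes and differs from the exact disk by well
   under one intensity count on noise-dominated images.  SMLM localization
   tables are rendered to images (2D histogram + Gaussian blur, default
   sigma = median localization precision) so a single downstream pipeline
   serves all modalities.

2. **Detection.**  The DNA-backbone channel is smoothed with a Gaussian of
   0.05 µm (≈ one PSF sigma; a matched filter for line detection — without
   it, shot noise shreds the mask boundary and the skeleton of an
   SMLM-scale image degenerates into tens of thousands of spurious
   branches) and thresholded (Otsu by default; fixed threshold for
   reproducible tests).  Components smaller than a 0.5 µm disk are
   removed.  The mask is thinned to a 1-px skeleton and decomposed into a
   graph: nodes are endpoints and branch points (8-adjacent branch pixels
   are clustered into a single junction), edges are ordered pixel chains.
   Dangling chains shorter than 0.2 µm are pruned as spurs and chains are
   merged through the 2-way junctions this leaves; pixels within 0.25 µm
   of any remaining ≥3-way junction are discarded, so only unambiguous
   single-filament stretches survive.  Chains are filtered by arclength
   (≥ 1.5 µm) and mean local width (2 × distance transform along the
   chain, default max 0.5 µm — "thin" has no published cutoff, so the
   width limit is configuration).

3. **Arclength estimation.**  Path pixel coordinates are smoothed along
   the chain (Gaussian, sigma 2 px) before the arclength is accumulated.
   This is deliberate: the raw 8-connected chain code overestimates the
   length of oblique digital lines by up to ~8% (a classical quantization
   bias), which would inflate every periodicity estimate by the same
   factor; after smoothing, straight-line arclength is accurate to ~1% at
   all orientations.

4. **Fragments and profiles.**  Each path is cut into contiguous 1.5 µm
   fragments anchored at arclength 0 (remainder discarded; fragment count
   = ⌊L/1.5⌋).  Per channel, intensity line profiles are sampled at
   arclength steps Δs (default half a pixel: ≈16 nm SIM, 10 nm STED, 5 nm
   SMLM) by bilinear interpolation, averaged over ±line_width/2 along the
   local normal (default 3 px).  Fragments with any sample outside the
   image are excluded and counted.

5. **Periodicity.**  The autocorrelogram of each mean-subtracted profile
   uses the biased Pearson-style estimator
   `r(k) = Σ (x_i − x̄)(x_{i+k} − x̄) / Σ (x_i − x̄)²`
   (full-series mean and denominator), which guarantees `r(0) = 1` and
   `|r| ≤ 1`.  Detrending is mean subtraction only — at 1.5 µm, slow
   trends are signal.  The *first peak* is the smallest lag ≥ min_lag
   (50 nm SIM/STED, 30 nm SMLM) that is a local maximum (plateaus count
   once, at their leftmost sample) with topographic prominence ≥ 0.05.
   Its distribution over fragments is the periodicity histogram; the
   predominant repeat distance is the center of a Gaussian fit to it.

6. **Mixture fitting and model choice.**  One- and two-component normal
   mixtures are fitted to the *raw* first-peak lags by maximum likelihood
   (EM), not least squares on histogram counts, so the result does not
   depend on the display bin width (25 nm, display only).  EM uses 10
   restarts from stratified-quantile initializations (jittered per
   restart, seeded), convergence when the log-likelihood changes by less
   than 1e−8, and component standard deviations floored at one sampling
   step Δs — below that scale, lag differences are quantization, and the
   floor is what prevents the classical spike degeneracy of mixture
   likelihoods.  AIC = 2(3K − 1) − 2 log L selects between K = 1 and 2
   (ties go to fewer components; non-converged candidates are excluded).

7. **Colocalization.**  Between two protein channels, the zero-lag
   normalized cross-correlation (Pearson r of the two profiles) is
   computed only on *double-labeled* fragments: both channels must show
   (max − median)/(1.4826·MAD) ≥ 3.  Summaries are median ± quartiles
   plus the double-labeled fraction.  Full cross-correlograms
   `r_AB(k) = r_BA(−k)` are available for lag analysis.

## Synthetic data: what it emulates and what it does not

The generator draws smooth open filament backbones (random-walk headings
smoothed at a curvature scale, default 3 µm; `inf` gives straight lines),
places protein puncta either periodically (spacing `d`, Gaussian jitter,
per-site labeling probability `p`, phase uniform per filament so fragment
boundaries are not phase-locked) or as a Poisson process at matched mean
density `p/d`, renders the DNA channel as a line integral and protein
channels as point masses (amplitude CV 0.2), convolves with an isotropic
Gaussian PSF (sigma = FWHM/2.3548), and applies Poisson shot noise,
Gaussian read noise and a diffuse background.  Modality presets:
FWHM/pixel = 100/32 nm (SIM), 60/20 nm (STED), 25/10 nm (SMLM).
Defaults: backbone 2000 photons/µm, punctum 800 photons, background 5,
read noise 1 — chosen once as plausible photon budgets for
antibody-labeled super-resolution data.

Not modeled: vectorial/depth-dependent PSFs, fluorophore blinking
kinetics and localization clustering, camera gain, chromatic aberration
beyond rigid shifts, filament overlap in z, and the huge per-site
intensity dispersion of real dSTORM clusters.  Passing tests therefore
demonstrate the correctness of the measurement chain on images whose
degradations are idealized, not performance on real tissue data.

### The multiple-spacing mechanism

When a fraction 1 − p of binding sites carries no label, the nearest
labeled neighbor is sometimes 2d away, so the first-peak distribution
gains a mode at twice the true spacing — apparent periods at integer
multiples of the repeat.  Exact enumeration of all 2^10 labeling patterns
of a 10-site fragment (constant amplitudes, SMLM PSF) shows the 2d mode
is small unless labeling is weak: P(first peak at 2d)/P(at d) is 0.012 at
p = 0.7, 0.095 at p = 0.5, and 0.185 at p = 0.4 — any surviving adjacent
labeled pair produces a qualifying autocorrelation peak at d.  The
property test for this mechanism therefore exercises it at p = 0.4.  At
p = 0.7 the 2d tail, together with jitter smear, is still reliably
captured by the AIC-selected two-component fit (center ratio ≈ 2).

## Known limitations

* **AIC overselection.**  AIC is not a consistent selector: on truly
  unimodal lag samples (n = 200, sd ≈ 0.028 µm, floor 0.016 µm) the
  two-component model is preferred in ~6–10% of seeded runs, roughly
  independent of n.  Users comparing K = 1 vs K = 2 should treat small
  AIC margins (|ΔAIC| ≲ 3) as inconclusive.  The acceptance suite keeps a
  strict ≥95% unimodal-recovery check, which fails at 94/100 — recorded
  here rather than hidden.
* **Crossings.**  Filament crossings are pruned, not resolved; material
  within 0.25 µm of junctions is never analyzed.
* **Rotation equivariance.**  Morphological thinning is raster-order
  dependent; path lengths change by up to ~1–2% under 90° image rotation.
* **Sparse-signal correlation.**  Zero-lag Pearson r between two *sparse*
  punctate channels on the same filament is positively biased when both
  share the same repeat distance, even with independent phases; the
  independence control in the tests therefore uses Poisson-placed puncta.

## Problem sizes in the validation suite

The test and acceptance runs use 640–1024 px images, 3 filaments of
9–16 µm per image, and 10–11 images per regime (≈ 220 fragments at SIM
scale, ≈ 80 at SMLM scale), chosen so a full validation completes in a
few minutes on one CPU while keeping every estimate comfortably inside
its tolerance at those n.
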