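# Methods

## Clustered-fraction statistic

The statistic quantifies how much of the segmented Mic60 signal of an image
sits in small ("single") clusters. The pipeline is:

1. **LoG filtering.** The image is convolved with a Laplacian of Gaussian of
   FWHM 80 nm (default), σ = FWHM / (2√(2 ln 2)), expressed in pixels via
   the image's physical pixel size. The response is sign-flipped so bright
   blobs give positive peaks — the published description does not fix a sign
   convention, but a "fraction of the brightest value" threshold is only
   meaningful on a blob-positive response — and negative values are clamped
   to 0. Before filtering, the image mean is subtracted: by linearity this
   only removes the constant offset the truncated discrete kernel leaves on
   the DC component, and it makes the response exactly zero on flat images.
   A σ below 0.5 px is rejected as a pixel-size metadata error.
2. **Thresholding and labelling.** Foreground is every pixel ≥ 4% of the
   global (or in-mask) maximum; the comparison is ≥ so the maximum itself is
   always foreground. Connected components use 8-connectivity — the
   conservative choice against splitting diagonal contacts. Border-touching
   segments are kept; excluding them would bias against large assemblies.
3. **Scoring.** Segments with area strictly < 0.0225 µm² are single
   clusters; the clustered fraction is their summed area over the total
   segmented area. An image with no segmented area yields an *undefined*
   result (NaN with a flag), never a silent 0 — the caller decides
   exclusion. The source figure legend elsewhere prints a 10× smaller cutoff
   (≤ 0.00225 µm²) and describes a signal (intensity) ratio rather than an
   area ratio; both alternatives are available — the cutoff as an explicit
   parameter, the intensity-weighted ratio as the clearly labelled
   `intensity_fraction` field — without deciding which the original authors
   used. The per-image unit of analysis is the whole image, or one cell's
   mitochondria when a binary mask is supplied.

Multiplying the image by any c > 0 changes neither segmentation nor
fraction (the threshold is relative); merging single clusters into a
super-cutoff segment can only lower the fraction.

## MINFLUX event filter

The five criteria are applied with the printed boundary semantics: p₀ and
r_rel are *retention* conditions (p₀ < 0.11, r_rel < 32 nm; an event failing
either is removed — the opposite reading would discard precisely the good
events), count rates strictly above 100 kHz are removed (an event at exactly
100 kHz is kept), photons must exceed 1000 strictly, and SBR must exceed 0.6
strictly. All failing criteria are recorded per event, enabling
per-criterion QC summaries. Events with non-finite fields are removed and
flagged MALFORMED, never silently dropped. p₀ and r_rel are treated as
opaque instrument scalars; their physical definition lives in the
instrument-side estimation, which is out of scope.

## Morphometry statistics

* **CJ frequency** is normalized to outer-membrane length. The headline
  number is the pooled ratio Σ n_CJ / Σ OM-length per condition (invariant
  to how sections are split); per-section rates with their SEM are returned
  for error bars.
* **Diameters** are pooled per condition; the SD is the sample SD (n − 1).
* **ANOVA** is the classical fixed-effects omnibus test; no post-hoc or
  multiple-testing correction is applied because none is part of the
  procedure being implemented. Zero within-group variance is reported as a
  flagged degenerate result (F = ∞, p = 0 as the distribution limit; NaN
  when all observations are identical).
* **Junction/septum accounting** works at section level by default: a
  junction-bearing section (≥ 1 junction of any kind) either is or is not
  septum-associated. The non-septum CJ prevalence is
  prevalence × (1 − septum fraction) and the relative decrease is
  1 − test/control. On the published rounded proportions (control 0.60
  bearing / 0.15 septum, test 0.36 / 0.50) this gives prevalences 0.51 and
  0.18 and a relative decrease of 0.647; the source text rounds the same
  comparison, computed from its unrounded data, to "66%". The two numbers
  are documented side by side and not asserted equal. A per-junction
  accounting mode (counting individual junctions instead of sections) is
  available because the original choice is not stated.
* **Line profiles** are sampled by bilinear interpolation at equidistant
  points and normalized by min–max, (p − min)/(max − min) — the only
  normalization that maps every profile onto [0, 1] before averaging;
  divide-by-max is available as an option. A flat profile cannot be
  normalized and flags the result degenerate. All lines must share one
  length so positions align.

## Synthetic-data generators

The generators exist so the analyses can be validated end to end with known
ground truth; their defaults describe the imaging regime the analyses
target.

* **Scenes.** Emitters live on the surface of a cylinder (default length
  2 µm, radius 150 nm) and are orthographically projected to the image
  plane — 2D nanoscopy of a tubule is effectively an axial projection and
  the metric is 2D, so no depth attenuation is modelled. Cluster centres
  follow one of four models: uniformly scattered; on circumferential rings
  spaced by a stripe period (the perpendicular stripe pattern of wild-type
  Mic60); confined to two diametrically opposed longitudinal strips of given
  half-width in projected transverse offset (the opposite distribution bands
  seen without Mic10); or extended contiguous arcs spanning a configurable
  angle (the ring/rib assemblies seen without OPA1). Cluster members jitter
  around their centre on the surface (σ = 15 nm); arc emitters are spaced
  10 nm along the arc. Defaults: 30 clusters of 8 emitters, 20 nm pixels
  (within the 15–25 nm range of the target instruments), 60 nm FWHM PSF,
  500 photons/emitter, background 2 counts/pixel — chosen once as realistic
  STED-like immunolabeling conditions.
* **Rendering.** Each emitter adds an isotropic Gaussian whose discrete sum
  equals its photon budget (truncated at 5σ, < 1% loss); uniform background
  is added, then per-pixel Poisson noise (skippable for analytic checks).
* **MINFLUX mixtures.** Valid events are drawn inside all five acceptance
  regions with margins; artifact events cycle round-robin through the five
  criteria so every filter branch is exercised, each violating exactly its
  assigned criterion. Ground-truth labels are returned with the shuffled
  events.
* **Morphometry.** OM lengths are log-normal with median 3 µm (log-SD 0.4);
  per-section length statistics are not published, so these are free,
  configurable parameters. CJ counts are Poisson(cj_per_µm × length). When a
  preset pins the fraction of junction-bearing sections p_any and the
  septum-associated share p_sep, a hurdle model is used instead: CJ presence
  is Bernoulli(q) with q = p_any(1 − p_sep)/(1 − p_any·p_sep), positive
  counts are zero-truncated Poisson, and an independent septum flag is
  Bernoulli(p_any·p_sep) — these closed forms make the expected
  junction-bearing fraction equal p_any and the expected septum share among
  bearing sections equal p_sep. Diameters are Normal(mean, SD) truncated at
  0 by resampling (clipping would put a point mass at 0 and bias mean
  recovery). Condition presets carry the reported diameter means (~20 nm
  wild type, ~28 nm without Mic10, ~32 nm without Mic60) and the reported
  prevalence/septum proportions; diameter SDs and absolute CJ rates are not
  reported and are set to realistic values (SD 4–7 nm, wild-type rate
  1 CJ/µm with knockouts scaled by the reported relative reductions).
* **Randomness.** One root seed; each generator draws from its own child
  stream, `SeedSequence([seed, stream_id])` with fixed ids (scene 0, render
  noise 1, MINFLUX 2, morphometry 3), so partial pipelines reproduce
  bit-identically.

What the generators deliberately do not emulate: labelling stochasticity
and antibody linkage error, detector artifacts, drift, out-of-focus light,
3D PSF shape, mitochondrial curvature/branching, and EM section obliquity.
Passing tests therefore establish correctness of the *statistics and
filters* under their stated assumptions, not performance on real
micrographs.

## Problem sizes and numerical choices

The validation suite uses 20 seeded scenes per spatial model for the
discrimination check, 10,000 events for filter/ground-truth agreement, 100
seeds × 96 pooled diameters for mean recovery (2·SEM criterion), 500
sections for rate recovery (3·SE), and 200 random ≤ 64×64 images against a
brute-force flood-fill segmentation oracle. Images default to float64 in
memory and float32 on disk; pixel size travels in a JSON sidecar (exact)
mirrored into TIFF resolution tags (rational, ~10⁻⁴ relative precision);
CSVs are re-read with round-trip float parsing so the package's own outputs
reload losslessly.

## Known limitations

* The clustered fraction depends on the relative threshold, so it is
  undefined on empty images and sensitive to a single dominant bright
  structure; masks should be used for per-cell analysis.
* The cylinder scene model has no tubule curvature or branching, and
  opposite-band geometry is specified in projected offset, not arc length.
* The hurdle morphometry model decouples CJ-count intensity from the pinned
  prevalence; with a preset prevalence the conditional count distribution is
  zero-truncated and the pooled rate is no longer exactly cj_per_µm.
* ANOVA assumes homoscedastic normal groups; no robust alternative is
  provided.
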