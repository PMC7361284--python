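# cristaquant

Quantitative analysis toolkit for mitochondrial cristae nanoscopy and
electron-microscopy morphometry, aimed at researchers studying the MICOS
complex (Mic60/Mic10 subcomplexes), OPA1 and crista-junction (CJ)
biogenesis. It implements four analyses that are usually scattered across
ad-hoc scripts, plus seeded synthetic-data generators so every stage can be
exercised and validated without microscope data:

1. **Mic60 clustered-fraction statistic** for 2D STED-like images. The image
   is filtered with a blob-positive Laplacian-of-Gaussian (FWHM 80 nm),
   thresholded at 4% of the brightest response, and 8-connected components
   are labelled. Segments with area < 0.0225 µm² are *single clusters*, and

   clustered fraction = Σ area(single clusters) / Σ area(all segments).

   Higher values mean smaller, punctate Mic60 assemblies; lower values mean
   extended ring/rib-like assemblies.
2. **MINFLUX localization QC filter.** An event is kept iff
   p₀ < 0.11 ∧ r_rel < 32 nm ∧ rate ≤ 100 kHz ∧ photons > 1000 ∧ SBR > 0.6,
   with every failing criterion recorded per removed event.
3. **EM morphometry statistics**: CJ frequency per µm of outer membrane
   (pooled and per-section, with SEM), pooled CJ diameter mean ± SD,
   cristae-morphology class fractions, section-level junction/septum
   accounting, and the classical one-way fixed-effects ANOVA
   F = (SSB/df_b)/(SSW/df_w) used for all group comparisons.
4. **Line-profile averaging**: bilinear sampling along user lines, min–max
   normalization onto [0, 1], pointwise mean ± SD.

The synthetic generators place emitters on a cylindrical tubule surface
(orthographic projection) under four spatial models — scattered puncta,
perpendicular stripe patterns, two opposite longitudinal bands, and extended
arc assemblies — then render Gaussian-PSF/Poisson images; they also simulate
MINFLUX event mixtures with per-event ground truth and per-section
morphometry tables from condition presets.

## Worked example

```python
from cristaquant import (SceneParams, SceneModel, simulate_scene, render_image,
                         analyze_image, simulate_minflux_events, filter_events)

for model in (SceneModel.SCATTERED_PUNCTA, SceneModel.EXTENDED_ASSEMBLIES):
    params = SceneParams(model=model, seed=42)
    result = analyze_image(render_image(simulate_scene(params)))
    print(f"{model.value:22s} n_segments={result.n_segments:3d} "
          f"single={result.n_single_clusters:3d} "
          f"clustered_fraction={result.clustered_fraction:.3f}")

sim = simulate_minflux_events(n_valid=200, n_artifact=100, seed=42)
report = filter_events(sim.events)
print(f"kept {len(report.kept)}/{report.n_input} events; "
      f"removals per criterion: {report.counts}")
```

prints

```
scattered_puncta       n_segments= 16 single= 15 clustered_fraction=0.880
extended_assemblies    n_segments= 17 single= 13 clustered_fraction=0.566
kept 200/300 events; removals per criterion: {'P0': 20, 'R_RELATIVE': 20, 'RATE': 20, 'PHOTONS': 20, 'SBR': 20, 'MALFORMED': 0}
```

A tubule with scattered puncta scores a high clustered fraction (0.88: most
segmented area sits in sub-cutoff segments), while the same tubule covered in
extended arc assemblies scores much lower (0.57) — the direction the
statistic is designed to discriminate. The QC filter keeps exactly the 200
simulated valid events and attributes the 100 artifacts to the five criteria
in equal shares, as constructed.

The same pipeline is available from the shell:

```sh
cristaquant --seed 42 --output-dir out simulate-image --model opposite_bands
cristaquant --output-dir out cluster-metric out/scene.tif
cristaquant --output-dir out minflux-filter events.csv --photons-min 1000
```

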