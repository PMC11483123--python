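# vesiclefuse

Single-vesicle analysis of dense-core-vesicle (DCV) exocytosis and transport
in neurons, built around the NPY-pHluorin optical fusion reporter.

Neuropeptides are packaged in DCVs and released by calcium-triggered
exocytosis. With an NPY-pHluorin reporter, each fusing vesicle lights up
abruptly (the acidic lumen quenches the fluorophore until fusion), and a
final NH4+ perfusion dequenches every remaining labeled vesicle so the
unreleased pool can be counted. `vesiclefuse` implements the complete
quantification chain for such experiments:

* **Fusion-event detection** — 3×3-pixel ROI traces; an event is a transient
  that appears suddenly (rise to peak within ≤2 frames) with peak ΔF at
  least *k*·SD above the noise (default *k* = 2, robust MAD noise from the
  baseline epoch); automated candidate ROIs make the workflow unattended.
* **Pool and released fraction** — median projection over the NH4+ epoch,
  punctum segmentation with overlap correction by intensity quotient
  (each blob assigned `max(1, round(I / unit))` vesicles against a robust
  single-punctum unit), and released fraction = events / remaining pool.
* **Transport on kymographs** — wide-reslice kymographs along neurite
  polylines, punctum tracking, and the displacement rule for mobility:
  a punctum is *moving* if some 10-s window displaces it ≥ 3/4 µm.
  Per-kymograph moving fractions, cross-channel co-travel fractions, and
  min-to-max-normalized FRAP recovery curves.
* **Colocalization** — Pearson's r and Manders' M1/M2 (Otsu or manual
  thresholds) plus object-based containment fractions.
* **Morphometry** — immunofluorescence punctum counting with the
  quantile-mode single-DCV unit (mode of the first quartile of punctum
  intensities), skeleton-based neurite length (Σ of 1/√2-weighted pixel
  edges), densities, and length-count regressions.
* **Statistics** — Shapiro-Wilk/Levene screening, t-test or Mann-Whitney U
  for two groups, Kruskal-Wallis + Dunn (Holm-corrected) beyond two,
  Tukey-boxplot descriptives, per-experiment normalization to control.
* **Synthetic scenes** — a ground-truthed simulator (neurites, quenched
  vesicles, stimulation-locked fusion, NH4+ dequench, run-pause transport,
  photobleach, EMCCD noise) so every stage is testable end to end without
  experimental data. Condition presets encode published effect sizes
  (`KO-like` fusion rate = 3 × `WT-like`; `NPY-like` mobile fraction 0.47;
  `RPH3A-like` 0.105).

## Worked example

```python
from vesiclefuse.simulate import condition_preset, default_timeline, make_scene, render_movie
from vesiclefuse.pipeline import analyze_fusion_movie

cfg = condition_preset("KO-like", seed=3)      # 128x128 px, 2 Hz, 0.2 um/px
timeline = default_timeline(cfg)               # 30 s baseline, 2x8x50 AP at 50 Hz, NH4 at +50 s
truth = make_scene(cfg, timeline)
movie = render_movie(truth, cfg, timeline)
events, pool, release = analyze_fusion_movie(movie, timeline)
print(f"simulated {len(truth.fusion_schedule)} fusion events, detected {len(events)}")
print(f"remaining pool {pool.n_pool} (truth {truth.pool_size - len(truth.fusion_schedule)})")
print(f"released fraction {release.released_fraction:.3f}")
```

prints, for this seed:

```
simulated 18 fusion events, detected 17
remaining pool 33 (truth 42)
released fraction 0.515
```

17 of the 18 scheduled fusion transients pass the 2×SD sudden-appearance
rule; the NH4+ epoch reveals a remaining pool estimate of 33 puncta-worth
of vesicles (an underestimate here because this crowded default scene
leaves some sub-resolution clusters), and the released fraction divides
detected events by that pool. The `examples/` directory has one short
script per capability (fusion detection, pool/release, kymograph mobility,
co-travel, FRAP, colocalization, morphometry, group statistics, and the
end-to-end pipeline).

A thin CLI mirrors the library for shell use, e.g.
`vesiclefuse simulate --preset KO-like --seed 3 --out movie.ome.tif` and
`vesiclefuse detect --movie movie.ome.tif --timeline tl.yaml --out events.csv`;
run `vesiclefuse --help` for the full list.

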