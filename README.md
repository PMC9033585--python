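# aggremap

Quantitative image analysis of **centrosome-seeded aggresomes** and
**centriolar satellites** in multi-channel fluorescence microscopy.

When the proteasome is overwhelmed, cells concentrate misfolded protein into
a single juxta-nuclear inclusion — the aggresome — that assembles at the
centrosome. `aggremap` measures this process: it finds centrosomes from a
centriole-marker channel (e.g. CEP135), segments the aggresome around each
centrosome by seeded watershed on an aggresome-marker channel (e.g.
phosphorylated HSP27), maps the spatial distribution of PCM1-positive
centriolar satellites relative to the centrosome, scores channel
colocalization on aggresome-centred crops, quantifies clonogenic-survival
plates, and compares conditions with nonparametric statistics. A built-in
synthetic-microscopy generator with ground truth makes every stage testable
without any raw data.

The package is aimed at cell biologists quantifying pericentrosomal
phenotypes (aggresome growth, satellite clustering vs dispersal, knockout
contrasts) and at anyone needing a tested, scriptable reimplementation of
this measurement chain.

## The measurement model

* **Centrosome seeds.** Laplacian-of-Gaussian spot detection on the
  centriole channel; foci strictly closer than 8 px are merged to their
  intensity-weighted centroid (single-linkage, iterated to a fixed point);
  each merged focus is shrunk to a single pixel.
* **Aggresome morphometry.** The aggresome channel is background-subtracted
  at its lower quartile Q₁ (per image, linear-interpolation quantile);
  a seeded watershed expands from the centrosome pixels over the inverted
  intensity, bounded by the Otsu foreground of the subtracted channel.
  Readouts per seed: area *A* (px² and µm²) and background-corrected total
  intensity Σ max(0, I − Q₁) over the region.
* **Satellite cartography.** Around the seeds, an inner pericentrosomal
  disc (Euclidean distance ≤ 13 px) and an outer annulus (+100 px) are
  defined by distance transform. Granules are segmented by adaptive Otsu
  (inner) and global Otsu (outer), every object's position is recorded
  relative to its nearest seed, intensities are corrected by a scalar
  spurious-object reference estimated from knockout (satellite-null)
  images, and all cells are overlaid centrosome-centred into an
  intensity-weighted hexbin map normalized by cells × replicates. The
  headline statistic is the **inner percentage**: the share of total
  corrected intensity within the 13-px disc.
* **Colocalization.** Pearson's r = Σ(aᵢ−ā)(bᵢ−b̄)/√(Σ(aᵢ−ā)²Σ(bᵢ−b̄)²)
  per z-plane on 7.5 × 7.5 µm crops centred on the aggresome.
* **Colonies.** Crystal-violet plate scans are masked (smoothed Otsu),
  inverted, background-subtracted with a 50-px rolling ball, and the masked
  signal summed per well.
* **Statistics.** Kruskal–Wallis H on tie-corrected midranks with χ²
  p-values, Dunn post-hoc z tests (Bonferroni-adjusted), classical
  two-tailed unpaired Student t-tests, and box/whisker summaries (median,
  quartiles, 1.5×IQR whiskers).

## Worked example

```python
import aggremap as am
from aggremap import pipeline

cfg = am.AnalysisConfig()                      # 0.1 um/px defaults
field, truth = am.generate_field(cfg, "wt", rng_seed=1)

seeds = pipeline.find_seeds(field, cfg)        # detect -> merge(8 px) -> shrink
print("seeds:", [(x, y) for x, y, _ in seeds.foci])

df = pipeline.measure_aggresomes(field, cfg, seeds)
print(df[["seed_x", "seed_y", "area_um2", "total_intensity", "positive"]])
print("ground-truth area: %.2f um^2" % truth.aggresome_area_um2)

ko = [am.generate_field(cfg, "ko", s)[0] for s in (11, 12)]
records, dmap = pipeline.satellite_cartography([field], cfg, ko_fields=ko)
print("satellites: %d, inner share: %.1f%%"
      % (len(records), dmap.inner_percentage))
```

Output:

```
seeds: [(128.0, 132.0)]
   seed_x  seed_y  area_um2  total_intensity  positive
0   128.0   132.0     12.55    245153.810958      True
ground-truth area: 12.54 um^2
satellites: 21, inner share: 30.8%
```

The detected seed sits within a pixel of the simulated centrosome; the
measured aggresome area (12.55 µm²) matches the 12.54 µm² ground-truth disc;
and the clustered satellite condition concentrates ~31% of corrected PCM1
intensity in the 13-px pericentrosomal disc (a dispersed condition gives
~2%, the analytic uniform value).

## Command line

Every stage is also exposed as a subcommand of the `aggremap` console
script — `simulate`, `aggresome`, `satellites`, `coloc`, `colonies`,
`stats` — each taking `--config` (YAML), `--seed` and `--out`. For example:

```sh
aggremap simulate --out sim/ --seed 1 --n-fields 5
aggremap aggresome sim/manifest.csv --out areas.csv
aggremap stats areas.csv --out stats.csv --value area_um2
```

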