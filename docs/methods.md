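# Methods

This note records the models, conventions and open design choices behind
`aggremap`, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic benchmark does and does not show
about real data.

## Conventions

Coordinates are 0-based with x = column, y = row, pixel-centre; all
distances are Euclidean in pixel units, because the pipeline's spatial
constants (8-px merge, 13-px inner disc, 100-px annulus, 50-px rolling
ball) are defined in pixels. Quantiles everywhere — background subtraction,
box plots — are linear-interpolation quantiles between order statistics, so
a single oracle definition serves the whole package. Images carry a
required µm/pixel calibration supplied by the user (microscope metadata is
not parsed); the generator default is 0.1 µm/px, typical of a 60×
high-NA camera system. Z-stacks are reduced by maximum-intensity projection
for morphometry and cartography; colocalization is computed per z-plane.

## Centrosome seeds

The centriole marker appears as diffraction-limited spots. Detection is
Laplacian-of-Gaussian over σ ∈ [1, 3] px with a threshold relative to the
channel maximum (default 0.1). The detector itself is a free choice — any
spot operator would do — and is parameterized in `AnalysisConfig`.

Merging: foci strictly closer than 8 px ("closer than" read as d < 8)
are merged by single-linkage clustering, each cluster collapsed to its
intensity-weighted centroid with summed intensity. Collapsing can create
new sub-threshold pairs, so the pass iterates to a fixed point; this is the
only semantics under which the output simultaneously satisfies the
pairwise-distance guarantee (no two merged foci within 8 px) and
idempotence, and it is order-independent. Shrinking to a single pixel uses
round-half-to-even per axis (deterministic, unbiased); foci that land on
the same pixel collapse with summed intensity.

## Aggresome morphometry

Background is the image's lower quartile, subtracted and clamped at zero.
The watershed floods inverted intensity from the seed pixels; since a
marker-based watershed needs a support to stop in, expansion is bounded by
the Otsu foreground of the subtracted channel (computed per image). This
"propagate until the intensity threshold" reading mirrors the
secondary-object semantics of standard cell-image pipelines and makes area
well-defined; whether the original analysis capped expansion by threshold
or by distance is not recoverable, so the choice is documented here rather
than inferred. A seed whose pixel falls outside the foreground reports
area 0. Total intensity is the sum of the *subtracted* raster over the
region (subtraction before summation). The aggresome-positive call is
`area_um2 >= min_area_um2` (default 1 µm², configurable); the boundary is
inclusive.

Scale behaviour: multiplying a channel by a positive constant leaves areas
unchanged (Otsu and the watershed ordering are scale-equivariant) and
scales intensities proportionally — asserted in tests.

## Satellite cartography

Inner disc and outer annulus are built by Euclidean distance transform from
the seed pixels: inner = d ≤ 13, outer = 13 < d ≤ 113. "Expanded 13
pixels" is read as isotropic Euclidean dilation, not square dilation,
matching the radial logic of the overlay.

Granule segmentation is Otsu-based: per-tile (51-px window) thresholds
inside the inner disc, floored at the inner region's global Otsu; one
global Otsu for the annulus. Two guards are applied on top, both standard
in granule detection. First, every threshold is floored at a robust
image-wide noise floor, median + 5 × 1.4826·MAD of the subtracted raster:
Otsu applied to a signal-free region (a knockout image, or a background
tile) bisects the noise histogram and otherwise produces thousands of
spurious one-pixel objects. Second, components smaller than 3 px are
discarded as shot noise. Object intensity is integrated over the component
footprint expanded by 2 px (collision-free label expansion), so the
sub-threshold Gaussian skirt of a granule counts toward its total; without
this, totals are biased low by whatever fraction of the point-spread
function the threshold happens to cut.

Each object is assigned to its nearest seed (ties to the lowest seed
index); its region label follows from the centroid-to-seed distance versus
the 13-px radius. The knockout correction is a single scalar: the mean
per-object intensity measured by the same segmentation on satellite-null
fields, subtracted from every object and clamped at zero (records reaching
zero are kept with weight 0 so counts are preserved). A scalar is the
least-structured reading of "subtract based on knockout images"; a
per-pixel reference image would demand registered geometry the overlay does
not assume. Background subtraction happens per image before pooling.

The overlay assumes rotational similarity of cells: all records are pooled
by seed-relative position and binned into pointy-top hexagons (default
width 5 px, chosen to resolve the 13-px disc with at least two rings of
bins) via exact cube-coordinate rounding, so the map conserves total
weight; values are divided by n_cells × n_replicates. The inner percentage
is weight-ratio based and therefore independent of the normalizer and of
any global rescaling of intensities.

## Colocalization

Pearson's correlation on 7.5 × 7.5 µm crops centred on the aggresome seed
(the brightest merged centrosome focus), computed per z-plane; planes where
either channel is constant are skipped with a log message rather than
propagating NaN. Only Pearson is reported — no Manders/Costes variants.
Fewer than 10 image pairs per channel combination is a warning-level
concern, not an error.

## Colony quantification

The original plate segmentation used a per-replicate trained pixel
classifier, which cannot be shipped or specified; the mask here is Gaussian
smoothing (σ = 2 px) + Otsu on the inverted plate, with a contrast guard
that returns an empty mask when the foreground is not meaningfully brighter
than background (< 6 background SDs) — an empty plate must measure zero.
Everything downstream follows the stated chain exactly: threshold → mask →
invert → 50-px rolling-ball background subtraction → masked sum per well.

The rolling ball is `skimage.restoration.rolling_ball`. One pass leaves a
small uniform residual under tilted illumination (a ball of radius R under
a plane of slope s sags by ≈ R·s²/2), so the subtraction runs two passes;
the second removes the sag and makes the operation idempotent on smooth
backgrounds. On pixel noise no morphological background estimator is
idempotent — noise is not background — so idempotence is a clean-background
property.

## Group statistics

Kruskal–Wallis H on midranks with the standard tie correction and a χ²
approximation (k − 1 df). The Dunn post-hoc uses the pooled-midrank z
statistic with the tie term Σ(t³−t)/(12(N−1)) and two-sided normal
p-values; the multiple-comparison adjustment is Bonferroni over all pairs —
the conventional Dunn pairing, configurable to "none". The t-test is the
classical equal-variance Student test (no Welch correction), two-sided.
Box summaries: median, Q1, Q3, whiskers at the most extreme data points
within 1.5×IQR of the box.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes, with
ground truth recorded pre-noise:

* **Geometry.** A cell disc (radius 100 px = 10 µm) around one centrosome —
  a centriole pair 4 px apart (optionally two pairs), rendered as Gaussian
  spots (σ 1.5 px, amplitude 500) in the centriole channel.
* **Aggresome.** Wild-type-like: a uniform disc of configurable radius
  (default 20 px ⇒ 12.6 µm², a typical mature inclusion) at amplitude 200.
  Knockout-like: a thin ring (2–4 px) hugging each centriole — the residual
  pericentriolar signal seen when satellite trafficking is lost. A second
  channel (`ub`, emulating ubiquitin co-staining) shares the aggresome mask
  at 0.6× amplitude; a `noise` channel carries background only, as a null
  control for colocalization.
* **Satellites.** Clustered condition: isotropic Gaussian around the
  centrosome, σ = 10 px (1 µm), truncated to the cell disc — chosen so most
  satellite mass sits in or near the 13-px pericentrosomal disc, as in
  wild-type images. Dispersed condition: uniform on the cell disc.
  Knockout: none. Default 30 puncta per cell with a 5-px minimum separation
  (satellites are discrete granules); 30 keeps the rejection sampler from
  saturating the pericentrosomal core, which would flatten the clustered
  distribution. Each punctum is a Gaussian spot (σ 1.2 px, amplitude 300).
  Every condition additionally contains 4 dim nonspecific puncta
  (amplitude 60), the only objects in knockout fields — these give the
  knockout-based correction a real spurious signal to calibrate against.
* **Noise.** Gaussian PSF blur (σ 1 px), constant background (10 counts),
  Poisson shot noise, Gaussian read noise (σ 2). Signal-to-noise defaults
  are chosen as plausible for camera-based fluorescence, not fitted to any
  dataset.
* **Time course.** Aggresome radius 0 before a 2-h onset, then a
  square-root-in-time front (linear area growth) saturating at 5 h;
  knockout-like fields keep only the ring after onset. A time course
  follows a single cell (fixed centre) so ground-truth areas are nested and
  monotone.
* **Plates.** Gaussian-blurred flat discs (radius 6 px, amplitude 120,
  edge σ 1 px) on a bright background (220) with a planar illumination
  gradient (amplitude 20) and read noise; truth is the summed colony
  signal after inversion, before the gradient. Plateau-like discs, rather
  than literal Gaussian bumps, reflect real crystal-violet colonies and
  make "masked intensity" a faithful estimator of the total signal.

What passing the synthetic benchmark shows: the measurement chain is
internally correct — it recovers known areas, positions, intensity shares
and contrasts from images with realistic noise. What it does not show:
performance on real microscopy with cell-to-cell variability, uneven
staining, out-of-focus haze, touching cells or aggresome-adjacent satellite
signal; absolute numbers from the original study's unreleased images are
out of reach by construction, and no comparison to them is attempted.

## Problem sizes and determinism

Tests and the reproduction script use 256×256 fields, 3–10 simulation seeds
per condition, 2,000 null simulations for the Kruskal–Wallis calibration
and 200×200 plates — sizes at which every quantity of interest is stable to
well within its tolerance while the whole suite runs in a few minutes on a
single core. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; identical seeds reproduce fields bit-for-bit.

## Known limitations

* Cell boundaries are not segmented; satellite-to-cell assignment is by
  nearest centrosome seed, and per-cell aggregation of multi-seed cells is
  left to the caller (the generator places one cell per field).
* The adaptive-Otsu window (51 px) is tiled, not sliding; thresholds are
  piecewise constant across tiles.
* The knockout correction is a scalar per-object subtraction; structured
  spurious signal (e.g. spatially varying nonspecific staining) would need
  a richer reference model.
* The colony mask substitutes an untrainable classifier with
  smoothing + Otsu; on plates with very low colony contrast the guard may
  declare an empty mask.
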