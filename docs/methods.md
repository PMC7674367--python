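# Methods

This document describes the models, algorithms and numerical choices behind
cytomorph: a pipeline for quantitative cytoarchitecture that detects stained
cell bodies on grayscale histology-like images, measures ten morphometric
descriptors per cell, and compares multiple animal populations with
permutation-based multi-aspect inference and dominance ranking.

## 1. Synthetic data model

Real Nissl slides and multi-animal cell tables are not shipped; everything is
validated against two seeded generators with exact ground truth.

### 1.1 Slide generator (`cytomorph.synthetic.generate_slide`)

A slide is a `[0, 1]` grayscale raster (default 1 µm/px) with dark cells on a
light background (default level 0.71). The image height is tiled by
horizontal layer bands (molecular / Purkinje / granular by convention). Each
cell is drawn from an archetype — a named distribution of full major/minor
axis lengths (µm) and an intensity depth:

| archetype | major (mean ± SD) | minor | depth |
|---|---|---|---|
| stellate | 11 ± 1.2 | 8 ± 1.0 | 0.45 |
| basket | 19.5 ± 1.8 | 15 ± 1.5 | 0.45 |
| purkinje | 70 ± 5 | 50 ± 4 | 0.50 |
| granule | 11 ± 1.0 | 9 ± 0.9 | 0.45 |
| golgi | 28 ± 2.5 | 13.5 ± 1.5 | 0.45 |

Each cell is rendered as an anisotropic Gaussian intensity dip whose 2σ
contour equals the cell's elliptical boundary (i.e. σ along an axis is a
quarter of the full axis length), truncated at that contour. Cells are placed
by rejection sampling (10 000 attempts per cell, then `PlacementError` naming
the layer): non-clustered cells keep a per-layer minimum centre spacing;
a configurable `clustering` fraction is laid out as **touching pairs** whose
centre distance is 0.75 × the sum of the two semi-major axes — close enough
that the thresholded masks merge, exercising the declumping path. Finally the
image is blurred (Gaussian, σ = 0.5 px), corrupted with additive white noise
(default SD 0.02) and clipped to `[0, 1]`.

Scope and limitations: layers are straight horizontal bands (no folial
curvature), illumination is uniform (the adaptive threshold is still
exercised by local density variation and noise), staining depth is constant
per archetype, and overlaps beyond pairs are not generated. These keep the
ground truth unambiguous.

### 1.2 Cell-table generator (`generate_cell_table`)

Descriptor vectors for the statistical path follow an additive model per
population *j*, animal *a*, cell *i* and descriptor *k*:

```
Y = mu_k + tau_jk + animal_sd * u_a * sd_k + s_jk * sd_k * eps
```

with one standard-normal scalar `u_a` per animal **shared across
descriptors** (the animal-level random effect) and i.i.d. `eps`. Baseline
`mu` is a granule-like profile (area 83 µm², perimeter 30 µm, axes 11 × 9 µm,
solidity 0.93, extent 0.72, inv_ar 0.82, convex circularity 0.90, 12 / 40
neighbours within 50 / 100 µm) with within-animal SDs roughly 10–15 % of the
mean for size and density and small absolute SDs for the bounded regularity
ratios, which are clipped to `[0, 1]` after the draw.

Location shifts `tau` must sum to zero over populations; scale multipliers
`s` must be positive. `PopulationEffectSpec.from_sd_effects` expresses both
in within-SD units; "a d-SD effect between two populations" means their mean
difference is `d × sd_k` (symmetric shifts ±d/2).

**Why `animal_sd = 0.4`.** With 8 animals per population the standard error
of a difference of animal means is `sd · sqrt(2/8) · sqrt(animal_sd² + 1/n_c)
≈ 0.2 sd`. A 1-SD shift is then ≈ 5 SE (power ≈ 1) and a 0.5-SD shift ≈ 2.5
SE (power ≈ 0.8) for a one-sided α = 0.05 test — a regime in which power is
high but visibly monotone in the effect size. The value was fixed from this
arithmetic before the validation simulations were run.

## 2. Detection (`cytomorph.detect`)

1. **Adaptive threshold.** Polarity-corrected signal (cells bright) is
   compared with its moving-average over an odd square window (default
   25 µm) plus an offset (default 0.08). The local mean adapts to background
   trends a global threshold cannot follow; borders are reflected.
   *Caveat:* the window must exceed the largest soma of interest — a 25 µm
   window sits inside a 70 µm Purkinje body and fragments it; use 80–150 µm
   windows when large somata matter.
2. **Density partition.** The local foreground fraction over a window of four
   cell diameters labels each pixel dense/sparse (default cut 0.35),
   distinguishing packed granular tissue from sparse molecular tissue.
3. **Triage.** 8-connected components are classified by area and shape:
   singles (20–400 µm², solidity ≥ 0.88), Purkinje-like (≥ 800 µm², convex
   circularity ≥ 0.7, solidity above a floor that relaxes linearly with
   area), clusters (everything else of plausible area), rejects (< 20 µm²).
   All cutoffs live in `TriageRules`.
4. **Gaussian-mixture declumping.** Each cluster crop (padded 10 µm,
   background-subtracted with the border median) is fitted with a 2-D
   Gaussian mixture by nonlinear least squares (`scipy.optimize.least_squares`,
   tolerances 1e-10). The number of modes equals the number of local maxima
   of the σ = 1 px smoothed crop (minimum peak distance 4 µm, relative
   threshold 0.10). Each covariance is parameterized by its lower-triangular
   square root, which keeps it positive-definite without constraints; its
   entries are box-bounded so eigenvalues stay in `[1, 400]` µm² (sub-µm
   specks to Purkinje-scale somata). Each Gaussian is `exp(-½ d²)` with
   Mahalanobis `d`, so the amplitude is the peak height directly.
5. **Ellipse conversion.** Each fitted mode becomes a cell whose semi-axes are
   `mass_level × sqrt(eigenvalues)` with `mass_level = 2.0` — the same 2σ
   contour at which the generator truncates its dips, making detected and
   true axes directly comparable (≈ 86 % of the Gaussian mass).
6. **Evaluation.** Detections and truth centres are matched greedily
   nearest-first within a radius (default 5 µm), one-to-one; TP/FP/FN follow.
   A detection still adjacent to ≥ 2 attached truth centres counts one
   *remaining cluster* (an under-split clump).

Validated on synthetic slides: 500 separated granules → precision ≈ 0.99,
recall 1.0, median centroid error ≈ 0.12 µm; with 20 % of cells in touching
pairs ≥ 90 % of pairs split into exactly two detections with centre error
≤ 1.5 µm; a noiseless mixture render is recovered with centre error ≤ 0.25 µm
and residual < 1e-6 of signal energy.

## 3. Morphometry (`cytomorph.morpho`)

Ten descriptors in three domains:

- **size** — area (µm²), perimeter (µm), major and minor full axis length.
- **regularity** (all dimensionless, in `[0, 1]`) — solidity (area /
  convex-hull area), extent (area / bounding box), inverse aspect ratio
  (minor / major), convex circularity (4π · convex area / convex
  perimeter²).
- **density** — neighbour counts within 50 µm and 100 µm of the centre
  (self excluded; optionally restricted to the same tissue section).

Numerical choices that matter:

- **Perimeter.** Crofton estimator (4 directions) for pixel masks — naive
  edge counting overestimates by up to 4/π and can push circularity past 1 —
  and the Ramanujan approximation for parametric ellipses (relative error
  < 1e-4 against quadrature over the tested range).
- **Convex circularity from the polygon hull.** The hull polygon through the
  pixel centres (`scipy.spatial.ConvexHull`) supplies a *consistent*
  area/perimeter pair, so the isoperimetric inequality bounds the ratio by 1
  for any shape; mixing pixel-count area with a rasterized hull perimeter
  does not (a radius-8 disc scores ≈ 0.91 that way vs ≈ 0.98 here).
- **Solidity.** `convex_hull_image(offset_coordinates=False)`: the
  corner-offset variant systematically inflates hull area and drags convex
  shapes below solidity 1.
- **Axes.** From normalized second central moments (`regionprops`), matching
  the ellipse-of-inertia convention used by the detector's fitted
  covariances.
- Masks with < 5 pixels or a zero minor axis raise "degenerate boundary".

**Cell typing** is layer-aware: Purkinje layer → purkinje; granular layer →
granule (major axis ≤ 15 µm) or golgi; molecular layer → stellate vs basket
at a data-driven cut: the exact 1-D two-means split of the molecular major
axes (scan of all split points of the sorted sample), falling back to 15 µm
with a warning for < 10 cells or zero spread.

## 4. Multi-aspect inference (`cytomorph.mastats`)

Cells within an animal share a random effect, so cells are not exchangeable
across populations — **whole animals are**. All tests therefore operate on
animal-level summaries and permute or sign-flip animals:

- **Aspects.** *Location*: per-animal descriptor means; the pairwise partial
  statistic is the difference of animal means. *Scatter*: per-animal mean of
  `|value − own-animal median|` (a Brown–Forsythe-type dispersion summary);
  using each animal's own median makes the statistic exactly invariant to
  population-level location shifts, cleanly separating the two aspects.
- **Pairwise partial tests.** One-sided p = fraction of relabelings whose
  statistic reaches the observed one; the observed labelling always counts,
  so p ≥ 1/n_perm. All C(m, n) relabelings are enumerated when that is no
  more work than B random ones; sign-flip tests enumerate all 2^n flips under
  the same rule. A `exchange_unit="cell"` variant (relabel cells, ignore
  animals) exists only to demonstrate the resulting type-I inflation
  (≈ 0.4 at nominal 0.05 on the null generator).
- **Pairwise-restricted relabelings.** Each unordered population pair
  permutes only its own two populations' animals: the pair's null asserts
  exchangeability between those groups, and mixing in a third population that
  carries real effects would widen the reference distribution and destroy
  power. Within a pair, one relabeling set is shared by every descriptor and
  both directions; across pairs, sets are drawn independently with
  synchronized counts.
- **Nonparametric combination.** Partial statistics are converted to attained
  significance levels against the shared permutation distribution; the
  combining function (Fisher `−2 Σ log L`, or Tippett `min L`) is evaluated
  on every permutation, and the combined p is the upper tail of the observed
  combined statistic. This respects arbitrary dependence among descriptors.
- **Multiplicity.** The six directional hypotheses of each 3 × 3 matrix are
  adjusted by Westfall–Young free step-down min-p on the stacked
  per-permutation levels (monotone, never below raw; perfectly dependent
  hypotheses pay no penalty). Without a shared null the adjustment degrades
  to Bonferroni–Holm.
- **Univariate summaries.** µ (grand mean), τ (population deviations, summing
  to zero at equal cell counts), σ² (variance of animal-centred residuals),
  and per-(population, descriptor) block sign-flip tests rendered as
  ↑/↓ arrows at α = 0.01.

Calibration on the null generator (3 × 8 × 150 cells, 400 replicates,
B = 300): combined location and scatter tests reject at ≈ 0.04–0.05 at
nominal α = 0.05; power of the combined location test ≈ 0.8 at a 0.5-SD
shift and ≈ 1.0 at 1 SD.

## 5. Ranking (`cytomorph.ranking`)

Population *j* dominates *h* for an (aspect, domain) when the adjusted
one-sided p for "j larger than h" is ≤ α (default 0.05). A population's rank
is 1 + the number of its dominators, producing a weak order rendered as e.g.
`F > FM > M` or `F = M > FM` (ties alphabetical). Intransitive patterns
collapse to ties and are flagged `[cyclic dominance]` instead of being
silently reported. With adjacent effects spaced 1 SD the true order is
recovered in ≈ 94 % of replicates (B = 999, α = 0.05).

## 6. Pipeline and reproducibility (`cytomorph.pipeline`, `cytomorph.cli`)

One YAML document drives the run (`configs/demo.yaml` is a complete
example); stage order is simulate → detect → measure → test → rank → report,
any subset selectable. Every CSV/JSON output embeds the SHA-256 config hash
and seed in a header comment, and a rerun under the same config is
byte-identical (figures exempt). Errors abort with the failing stage's name
and a nonzero exit code; the run log records the defaults actually used
(window, offset, B, seeds, α).

The report stage adds descriptive views: per-domain PCA histograms (pooled
correlation matrix; component sign fixed positive on the domain's first
descriptor so histograms are comparable across runs), seeded k-means
(10 restarts) with a cluster-by-population contingency table, and bivariate
kernel-density contour plots with a fixed color map (orange = F, green = FM,
light blue = M).
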