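# Methods

`colonymorph` quantifies the colony morphology of live, unlabelled
human pluripotent stem-cell (hPSC) cultures from phase-contrast well
images and screens for the "cluster-A" phenotype: colonies with
collapsed, irregular edges and a flat, low-contrast periphery, the
morphological signature of an unstable, partially differentiated state
enriched in aberrant subclones. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Imaging model (synthetic generator)

Real acquisition uses an automated incubator microscope producing
8-bit grayscale tiles of 1,000 × 1,000 px covering 2,000 × 2,000 µm²
(2 µm/px). The generator emulates that geometry phenomenologically
rather than optically:

- **Background**: constant level 100 plus a tilted-plane gradient
  (amplitude configurable, default 10 grey levels; direction drawn from
  the scene seed).
- **Colony boundary**: a radius-modulated closed curve
  r(θ) = r₀(1 + e·w(θ) + f(θ)). `w` is a normalized sum of harmonics
  k = 2…5 and `e` (`edge_irregularity` ∈ [0,1]) is the maximum
  fractional radius deviation it contributes; `f` adds narrow Gaussian
  bumps in θ (count ≈ `fibrousness`, height 6–12 % of r₀, width
  0.03–0.05 rad) — the "fibrous points" of a collapsed outline. The
  boundary depends only on the colony's own parameters (hashed into a
  private RNG), never on the scene seed, so ground truth is invariant
  across noise realizations. A colony declared `collapsed_edge` must
  have e ≥ 0.15 (the documented floor).
- **Optics**: a bright halo ring (default strength 45 grey levels,
  width 6 px, tapering) just outside the boundary; an interior
  depression of 28 grey levels with clipped (±2σ) texture noise
  (`interior_texture_sd`); ESC-like colonies get an extra 6-level
  central darkening. With clipped texture the noise-free
  foreground-background contrast never falls below 28 − 2σ_texture
  (≥ 3 grey levels at the largest texture used, σ = 12).
- **Debris**: 2–8-px-radius specks of ±30–60 grey levels — well below
  the 2,046-px noise-reduction gate, exercising that step and the known
  failure mode of floating debris.
- **Noise**: additive Gaussian, then rounding to uint8. Scenes with
  pairwise colony-mask overlap above 10 % of the smaller mask are
  rejected as over-occluded.

`render_rotated(spec, half_turn=True)` rotates the noise-free optical
scene by 180° and draws *fresh* noise, modelling a physically rotated,
re-imaged plate.

**Two-population benchmark.** `make_two_population_benchmark(n, effect,
seed)` draws balanced single-colony scenes (960 × 960 px so that a
mature colony never clips the frame): base radius 255–285 px
(equivalent diameter 1.02–1.14 mm at 2 µm/px), shared baseline
parameters, and class deltas scaled by `effect` — at `effect = 1` the
collapsed-edge class adds 0.26–0.34 edge irregularity, 5–8 fibrous
spikes, −25 halo strength and +5 interior texture SD. At `effect = 0`
the two class distributions coincide exactly. These deltas are the
benchmark's calibration: they were fixed once so that the documented
pipeline separates the classes, and they define the study conditions
for every downstream reproducibility figure.

## Segmentation (six steps)

1. **Background flattening** — local median (7 × 7 px, reflect
   padding) subtracted, then the configured grey level 90 restored and
   the result clipped to [0, 255]. A constant image maps to 90; ramps
   varying slower than the kernel scale are removed. The stated grey
   value is interpreted as the restored background level (configurable).
2. **Texture recognition** — per-pixel features on the flattened
   image: local mean, local SD and smoothed Sobel gradient magnitude at
   5 px and 15 px windows, a half-resolution local entropy (disk radius
   4 on a 2 × 2 block-mean image, replicated back up), and raw
   intensity. All windows are centro-symmetric, so recognition commutes
   exactly with a half-turn rotation (for even image sizes).
   Training fits 50 randomized candidates — random feature subset
   (≥ 3) and regularization C ∈ 10^[−2,2] of a logistic per-pixel
   classifier on ~2,500 sampled pixels per class per image — and keeps
   the best held-out (one-third split) pixel accuracy. The foreground
   decision is probability > 0.5.
3. **Noise reduction** — 8-connected components with area strictly
   below 2,046 px removed (the stated value is the smallest surviving
   size).
4. **Object filling** — 4-connected enclosed background holes of
   ≤ 30 px filled; frame-touching background is never a hole.
5. **Manual cleansing** — an exclusion list of labels, by design never
   an automatic heuristic.
6. **Size gates** — connected components strictly > 30,000 px become
   colonies (labels in raster-scan order of first pixel); the maturity
   gate keeps equivalent-circle diameter 2·√(A·µm²/π) strictly
   > 1,000 µm. Note 196,349 px at 2 µm/px fails the gate and
   196,350 px passes (the boundary is π·500²/4 ≈ 196,349.54 px).

Conventions: 0-based row/column raster coordinates, origin top-left;
8-connected foreground with 4-connected holes (the complementary pair
that avoids topological paradoxes).

## Morphometric panel

Each colony gets 120 parameters in three families (40 volume,
36 shape, 44 frequency), in a fixed canonical order:

- **volume** — pixel/µm areas and perimeters (Crofton 4-direction
  perimeter, which is nearly unbiased on smooth discretized outlines),
  convex hull measures, axis lengths, Feret maximum, and intensity
  statistics of the raw image over the mask, over inner rim bands
  (5/10/20 px by Euclidean distance transform), eroded cores, and
  outer halo bands.
- **shape** — circularity 4πA/P², solidity, convexity P_hull/P,
  eccentricity, extent, aspect ratio, the seven Hu moments
  (signed-log scaled), radial-distribution shape (CV, skew, kurtosis,
  min/max ratio), and erosion/dilation area profiles.
- **frequency** — descriptors of the outline's radius series:
  256 equal-angle radii about the centroid (outer envelope per angular
  bin, circularly interpolated across empty bins). From it: normalized
  Fourier harmonic magnitudes (k = 2…32) and band energies — the low
  band (k 2–4) is the outline-smoothness complement, the high band
  (k 9–32) plus curvature-peak counts form the fibrous-points score —
  polar-curve curvature statistics (series pre-smoothed by a 5-sample
  circular moving average so pixel jitter does not dominate the second
  derivative), multiscale roughness, and radius-peak counts.

Equal-angle sampling was chosen over equal-arclength resampling
deliberately: under a 180° raster rotation the angular bins shift by
exactly 128 of 256, so every boundary descriptor is invariant up to
floating-point roundoff — the property that underwrites the
plate-rotation reproducibility experiment. Equal-arclength resampling
is only approximately invariant because its origin moves with the
contour start point.

Colonies touching the frame are profiled but flagged and excluded from
database construction by default.

**Parameter selection.** Two greedy filters, applied in this order and
idempotent as a composition:

1. correlation filter — walking the canonical order, drop any
   parameter whose |Pearson r| across colonies with an already-kept
   parameter exceeds 0.98 (the earliest kept parameter is recorded as
   its representative; correlation with a zero-variance column is
   defined as 0);
2. CV filter — drop parameters with 100·SD/|mean| > 30 on raw values
   (sample SD; zero-mean columns are dropped as infinite-CV).

On the synthetic benchmark roughly 30–35 parameters survive, spanning
all three families. The panel is versioned; the counts depend on the
data and no fixed survivor count is claimed.

## Colony database

Selected parameters are z-scored per parameter (sample SD, n−1).
Standardization before clustering is this package's choice — uncentred
correlation across parameters with heterogeneous units would otherwise
be dominated by large-magnitude parameters; it can be disabled for a
strict-replication run.

**Clustering** is agglomerative average linkage on distance
1 − uncentred correlation, where uncentred correlation is the
cosine-type similarity Σxᵢyᵢ/(‖x‖‖y‖). The Lance–Williams recursion is
implemented directly so the stored merge similarities are exactly the
values used and ties in the minimum distance break deterministically
toward the smallest (node_a, node_b) id pair. Tests verify exact
agreement with an independent brute-force average-linkage oracle and
with scipy's implementation on tie-free instances.

**Pruning** inverts the test of no correlation: with p parameters the
two-sided Student-t critical value t* at α = 0.05 and df = p − 2
converts to r* = t*/√(df + t*²); for p = 27, t* = 2.059539 and
r* = 0.380863. Clusters are the maximal subtrees whose internal merge
similarities all exceed r*, so every within-cluster join passes the
test of no correlation. The threshold is compared against the tree's
uncentred-correlation merge heights (the test is derived for Pearson
r; both similarity definitions are available, and neither is asserted
to be the original software's exact behaviour).

**Major clusters** contain strictly more than floor(0.05·N) colonies —
at N = 303 more than 15 — reconciling the ">5 %" and ">15 colonies"
statements so both hold simultaneously. Clusters are lettered A, B, …
(at most 20, A–T) by a composite key: aberrant-line-enriched clusters
first (within-line existence ratio higher for the aberrant than the
reference line), then major before minor, then descending mean colony
area. Cluster A is therefore the aberrant-enriched phenotype by
construction.

## Classification

A query profile is standardized with the *database* statistics and
compared with every database colony by centered Pearson correlation;
it inherits the cluster of the single best match (ties break by
database order). Pearson matching against an uncentred-correlation
dendrogram is a deliberate asymmetry of the original procedure and is
preserved. No rejection threshold is applied; a minimum-r warning is
available but off by default. A nearest-centroid mode exists for
robustness studies only.

## Expression validation

- **Normalization**: per-colony 75th-percentile shift on log2 values
  (linear interpolation between order statistics), leaving every
  colony's 75th percentile exactly 0.
- **Differential testing**: per-probe two-sample t-test of one cluster
  against the rest with Benjamini–Hochberg adjustment across all
  probes; significant at adjusted p < 0.05. Welch's form is the
  default (single-colony groups are small and unbalanced, e.g. 6 vs
  26); the pooled form is selectable. Fold changes are linear-scale
  ratios of de-logged group means, direction-signed as higher/lower in
  the target cluster.
- **A caution on Welch at extreme tails**: with m ≈ 800+ probes, BH
  effectively asks for p-values near 1/m. At 6-vs-26 the
  Welch–Satterthwaite approximation is anti-conservative that far into
  the tail (simulated family-wise null error ≈ 0.25 vs 0.04 for the
  pooled/exact form under equal variances). The FDR-control test
  therefore evaluates the pooled form, which is exact under the
  simulated equal-variance null; Welch remains the screening default
  because real single-colony groups need not share variances.
- **Clustering/PCA**: expression dendrograms use the same average-
  linkage/uncentred-correlation engine as the colony database;
  optional per-probe median centering mirrors a baseline shift. PCA is
  probe-centered SVD with the sign convention that each component's
  largest-magnitude loading is positive.
- **Synthetic matrices**: per-probe Gaussian log2 baselines
  (mean 8, SD 2), iid noise (default SD 0.5), per-colony technical
  offsets (±1, removed exactly by percentile normalization), and
  ±log2(fold) shifts on spiked probes in the target group, alternating
  direction.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed
(numpy PCG64); identical inputs and configuration give bit-identical
images, databases and saved files. The standard verification sizes
used by the tests and analysis scripts: texture training on six
512 × 512 fixtures; database and hold-out draws of 20 colonies per
class at effect 1; 15 colonies for the rotation study; expression
designs of 800–2,000 probes with 6-vs-26 groups and 100 probes spiked
4-fold; dendrogram oracles at n ≤ 8 leaves × 200 random instances.

## What the synthetic benchmark does not show

The generator reproduces the *cues* the method exploits (edge
collapse, halo loss, flat periphery, fibrous outline) but not real
phase-contrast optics (no wave-optics halo, no meniscus or tiling
seams), no colony merging or growth dynamics, and no biological
variability beyond the parameter draws. Passing the separation and
rotation suites therefore demonstrates the pipeline's internal
correctness and stability, not field performance on real cultures; the
published real-data figures (cluster membership percentages, probe
counts, staining rates) require the original images and arrays and are
out of scope here.

## Known limitations

- The 120-parameter panel is this package's documented equivalent of
  the original (unpublished) panel: the three families and the two
  anchored descriptors (outline smoothness, fibrous points) are
  covered, but no parameter-by-parameter mapping is claimed, and no
  fixed "27 survivors" count is asserted on other data.
- The texture recognizer is a documented re-implementation, not the
  proprietary original; only behavioural equivalence on fixtures is
  claimed.
- The equal-angle boundary representation takes the outer envelope per
  angular bin, so deeply re-entrant outlines (radius multivalued in θ
  with inner lobes) are smoothed; for the star-shaped-to-wavy colonies
  modelled here this is exact.
- Merged-colony splitting and time-lapse tracking are out of scope.
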