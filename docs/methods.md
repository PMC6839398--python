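# Methods

This note documents the models, numerical choices and limitations behind
each stage of the package. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic shape model

A sperm-head outline is a **superellipse body fused with a tapering
circular-arc hook**:

- body: `|x/a|^n + |y/b|^n = 1` with exponent `n = 2.5`, semi-axes
  `a = body_length/2`, `b = body_width/2`;
- hook: a circular-arc centerline of length `hook_length` rooted near the
  anterior tip, taking off at 55° and turning through
  `φ = clip(0.55 + 0.55·acrosome_curvature, 0.15, 2.7)` radians, carrying a
  band whose half-width tapers from `base_width/2` to 0.03 µm with exponent
  `q = 0.8 + 0.5·acrosome_curvature`. Tying both the bend and the taper to
  `acrosome_curvature` makes "more curved acrosome" and "sharper apex"
  co-occur, which is what the mutant morphology shows; with a fixed taper, a
  shorter mutant hook would measure *blunter* at the apex window and the
  planted ordering would invert.

The two polygons are fused by union (shapely), oriented counterclockwise,
resampled to 400 equally spaced vertices, scaled by `√area_scale`, and
individualized by a low-order Fourier radial perturbation of 0.5% amplitude
(seeded). Parameters must be positive; the hook-tip coordinate is returned
as ground truth on request.

Default wild-type parameters (µm): body 8.0 × 4.0, hook 3.2, curvature 1.0,
base width 1.4 — head area ≈ 29 µm², consistent with a mouse sperm head.
Genotype effects shift all cells (Yq-del: curvature +0.45, hook −0.35,
area −6%, body −0.30, base −0.10; shSLY larger still). Sex effects shift
**Y-bearing cells in mutant genotypes only**: curvature +0.10, hook −0.08,
area −1.5% — roughly half a within-population SD per parameter (SDs:
curvature 0.22, hook 0.20, …), so the X and Y shape distributions overlap
substantially. These defaults were chosen once so that clustering a
Yq-del population recovers a normal-cluster X proportion near 58–59% (the
documented calibration target); they are not estimates of real per-cell
distributions, which the source data do not report.

What the generator does *not* emulate: flagella, acrosome biochemistry, 3D
structure, staining heterogeneity, debris/overlapping cells, Poisson shot
noise (immaterial at the contrast used — images use Gaussian blur plus
additive Gaussian noise). Passing tests therefore demonstrate correctness
of the measurement and inference machinery under a clean, known generative
model, not robustness to every real-microscopy artifact.

## Segmentation

Otsu thresholding (or a fixed threshold), border-component removal,
hole-filling, connected components filtered to [min_area, max_area] µm².
Outlines are the marching-squares contour at the half level, converted to a
y-up µm frame, smoothed by a circular moving average over 2% of the
perimeter to suppress pixelation, and oriented counterclockwise. Round
trips (polygon → raster → segment → outline) preserve area within 2% at
pixel sizes ≤ 0.1 µm/px. `smooth_resample` performs pure arc-length
resampling by default — smoothing is opt-in there because a moving average
legitimately shortens a wiggly border, and the perimeter contract (±1%)
applies to resampling.

## Angle profile and anchoring

At each of 100 equally spaced perimeter positions `p`, the profile holds
the interior angle ∠(A, p, B) with A and B half a window before/after `p`
along the outline (window default 5% of perimeter; values ≥ 50% are
rejected). Convex vs reflex is resolved by the sign of the turn from
`p−A` to `B−p` against the counterclockwise orientation. Closed-form
checks: a circle gives `180° − 180°·f` everywhere; a square gives 90° at
corners and 180° mid-edge.

The hook apex is the global profile minimum (ties → earliest index;
near-constant profiles, range < 5°, raise a "no landmark" error). Profiles
are anchored by locating the apex on a 10× finer profile and starting the
final 100-point sampling **exactly** at that arc fraction. Anchoring to the
nearest coarse index instead leaves ±1-index jitter on the steep apex ramp,
which dominates Euclidean profile distances and destroys downstream
clustering — this was measured, not hypothesized.

Morphometrics: area (shoelace), perimeter (arc length), length (max caliper
over convex-hull vertex pairs), width (extent perpendicular to the caliper
direction), circularity `4πA/P²`, regularity `A/(π·L·W/4)` (area relative
to the ellipse spanned by length and width — the stand-in definition used
here), and the profile minimum. X-vs-Y comparisons use Wilcoxon rank-sum
tests per parameter with Bonferroni correction across parameters and a
0.01 family-wise threshold.

## Consensus

Outlines (equal point counts required) are index-rotated so the apex is
vertex 0, centered, optionally scaled to unit centroid size, then rotated
to the running mean by 2D least-squares rotation (no reflections, ever),
iterating from a permutation-invariant initial mean until the mean moves
< 10⁻⁶ of the mean radius (cap 200 iterations). The consensus is the
vertexwise mean with a per-vertex radial IQR envelope. The vertexwise-mean
scheme after landmark alignment is this package's documented choice.

## Clustering and composition

Ward linkage (scipy) on either the raw 100-vector profiles (seed-free;
default) or a Barnes-Hut t-SNE embedding (perplexity 100, 1000 iterations,
PCA initialization, fixed seed — requiring ≥ 3·perplexity cells); the
feature space used is recorded on the assignment. The dendrogram is cut at
a configured k, or at the silhouette-maximizing k ∈ 2..8 when unset — an
explicit rule standing in for cutting by eye. Per-cluster composition
reports `n_X`, `n_Y`, unknown-label counts, `p̂`, `SE = √(p̂(1−p̂)/n)`, and
one-sample Z-tests against 0.5 with Holm correction across clusters.
Clusters are ranked by the distance of their mean profile to a reference
(e.g. the wild-type mean) to name the "normal-shaped" cluster objectively.

## Capture/recapture matching

Candidates are all cross-phase pairs within a stage-coordinate radius
(k-d tree). Scoring resamples the post image to the pre pixel size,
centers it on the pre canvas, registers translation by phase
cross-correlation (stage repositioning is ~1 µm accurate), and averages
Gaussian-window SSIM over 3 dyadic scales. Identical images score exactly
1.0. Assignment is greedy by descending similarity with deterministic
tie-breaks (smaller distance, then lowest ids) and never violates
one-to-one-ness. The published star-variant of multi-scale SSIM is not
restated in the source; plain multi-scale SSIM is used — the task only
needs a ranking score. The FISH fixture distortion is an isotropic 10%
dilation plus blur and fresh noise; the acceptance threshold (default 0.5)
is a config value with no external anchor.

## Swim-up statistics

The generator draws, per male × state × fraction, a latent X proportion
`p ~ Beta(µφ, (1−µ)φ)` with `logit(µ)` linear in the centered fraction
index (killed-state slope always 0; default slopes WT −0.05, Yq-del +0.15,
φ = 150, 400 cells/fraction, 10 males), then `x_count ~ Binomial(400, p)`.
The analysis model — logit-link beta regression of the observed proportion
on `genotype × state × segment` with one log-scale precision — therefore
has the correct mean structure and approximately correct dispersion.
Boundary proportions (0 or 1) are shrunk by `(y(n−1)+0.5)/n` before
fitting. Segment enters numerically by default (the trend is the estimand);
a categorical mode is available through the formula. Rank-deficient designs
and non-convergence raise errors. Likelihood-ratio tests use
`2Δℓ ~ χ²(Δdf)`.

Proportion machinery: `SE = √(p̂(1−p̂)/n)`; two-proportion Z-tests are
pooled and two-tailed with the Yates continuity correction **on by
default** — the published resorption p-values (0.38, 0.13) are reproduced
by the corrected test (0.375, 0.133; the uncorrected test gives 0.29/0.10)
and the corrected form is algebraically identical to R's `prop.test`
chi-square. Exact binomial tests use the minimum-likelihood two-tailed
definition (a doubled-tail option exists). Wilcoxon rank-sum is exact for
≤ 20 combined tie-free values, tie-corrected normal otherwise; KS tests use
the asymptotic p.

## Pipeline and seeds

One pipeline seed is split by `numpy.random.SeedSequence.spawn` into logged
per-stage seeds. All intermediates are plain CSV/SVG/JSON; the manifest
records config, stage seeds and SHA-256 digests of every output, and
identical configs reproduce identical digests. Default problem sizes
(500 cells/genotype in the pipeline config; 200–1000 cells, 50 images and
200–500 regression replicates in the tests and acceptance script) were
chosen as the smallest sizes at which the calibration checks are stable.

## Known limitations

- The shape parametrization is a stand-in; real per-cell parameter
  distributions are unknown, so only qualitative orderings and the
  calibrated cluster-composition range carry over.
- "Regularity" follows the stand-in definition above; the original
  measurement suite defines it elsewhere and may differ.
- Beta regression pools fraction counts; no per-male random effects.
- t-SNE determinism holds for a fixed seed, library version and input;
  across versions the embedding (not the profile-space clustering) may
  change.
- Matching assumes the recapture preserves each cell's orientation (true
  for slide re-imaging); it is not rotation-invariant.
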