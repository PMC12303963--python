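# Methods

`chromascape` quantifies how the *spatial structure of color* in a
landscape photograph relates to its *perceived healing quality*. The
pipeline has two arms — a color arm that turns an image into 18 spatial
metrics, and a psychological arm that turns semantic-differential
ratings into perceptual factor scores — joined by a correlation table.
This note records the model choices, defaults, and the limits of what the
synthetic-data validation can show.

## Color segmentation

Each 8-bit sRGB photograph is decomposed into six binary masks, one per
color category (red, yellow, brown, gray, white, green). A pixel belongs
to a category when all three of its channel values fall inside that
category's inclusive RGB range. The default palette encodes the range
table for a traditional Japanese garden (e.g. red: R 131–208, G 8–120,
B 2–82; white: 212–255 on all channels); any palette can be supplied as a
name → (R lo, hi, G lo, hi, B lo, hi) mapping.

The ranges overlap — (150, 150, 150) satisfies both the brown and the
gray box — so two modes exist. `non_exclusive` keeps six independent
masks (the input of the per-color metrics). `exclusive` assigns each
pixel to the first matching category in a fixed precedence order,
**white > green > red > yellow > gray > brown** (most specific range
volume first, configurable), which yields the partition needed for area
proportions. The brown B-range (54–194) is implemented verbatim from the
published table even though it subsumes gray's; whether that is a
typographical artifact cannot be decided from the source, so the
configurable palette is the escape hatch. Pixels matching no category are
excluded from the proportion denominator (the diversity index is defined
over exactly six categories); the unclassified fraction is reported per
image.

## Spatial metrics

**Fractal dimension D** (spatial complexity). For box sizes ε the number
N(ε) of ε×ε grid cells containing any foreground pixel is counted on a
single top-left-anchored grid, partial edge boxes included; D is the OLS
slope of log N(ε) on log (1/ε). The default ladder is the twelve powers
of two 1, 2, …, 2048, dropping sizes that exceed min(H, W). Trailing
scales stuck at N = 1 beyond the first are trimmed before the regression
— they carry no information and flatten the slope. At least three usable
scales are required. Sanity anchors: a filled square gives D = 2.000, a
one-pixel line D = 1.000, and a depth-5 Sierpinski carpet (243²) gives
D ≈ 1.86 against the similarity dimension log 8 / log 3 ≈ 1.893. The
≈0.03 gap is the expected finite-size bias of power-of-two boxes on a
base-3 fractal, not an implementation error; the ladder is configurable
when base-aligned scales are wanted.

**Diversity H′** (evenness). Globally, H′ = −Σ pᵢ ln pᵢ over the six
exclusive-mode area proportions (0·ln 0 ≡ 0), ranging 0 to ln 6 ≈ 1.79.
Per color, the published tables report an H′ per category, for which an
across-category entropy is undefined; this package's convention is
*spatial* evenness: the frame is split into an 8×8 block grid, p_b is the
share of the color's pixels in block b, and H = −Σ p_b ln p_b, normalized
by ln 64 to [0, 1]. It is 0 when the color is confined to one block and
1 when spread evenly — a documented stand-in for an unstated upstream
computation, not a reproduction of it.

**Concentration C** (clustering). Moran's I of the color's presence on a
coarse lattice: I = (N/W) Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)². Pixel-level
weights matrices are infeasible at 10⁶ pixels, so the binary mask is
coarsened to a 100×100 lattice of block-mean presence values in [0, 1]
(capped at the mask size). Weights are rook contiguity, row-standardized,
by default; queen and binary-weight variants are available. Anchors: a
unit checkerboard gives exactly −1, a half-plane split on a 4×4 lattice
gives 17/24, one compact disc scores far above the same area scattered as
25 discs. Constant lattices (color everywhere or nowhere after
coarsening) have no spatial variance; the metric is reported as undefined
(NaN) rather than forced to a number, and downstream correlations use
pairwise-complete observations.

## Psychological arm

**Screening.** Candidate photographs are rated for healing quality on a
7-point scale; an image is retained when mean ≥ 5.0 and median ≥ 5.0
(inclusive) and the rater SD is < 1.2 (strict) — the consensus filter
that selected 42 of 150 views in the study design this mirrors. Median of
an even sample is the central-pair midpoint; SD uses n−1.

**Factor analysis.** The 24 bipolar items are correlated over
participant×image rows by default (an `image_mean` mode averages raters
first; the choice is recorded in the run manifest). Extraction is
principal-axis factoring: communalities start at squared multiple
correlations and are iterated on the reduced correlation matrix to 1e-6
(max 100 iterations; non-convergence is flagged, Heywood communalities
are clamped to 1 with a warning). The number of factors follows the
strict Kaiser rule — eigenvalues of the *unreduced* correlation matrix
greater than 1.0 — or a fixed k. Rotation is Kaiser-normalized varimax
using pairwise planar rotations with the closed-form optimal angle; this
is immune to the saddle-point stall of gradient-projection variants on
exactly symmetric loadings, preserves communalities to machine precision,
and matches the statsmodels varimax criterion. Factors are reported with
eigenvalue (sum of squared loadings), contribution rate
(100·eigenvalue/24) and cumulative contribution; printed-table output
uses decimal half-up rounding, the convention under which the published
six-factor solution's rates cumulate to 64.313%. Items with max |loading|
< 0.40 or a top-two gap < 0.20 are screened out of interpretation.
Scores are Thurstone regression scores (Bartlett optional) on
standardized items; image-level scores are rater means, z-scored across
images.

**Clustering.** Ward minimum-variance linkage on the image factor scores
(squared-Euclidean criterion), k = 8 by default to mirror the eight
landscape types of the motivating analysis, or silhouette-selected over
k ∈ 2..10. Per-cluster mean z-scores form the type-profile table. Merge
heights are non-decreasing by the Ward property; silhouette is undefined
(NA) for k = 1 or k = n.

**Correlation.** Each of the 18 metric columns (6 colors × D/H′/C) is
correlated with each factor-score column: Pearson r, two-sided p from the
t distribution with n−2 df, flags * (p < 0.05) and ** (p < 0.01), raw
p-values by default with Benjamini–Hochberg available as an opt-in.
Cells with fewer than 4 complete pairs or a constant column are NA.

## Synthetic data: what it emulates, what it does not

The generators provide every pipeline input with planted ground truth:

- **Masks**: IFS fractals (Sierpinski carpet/triangle, Cantor dust,
  Vicsek) with analytic similarity dimensions, filled/line/checkerboard
  limit cases, and disc clusters for concentration ordering.
- **Landscape images**: regions painted with pixel values
  rejection-sampled to satisfy *exactly one* palette box, so segmentation
  recovers the planted masks exactly under any precedence. Layouts:
  contiguous blocks (exact area fractions), random blobs, or one color as
  a fractal.
- **Healing ratings**: discretized clipped normals, 23 raters per image,
  ~30% of images planted as high-consensus healing views (mean 5.4–6.3,
  SD 0.7) and the rest below threshold (mean 2.5–4.6, SD 1.4) — values
  chosen so the two populations straddle the filter the way a real
  preliminary panel would, with occasional borderline images.
- **SD ratings**: X = FΛᵀ + E per participant×image with image-level
  factor draws, 5-point discretization at equiprobable normal quantiles;
  defaults 58 × 24 × 42 with a 6-factor simple structure at loading 0.7.
- **Joint metric–factor tables**: Gaussian draws from an identity
  covariance plus a planted cross-correlation block (PSD-checked).

All randomness flows through one explicit seeded generator; identical
spec + seed is bit-identical. What passing these tests shows is that the
*estimators* recover known structure at study-scale sample sizes. What it
does not show: real photographs have calibration error, mixed pixels,
and color ranges that overlap ambiguously (the synthetic images avoid
overlap zones by construction), and real raters are not conditionally
independent Gaussians — so field results will be noisier than the
planted-truth recovery rates here.

## Numerical conventions

- Proportions validated to sum to 1 within 1e-9; entropy uses natural
  logs throughout.
- Box-count regression requires ≥ 3 scales after saturation trimming.
- PAF convergence 1e-6; varimax angle tolerance 1e-6; factor-score ridge
  fallback 1e-8 on a singular item correlation matrix.
- Ward ties resolved deterministically by input order (scipy linkage);
  output CSVs use a fixed dialect (UTF-8, comma, '.' decimal, NA) so
  reruns are byte-identical.
- Problem sizes used in the validation suite: 243²–729² masks for
  dimension recovery, n = 500 × 20 seeds for factor recovery, 42 images
  for clustering and small-sample correlation, n = 50 000 for correlation
  consistency, 1000 replicates for the Fisher standard-error check.

## Known limitations

- The per-color H′ is this package's block-entropy convention; other
  definitions (e.g. across-image entropy of that color's proportions)
  would give different absolute values.
- Moran's C depends on lattice resolution and weight scheme; values are
  comparable only within one configuration.
- Box-counting D on ladders not aligned with a fractal's base carries a
  small negative bias at finite resolution (documented above).
- The exclusive precedence order is a modeling choice where palette boxes
  overlap; proportions for heavily overlapping palettes are
  precedence-sensitive.
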