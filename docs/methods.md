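# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `rootangle`: what each stage computes, why the
defaults are what they are, and what the synthetic-data tests do and do
not demonstrate about behaviour on real images.

## Angle measurement

**Inputs.** Per image, two same-size binary masks: roots and seed
regions. A pixel is foreground iff its first-channel value is nonzero,
which accepts both 0/255 and 0/1 mask exports. All coordinates are in
pixels, origin top-left, y downward; no mm calibration is attempted.

**Seed points.** Connected components (8-connectivity, so
diagonally-touching pixels remain one object) of the seed mask are
filtered at `min_seed_area` = 100 px — components below this are
segmentation noise, not seeds. The threshold is read strictly: a 100-px
component survives. The seed point is the component's top-centre: x is
the (sub-pixel) mean of member x coordinates, y the minimum member y.
Top-centre rather than the blob centroid matters because the seed blob
extends downward over the root junction; the topmost row is the stable
anatomical anchor. A centroid variant is available behind
`RunConfig.seed_vertex` for comparison. If more than
`max_seeds_per_image` components survive (rhizoboxes hold a known plant
count), the largest by area are kept, ties broken toward the left.

**Angle.** Around each seed point a square window of half-width
`outer_radius` is cropped and the root mask within it is thinned to a
1-px skeleton. Skeletonization uses Lee's thinning scheme: it preserves
the 8-connectivity of each component, keeps isolated pixels, and — the
reason it was chosen over the classic two-subiteration raster scheme —
its deletion rule commutes with horizontal reflection, so mirrored
scenes give exactly mirrored skeletons and the measured angle is exactly
mirror-invariant rather than approximately so. Skeleton pixels at
distance d from the seed with `inner_radius` ≤ d ≤ `outer_radius`
(closed on both ends; the strictness is a free choice at raster
resolution) are kept. The surviving skeleton is decomposed into
8-connected segments; the leftmost and rightmost segments *by centroid
x* are selected (centroids are robust to single-pixel spurs, unlike
extreme pixels; ties break toward smaller centroid y). The reported
angle is the unsigned angle at the seed vertex between the rays to the
two centroids, computed as atan2(|u×v|, u·v) — numerically safe near 0°
and 180°. Zero segments, one segment, or a centroid coinciding with the
vertex yield per-seed error codes (`no_root_segments`,
`one_root_segment`) in the output CSV; a seedless image yields one
`no_seed` row. Failures never abort a batch.

**Radii defaults.** `inner_radius` = 50 px, `outer_radius` = 300 px.
The inner radius must exceed the region where the two seminal roots are
still merged (seed blob half-width ~15 px plus root width); the outer
radius must stay short of where lateral roots dominate. Both are
mandatory tuning parameters on real data (they depend on image
resolution); the defaults are sized for portrait rhizobox crops a few
hundred pixels wide per plant. Deleting or occluding root pixels
strictly inside the inner radius provably cannot change the measurement.

**Total root length.** The full root mask is skeletonized and length is
the sum over adjacent skeleton-pixel pairs: 1 per 4-neighbour adjacency,
√2 per diagonal, each pair counted once. On exact 1-px polylines whose
corners turn by ≥135° this equals the chain's ideal path length exactly;
a 5-px-thick bar measures within ~2% of its axis length (thinning eats
about half the width at each end). Root-mask components smaller than
`min_root_area` (default 100 px) are removed before the per-image length
is computed — the same noise rationale as the seed filter, and the
reason sub-threshold specks anywhere in either mask leave the output CSV
byte-identical. The bare `total_root_length()` function defaults to no
filtering so that its value on hand-built fixtures is the pure geometric
length. The √2 diagonal weight is a choice; an unweighted pixel count
would bias lengths of oblique roots downward by up to 29%.

**Brightness correction.** A visualization aid for photographs only
(masks are never altered): Yen's maximum-correlation threshold t is
computed from the intensity histogram and the image is piecewise-linearly
rescaled so [min, t] fills [0, 127] and (t, max] fills (128, 255].
Constant images are returned unchanged with a warning.

## Synthetic scenes

The generator emulates the mask pairs the pipeline consumes, not the
photographs: an elliptical seed blob (default 30×20 px, area ≈ 470)
whose top-centre is the ground-truth seed location; two straight
5-px-wide roots of length 380 px from the seed point, symmetric about
vertical at the requested spread (or explicit per-side half-angles, used
to rotate the root system rigidly); optional lateral branches, occlusion
gaps at given arc intervals, and sub-100-px noise specks placed clear of
real foreground. Default canvas 800×1200 (portrait, like a rhizobox
crop). Scene generation is a pure function of (truth, image size); the
only randomness (speck placement) is seeded. The manifest's true angle
is computed analytically from the two ray directions.

Straight rays suffice because the algorithm only ever sees the annulus
near the seed; curvature, root thickness variation, soil texture and
segmentation-model errors are *not* emulated. Passing the synthetic
acceptance tests therefore demonstrates the geometry and bookkeeping of
the pipeline, not robustness to poor segmentations — on real data,
accuracy is bounded by root visibility and segmentation quality.

The paired-measurement simulator draws true angles uniform on
[40°, 150°] (the span of angles seen in barley seedlings), gives the
"manual" reading additive N(0, sd²) noise and the "automated" one a
fixed bias, a proportional bias and its own noise; defaults n = 132
pairs, sd = 5°, matching a two-plants-per-box validation set of 66
images.

## Agreement statistics

Orientation is fixed throughout: manual is the response, automated the
predictor, and Bland–Altman differences are manual − automated (so
automated overestimation appears as negative bias). Ordinary Least
Products is implemented as the geometric-mean / standardized-major-axis
estimator — slope = sign(r)·s_m/s_a, the conventional reading of "least
products" — with the standard SMA closed-form confidence interval:
slope ∈ slope·(√(B+1) ± √B), B = (1−r²)·F₀.₉₅(1, n−2)/(n−2), and the
intercept interval propagated through the slope interval at the sample
means. A fixed bias is flagged when the intercept CI excludes 0, a
proportional bias when the slope CI excludes 1 — note these flags follow
the CI rule even in degenerate perfect-fit cases (data lying exactly on
m = 2a has a zero-width slope CI at 2 and is flagged as proportional
bias, which is the correct reading: the bias is real and certain).
Bias correction maps automated values through the fitted line
(corrected = intercept + slope·a, projecting onto the manual scale);
it is refused when the slope CI contains zero. The correction can
worsen MAE under heteroscedastic noise — the package exposes before/after
MAE rather than asserting the correction helps.

The stability analysis computes running Pearson r over growing prefixes
(3..n) of randomly permuted pair orderings, via cumulative sums, and
aggregates mean and sd per count across permutations.

## BVS QTL model and sampler

The mixed model and mixture prior are described in the README. Sampler
details and the reasoning behind them:

- **β blocks.** Markers are processed in genome order (chromosome,
  position, id — sorted internally, results mapped back to input order,
  which makes every posterior summary exactly invariant to the column
  order of the input file). Consecutive blocks of 10 are drawn jointly
  from the conditional multivariate normal via Cholesky factorization of
  the 10×10 posterior precision (block Gram matrices are precomputed).
- **ζ pairs.** Each sweep draws a fresh random pairing of markers.
  For a pair, both marker effects are integrated out analytically
  (2×2 Woodbury/determinant-lemma identities) and the four (ζᵢ, ζⱼ)
  configurations are scored by marginal likelihood times the current
  π₀ prior mass; after the configuration is sampled the pair's effects
  are redrawn from their joint conditional so the chain state stays
  coherent. Integration uses current-state variance draws.
- **τ₁² update.** Gaussian random walk on log τ₁² with the Jacobian
  correction and a flat prior, spike locked at τ₀² = 0.01·τ₁². The step
  size adapts toward ~40% acceptance during burn-in only (diminishing
  adaptation is unnecessary since the step is frozen afterwards); a
  final acceptance rate outside [0.1, 0.7] produces a warning.
- **π₀** is conjugate: Beta(100 + #{ζ=0}, 1 + #{ζ=1}).
- **Random effects and variances.** Each factor's levels are drawn
  jointly (they are conditionally independent given the residual), and
  each variance from its scaled-inverse-χ² conditional under the
  improper uniform prior, df = levels − 2 (floored at 1 for tiny
  factors), with a 1e-12 floor on all variances to avoid absorbing
  states. The residual variance uses df = n − 2. The intercept has a
  flat prior.
- **Bayes factors.** Prior inclusion odds are evaluated at the prior
  mean of π₀ (100/101), giving prior odds 1/100, so BF =
  100·PIP/(1−PIP). A PIP of exactly 1 reports +inf (and classifies as
  strong). Classification: BF > 5 strong, 3.2 ≤ BF ≤ 5 putative
  (both boundaries putative).
- **Cohen's d** compares minor-allele carriers against major-allele
  homozygotes (carriers = at least one minor-allele copy), pooled-sd
  denominator with n−1 variances.

**Chain lengths.** The production default is one long chain of 250 000
sweeps with 20 000 burn-in. The package's own calibration runs are
scaled down: null calibration uses 10 000 sweeps (n=200, p=300), power
checks 4 000 sweeps (n=300, p=500) — sizes at which the planted-QTL
posterior has long since stabilized, as the recovery results show, while
keeping a full test cycle interactive.

**Simulator.** Genotypes are binomial(2, f) − 1 per marker with minor
allele frequency uniform on [0.1, 0.5] (resampled if monomorphic); QTL
effects are standard normal draws pushed away from zero by 0.3 sd (so
"largest planted effect" is well defined in power studies) and scaled so
the marker term explains the requested fraction of unit phenotypic
variance. The glasshouse design is emulated with 15 blocks, 4 positions
per block (nested), and 10 growth-degree-day levels, 5% variance each by
default; growth degree days are modelled as a generic nested random
factor — a per-individual GDD level would be unidentifiable against the
residual. The residual absorbs the remaining variance; a budget over
100% is an error.

**Validation against closed forms.** With ζ pinned to all-ones, no
random effects and fixed variances, the marker tier collapses to
Bayesian ridge regression; the posterior mean from the blocked sampler
matches the closed-form ridge solution with penalty σε²/τ₁² to within
5% on a 50×20 instance. Under a null simulation the posterior spike
weight stays above 0.9 and under 1% of markers exceed BF 5.

## Numerical and degenerate-input conventions

- Pearson correlation and the OLP fit refuse constant vectors; the OLP
  fit refuses r = 0 exactly (slope sign undefined).
- Angle records enforce their own consistency (angle present ⇔ no error
  ⇔ both centroids present) at construction.
- Annulus bounds are closed; component order is deterministic (bbox
  lexicographic) so all outputs are reproducible bit-for-bit.
- CSV floats are written with fixed 6-decimal formatting so equal seeds
  give byte-identical files.
- All stochastic stages take a single integer seed; nothing reads global
  RNG state.

## Known limitations

- Lateral roots inside the annulus are measured like seminal roots; the
  package does not attempt lateral exclusion (adjusting the radii is the
  available mitigation) or ownership assignment of roots from a
  neighbouring plant that cross into a seed's annulus.
- All outputs are in pixels; physical calibration is out of scope.
- The mirror-invariance guarantee is a property of Lee thinning on the
  scenes tested; rotation invariance is only approximate (≤ 2° for
  rigid rotations up to 10°) because the raster grid is not isotropic.
- The BVS sampler assumes complete genotypes (no imputation) and drops
  monomorphic markers; Bayes factors inherit Monte-Carlo error from the
  PIP estimate, so markers with PIP near 1 have unstable (capped) BFs.
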