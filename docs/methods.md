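# Methods

This note documents the models, numerical choices and limitations behind
`irismoments`, in the order the pipeline runs.

## Segmentation

The eye is modelled as three nested intensity regions: a near-black pupil
disk, a textured iris annulus, and a near-white sclera.  Segmentation
estimates the two boundary circles.

**Denoising.**  Three passes of a 3×3 median filter (both configurable).
Iterated small-window medians suppress impulse noise while preserving the
step edges the detector needs.

**Luminosity normalization.**  The 99th-percentile intensity is taken as
the sclera level and the frame is rescaled so that it sits at 230.  All
edge thresholds are expressed in this normalized scale, which makes them
stable under global illumination gain.

**Edge detection.**  Canny (default) with σ = 2 and hysteresis thresholds
50/80 in raw-Sobel units, or a plain Sobel magnitude threshold
(default 150).  The thresholds sit between the weakest boundary step the
synthetic model can produce (≈ 50 intensity levels, giving a smoothed
Sobel response of ≈ 85) and the strongest band-limited texture gradients
inside the iris (≈ 30).  The Sobel path uses the raw ±1/±2 kernels so its
response to an ideal 0→v step is exactly 4v in the two adjacent columns,
which keeps unit tests hand-checkable.

**Pupil hint and point collection.**  The pupil is the largest connected
component darker than 26% of the sclera level; its centroid and
equivalent-area radius r̂ seed two radial bands, (0.5 r̂, 1.6 r̂) for the
inner edge and ±25% around the median radius of the remaining edge
pixels for the outer edge.  Edge pixels are raster-scanned and assigned
to the inner or outer point array by distance from the hint centre;
pixels in neither band are discarded.  Fewer than three points in either
band is a hard segmentation failure.

**Three-point circle solution.**  A triplet of non-collinear points
determines x² + y² + 2gx + 2fy + c = 0 exactly; the implementation solves
the printed closed form for g, f, c (permuting the triplet when the
pair used in the f-denominator shares a y value) and rejects triplets
whose signed-area denominator vanishes.  The centre is (−g, −f) and
r = √(g² + f² − c).

**Robust aggregation.**  50 seeded triplets per circle are solved
exactly; the 20% of centre estimates farthest from the coordinate-wise
median are discarded, and the surviving centres and radii are averaged.
The final annulus pools the inner and outer centre estimates into one
shared centre (their mean).  Trim fraction, triplet count and seed are
configurable; the estimator tolerates ~10% gross outlier points at trim
0.3.

## Unwrapping

The annulus is mapped to a rectangular canvas with rows indexed by
radius (row 0 ↔ r_m) and columns by angle (column j ↔ θ = j·2π/n_θ,
measured from the +x axis in image coordinates, y downward).  Each
radial segment is rasterized with the integer midpoint line algorithm —
first-octant decision variable d₀ = 2dy − dx, North-East step when
d > 0 (update 2(dy − dx)), East otherwise (update 2dy), ties to East,
other octants by axis swap and sign reflection — and the pixel run is
resampled to exactly n_r cells by nearest index.  No sub-pixel
interpolation is used anywhere; the transform is integer/nearest
throughout, matching the rasterizer's spirit.  Eight-way circle symmetry
is exposed as `eight_way_reflect` (all seven dihedral partners).

**Canvas shape (n_θ = 96, n_r = 64 by default).**  The obvious choice of
one column per degree (360) is deliberately not the default.  Third-order
canvas moments weight column indices by up to (n_θ/2)³, while the
identity-bearing radial structure lives in the rows; the per-column
half-pixel rasterization noise (from rounding the segment endpoints to
the pixel grid) therefore enters the third-order x-moments amplified by
roughly (n_θ/n_r)³ relative to the radial signal.  At 360×64 this noise
dominates I3/I4 and ruins identification; at 96×64 the axes are balanced
and the features stabilize.  Both dimensions remain configurable.

**Rotation ↔ column shift.**  Rotating the eye by k·(2π/n_θ) shifts the
canvas circularly by k columns — exactly for quarter and half turns
(pixel-grid symmetries) and within nearest-pixel resampling noise
(mean ≈ 3 intensity levels) otherwise.  This is the mechanism by which
the canvas features inherit approximate rotation invariance.

## Moment features

Moment sums use 1-based pixel coordinates (x over columns 1..K, y over
rows 1..L).  Central moments are computed by direct summation about the
intensity centroid and cross-checked in the tests against their
raw-moment expansion identities; first-order central moments are set to
exactly zero (they vanish identically and the assignment removes
accumulated round-off).  Scale normalization uses
η_pq = μ_pq / μ00^((p+q)/2+1) for p+q ≥ 2.  The orientation angle is
½·atan2(2μ′11, μ′20 − μ′02) ∈ (−π/2, π/2]; an isotropic image (both
arguments zero at 1e-9 relative tolerance) has no orientation and this
is reported as missing metadata rather than an error of the feature
extractor.  Eigenvalues are clipped at zero against round-off before the
eccentricity √(1 − λ2/λ1) is formed.

**Matching vector.**  [s(I1), s(I2), s(I3), s(I4), −log₁₀|I5|, s(I6),
eccentricity], with the signed log s(v) = −sign(v)·log₁₀(|v| + ε),
ε = 1e-30 guarding exact zeros from symmetric images.  Rationale:

* The Hu invariants span tens of orders of magnitude; Euclidean distance
  on raw values would be meaningless, hence the log scale.  The sign is
  retained where it is a stable property of the image (I6's sign follows
  the sign of the radial-profile skewness times the canvas anisotropy).
* **I7 and I8 are computed and reported but excluded from matching.**
  On a canvas covering a full angular revolution, x-odd third-order
  moments (η30, η12, η11-coupled products) vanish identically for any
  purely radial structure, and every term of I7 and I8 contains one such
  factor.  Their measured values are therefore resampling noise with
  random sign; in log space they fluctuate by tens of units within a
  class (between/within variance ratio ≈ 0.2–0.4) and, once
  standardized, randomize the Euclidean distances.  Including them cuts
  10-class hold-out accuracy roughly in half.
* I5 has the same sign instability (its one stable term is the fourth
  power of the radial-profile skewness) but a strongly class-dependent
  magnitude, so it enters as a magnitude-only log.
* The orientation angle Θ is rotation-covariant — the one thing the
  feature vector must not depend on — so it is metadata, never matched.
* Eccentricity of the canvas is retained; it is cheap and mildly
  informative (it reflects how the radial profile redistributes mass).

**Known caveat (by design):** none of the moments are invariant to a
global intensity gain.  The method assumes all images come from the same
acquisition setup at the same illumination; the property tests assert
the non-invariance rather than hiding it.  Gain normalization is used
only inside segmentation (for thresholds), not for features.

## Matching

Features are standardized per component with training-set mean and
standard deviation (frozen into the model).  k-means uses K = number of
enrolled classes, initialized with one sample per class (the first
enrolled image of each), which fixes the cluster → class map.
Assignment ties break to the lowest cluster index so each vector lands
in exactly one cluster; a cluster emptied mid-run is re-seeded with the
vector farthest from its previous mean; iteration stops at the first
assignment pass with no changes (max 300).  The within-cluster
sum-of-squares objective is recorded after every half-step and is
non-increasing — asserted per iteration in the tests.

**Confidence thresholds.**  Levels 0–4 band the distance to the nearest
centroid against t0 < t1 < t2 < t3.  Defaults: the {50, 75, 90, 99}th
percentiles of training within-cluster distances, with two corrections:

* each training distance is rescaled by n_i/(n_i − 1) — the exact
  leave-one-out identity |x − mean(S∖x)| = |x − mean(S)|·n/(n−1) —
  because with few enrollment images per class every vector visibly
  shrinks its own centroid toward itself;
* each t_j is floored at a fraction (0.15, 0.30, 0.45, 0.60) of the
  median inter-centroid distance, so the accept bands scale with the
  geometry of the enrolled classes rather than with the sampling noise
  of a handful of training distances.  Measured on the synthetic study
  conditions (6 enrollment images per class), the nearest centroid was
  the correct class in 100% of probes while raw percentile thresholds
  rejected up to 15% of them; the floors fix the rejections without
  touching the ranking.

Both corrections are parameters and can be disabled to obtain the plain
percentile rule.  Level 4 (distance > t3, i.e. beyond 60% of the typical
centroid gap) reports no class.

## Synthetic eye model

`synthetic.generate_eye_image` renders sclera 230, pupil 20 and an iris
annulus textured by a deterministic function of the class id evaluated
in normalized polar coordinates (r_norm ∈ [0, 1] across the annulus,
θ − rotation):

* 2–4 active radial "ring" sinusoids, 0.2–2.0 cycles across the annulus,
  amplitudes 6–20 intensity levels;
* 4 angular "furrow" sinusoids with 8–24 cycles per revolution (whole
  cycles, so the texture closes at the θ wrap), amplitudes 0.5–1.5;
* a radial shading ramp of ±(10–50) levels with random sign, emulating
  class-specific limbal darkening;
* the summed texture is clipped to ±55 about the base level 128, keeping
  the iris clear of the pupil and sclera levels so the boundary edges
  stay the strongest gradients in the frame.

The texture basis depends only on the class id — never on the image
seed — so rotation, scale and translation act purely as geometric
transforms of one underlying pattern.  The emphasis on low-frequency
radial structure is deliberate: canvas moments integrate pure-angular
content to zero over a full revolution, so whatever identifies a class
must live in rotation-stable radial structure.  Real iris texture is far
richer (and its identity is carried largely by angular detail that this
feature set cannot see); passing tests on this generator demonstrate
that the pipeline's geometry, invariances and matching logic work as
specified, not that moment features would reach comparable accuracy on
real iris databases.

Datasets draw per-image transforms from configurable ranges (defaults:
translation ±10 px, scale 0.8–1.2, rotation 0–2π, noise σ 0–4,
luminosity pinned at 1 per the equal-illumination assumption) inside
200×200 frames with base radii 24/64.  Randomness is one stream per
dataset, split per image by (seed, class, index) counters, so generation
is reproducible and order-independent.  Images are 8-bit PNG with a CSV
ground-truth sidecar.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale by choice:
100-image segmentation sweeps, 200-image moment-identity sweeps,
exhaustive 21×21 rasterizer enumeration (194 481 endpoint pairs),
exhaustive 10×10-lattice circle-fit enumeration in the tests with a
20 000-triplet seeded sample in the acceptance script, and a 10-class ×
8-image identification experiment split 6 train / 2 test.  Every random
draw flows from an explicit seed; two runs with the same seed are
bit-identical.

## Limitations

* No eyelid/eyelash occlusion, specular highlights, or non-circular
  boundary models — segmentation assumes two clean circles.
* Nearest-pixel unwrapping bounds the achievable feature stability;
  bilinear resampling would reduce within-class jitter but is outside
  the integer/nearest design of the transform.
* Features are not gain-invariant (above) and only approximately
  rotation-invariant through the canvas column-shift mechanism.
* Confidence levels are calibrated from enrollment data only; with very
  few images per class the bands lean on the inter-centroid floor.
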