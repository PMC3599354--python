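# Methods

This note records the modelling choices behind `woundshape`: what is
computed, which parameters matter and why they default to what they do,
what the synthetic data does and does not emulate, and where the design was
genuinely open.

## Data model and normalization

A specimen is a single open triangle mesh: one centrally located lesion on
an otherwise flat patch, evenly gridded (~10 vertices/mm, near-equilateral
triangles). Before anything else the patch is translated so its centroid
sits at the origin and scaled by one uniform factor so that the larger of
the x- and y-extents equals 1. Two points were open here and decided as
follows: the centroid (not the bounding-box center) goes to the origin,
which makes the concentric-sphere descriptors well defined and robust to
asymmetric flat margins; and the single scale factor is applied to all
three axes, because uniform scaling preserves every pairwise-distance ratio
and simply divides all curvatures by the factor, keeping the curvature-band
structure intact. Normalizing a normalized patch is the identity.

Vertex deduplication (1e-9 in raw units) and zero-area-face removal happen
on read and are logged, never silent. Mesh repair, hole filling and
adaptive remeshing are out of scope: the pipeline assumes evenly gridded
input.

## Curvature estimation

Per-face second-fundamental-form (Weingarten) tensors are fit by least
squares to the finite differences of the vertex normals along the three
face edges, then averaged onto vertices in each vertex's own tangent frame.
Averaging weights are the face's mixed-Voronoi area contribution at the
corner (obtuse triangles fall back to the area/2–area/4 split, which keeps
all weights positive); uniform (area/3) weighting is available as a config
switch and agrees with the Voronoi weights to a few percent on smooth
test surfaces. Vertex normals are angle-weighted face-normal averages.
Principal curvatures are the eigenvalues of the averaged 2×2 tensor.

Sign convention: a unit sphere with outward normals has mean curvature +1;
on the generated patches (normals pointing up) bumps are convex/positive
and pits concave/negative. The estimator requires globally consistent face
winding and refuses meshes where two faces traverse a shared edge in the
same direction. Boundary vertices are retained with one-sided
neighborhoods; on real patches the boundary is flat surround, so their
(less accurate) estimates land in the discarded flat band.

Accuracy on analytic surfaces at the mesh resolutions used: sphere within
1.5% of mc = 1, cylinder within 5% of 1/(2r), plane below 1e-6, saddle
100% hyperbolic on interior vertices.

Curvature is computed **after** unit-square normalization. The fixed band
thresholds below are dimensionless and only comparable across specimens in
that frame; this is the one choice that makes a fixed flat threshold
meaningful for patches of different physical sizes.

## Curvature bands

Vertices are partitioned into 13 bands of mean curvature: the flat band
|mc| ≤ 0.17 and six convex / six concave bands with edges at
0.17, 0.25, 0.4, 0.5, 0.6, 0.8 (convex bands take the upper edge, concave
bands the lower edge; the flat band wins at ±0.17). The flat threshold
0.17 is the published operating value of the visual-tuning range [0, 0.3]:
lower values push surround noise into the outermost non-flat bands, higher
values start to swallow genuinely lesion-specific low-curvature surface.
The flat band is discarded; the other 12 feed the descriptors.

## Descriptors (107 per band, 1284 per mesh)

Within each band's vertex set: a 40-bin histogram of all pairwise
Euclidean distances (d0–d39); max/mean and max/median distance ratios
(d40, d41); convex-hull volume and surface (d42, d43); max/mean histogram
frequency (d44); the vertex count (d45); cumulative counts inside 10
concentric spheres around the origin with radii j·R/10, R being the
largest vertex norm of the whole mesh (d46–d55); DFT magnitude spectra of
the histogram and of the sphere series (d56–d95, d96–d105); and the count
of hyperbolic points, K < 0 (d106).

Numerical conventions, all of which were open:

* Histogram bins are fixed to [0, 2] in normalized units for every band
  and specimen (a per-mesh range would destroy cross-specimen
  comparability); bins are half-open with the last bin closed, and the
  rare distances beyond 2 are clipped into the last bin.
* The spectra are magnitude spectra, DC term first, same length as the
  input; the DC terms therefore equal the histogram mass and the sphere-
  series sum, which the tests use as invariants.
* "Histogram" for the first spectrum means the 40-bin distance histogram
  of the band — the only 40-length series defined per band. (Reading it
  as a histogram of mc values instead was considered and rejected: that
  histogram does not exist anywhere else in the pipeline.)
* All-pairs distances are O(n²); bands larger than 2000 vertices are
  subsampled with a seeded uniform draw (d45 always reports the true band
  size). Shape vectors are bit-reproducible for a fixed seed.
* Empty bands contribute zero blocks, keeping the feature matrix
  rectangular; degenerate hulls (< 4 points, coplanar, collinear) are
  defined as volume 0 / surface 0 rather than errors.

## Descriptor reduction

Three filters run in order, on training rows only, re-run inside every
cross-validation fold:

1. **SNR ≥ 3.00.** For each descriptor and each of the 15 class pairs,
   SNR = |μ₁ − μ₂| / max(σ₁, σ₂) (sample sd); the descriptor's score is
   the maximum over pairs. Max- rather than min-over-pairs was chosen
   because requiring every pair to separate would eliminate pair-specific
   discriminators, which are exactly the descriptors a multiclass
   classifier needs. If both sds vanish the pair contributes 0 (equal
   means) or +inf (different means).
2. **Moments.** A descriptor is dropped if its worst per-class
   bias-corrected excess kurtosis exceeds 16.0 or worst |skewness|
   exceeds 13.4. Bias-corrected moments are what mainstream statistics
   packages report and are consistent with the reference behaviour that a
   single extreme outlier among 18 samples (kurtosis 18.0) trips the
   filter. Zero-variance groups contribute moments of 0.
3. **Kendall |τ_b| ≤ 0.95.** Greedy pass in decreasing-SNR order (ties
   broken toward the lower index): a candidate is dropped on its first
   kept partner with |τ_b| > 0.95, so the higher-SNR member of each
   correlated pair survives and the pass is deterministic. τ_b is
   evaluated via precomputed pairwise sign vectors, which is
   algebraically identical to the textbook definition and keeps the
   filter O(survivors² · pairs) in fast vectorized arithmetic.

Every input descriptor ends up either kept or attributed to exactly one
filter (audited in the `SelectionReport`). An empty result raises by
default; the noise experiment (below) instead falls back to keeping the
ten best-SNR descriptors so that heavily degraded regimes still produce
predictions rather than aborting.

## Discriminant analysis

Columns are standardized to mean 0 / sd 1 with training statistics; test
rows are always transformed with the training statistics. Class
covariances are shrunk twice: λ toward the pooled covariance, then γ
toward the scaled identity (trace/p)·I — Friedman's regularization path,
with the literal-diagonal target available as a config option. The
operating point λ = 0.99, γ = 0.001 is an almost-linear model with a
whisper of ridge: with ~15 training samples per class and dozens of
descriptors the per-class covariances are singular, pure QDA is
infeasible, and the tiny γ floor guarantees positive definiteness (checked
by Cholesky; failure raises with the advice to increase γ). A crude grid
search utility over {0, 0.25, 0.5, 0.75, 0.9, 0.99, 1} × {0, 0.001, 0.01,
0.1, 1} scored by training CRR reproduces how the operating point is
found. Priors are uniform (the classes are balanced by design).

Classification minimizes the quadratic score
(x−μ_k)ᵀΣ_k⁻¹(x−μ_k) + ln det Σ_k − 2 ln π_k; ties break to the lowest
class index (logged implicitly by argmin). At λ=1, γ=0 the predictions
coincide with an independently implemented LDA, which the tests verify
against scikit-learn. Diagnostics: per-class Mahalanobis distances and
one-vs-rest ROC/AUC from the negated scores via the Mann-Whitney rank
formula with midranks.

## Cross-validation and noise

Stratified 6-fold plan: seeded within-class shuffle, round-robin
assignment, so each test fold holds exactly 3 of the 18 instances of every
class (90 train / 18 test). Descriptor selection and standardization are
functions of the training rows only — re-selected inside every fold — and
a structural test asserts that perturbing test rows changes neither. The
mean CRR is the unweighted mean of per-fold CRRs (identical to the pooled
rate here because folds are equal-sized).

The robustness experiment adds uniform noise on [−aσ_j, aσ_j] per
descriptor j, with σ_j the sd of the full clean matrix, to training and
test rows alike, before the identical protocol is re-run. The σ referent
and its timing were open; per-descriptor σ applied pre-standardization was
chosen as the reading under which "one standard deviation of noise" means
the same thing for every descriptor regardless of scale. At amplitude 1
recognition degrades but stays far above chance; at amplitude 10 the SNR
filter finds nothing (the noise sd is ~5.8× every column sd) and the
keep-top fallback yields near-chance recognition. Full convergence to
exactly 1/6 is not reached at amplitude 10 because uniform noise of that
size still leaves a residual per-descriptor effect size of ~0.5 on the
strongest bimodal descriptors.

## Synthetic lesion generator

The generator stamps class-characteristic height-field deformations into a
flat n×n grid patch (default 80×80 vertices over ~8 mm, i.e. ~10
vertices/mm): an irregular rough blob (abrasion), a narrow straight
V-groove (incised), a deep Gaussian pit with raised rim (gunshot entry), a
flat-bottomed steep-walled transverse furrow (smooth strangulation), the
same furrow with periodic stria on its floor (textured strangulation), and
an L-shaped sharp-walled imprint (patterned). Depth/width/position/
rotation jitter, a gentle random base undulation (0.12 mm sd, 2 mm
correlation — a hand-flattened block is never perfectly plane) and a
per-instance patch extent (±17% around 8 mm — the analogue of clipping a
variable amount of flat surround before the unit-square resize, which
shifts every normalized quantity of an instance coherently) provide
within-class variability. Defaults are chosen so that training sets are
descriptively perfectly separable (one-vs-rest AUC 1.0) while held-out
instances retain a small error probability, and so that the
SNR/moment/correlation filters retain on the order of 150 of the 1284
descriptors — the regime in which an almost-linear RDA is the right
model. The strangulation profile is deliberately flat-bottomed: a smooth
Gaussian valley's curvature sits near the strong-concave band edge and
jitters across it, which makes its band signature collide with the
V-groove's; the steep-walled furrow instead contributes two full-width
wall lines that no other class produces.

What the generator does **not** emulate: scanner artifacts beyond optional
i.i.d. vertex noise, overhangs or undercuts (height fields cannot fold),
skin texture and color, lesion classes with overlapping morphology, and
the decaying, healing, in-between injuries of real forensic material.
Passing the surrogate experiment therefore demonstrates that the pipeline
recovers well-separated morphological classes from mesh geometry under
realistic within-class variation — not that real skin injuries of
ambiguous cause would be classified at the same rate.

## Problem sizes

The shipped experiments use the full study geometry (108 meshes of 6400
vertices; 6-fold cross-validation with per-fold selection) and finish in
well under a minute per run; the acceptance script repeats the experiment
for three master seeds and reports the worst case. Analytic curvature
oracles run on an icosphere (642 vertices), a 30×30 plane, a 41×41 saddle
and 64×24 cylinder tubes.

## Known limitations

* Curvature estimates at boundary vertices are one-sided and biased; the
  pipeline relies on the flat band absorbing them.
* The fixed histogram range [0, 2] allocates few informative bins to very
  compact bands; the spectra partially compensate.
* The SNR filter is univariate: descriptor sets that separate classes only
  jointly are invisible to it.
* With more than ~84 surviving descriptors the pooled covariance itself is
  singular and classification rests entirely on the small γ ridge; the
  generator defaults deliberately avoid that regime, but real data with
  many stable descriptors would warrant a larger γ.
* VRML 2.0 input is not parsed; OBJ/PLY cover the same geometry content.
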