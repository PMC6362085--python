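# Methods

## The pipeline and its assumptions

The package orders grayscale anterior-chamber OCT B-scans by computing a
pairwise distance matrix over pose-normalized images and embedding it in
two dimensions. The core modeling assumptions are:

* **Tissue dominates the image mass.** Centering and alignment use the
  intensity-weighted centroid and covariance of the whole image, so the
  principal axis tracks the anatomy only if background contributes little
  to `S = Σ M(i,j)`. See *Limitations* for the quantitative failure mode.
* **Pose is nuisance, shape is signal.** In-plane rotation and translation
  of the eye within the frame are removed by moment alignment; everything
  left (angle configuration, chamber depth, overall anatomy) is what the
  distances then measure.
* **The image, normalized by its mass, behaves like a probability
  density.** The Hellinger distance compares the square roots of
  `M/S`, making the comparison invariant to acquisition gain; the
  Euclidean distance keeps absolute intensity differences.

## Pre-processing

Order is fixed: normalize → homogenize → median filter → anisotropic
diffusion → align.

* **Normalization**: affine rescale to `[0, 1]`; a constant image is an
  error (zero dynamic range).
* **Homogenization**: the instrument samples anisotropically (default
  frame 256 × 1024 px for 8 mm × 16 mm, i.e. 31.25 µm vertical ×
  15.625 µm horizontal). The coarser axis is *up*sampled by bilinear
  interpolation to the finer spacing, preserving detail; physical extent
  is preserved to within one pixel.
* **Median filter**: rectangular window specified in physical units,
  default 0.055 mm × 0.117 mm, converted to the nearest odd pixel count
  per axis (3 × 7 px at the default isotropic 15.625 µm); edge-replicated
  borders. A window below one pixel degrades to the identity with a
  warning.
* **Anisotropic diffusion** (Perona–Malik, explicit scheme, 4-neighbor
  gradients): conduction `g(∇) = exp(−(∇/κ)²)`, update
  `u += λ Σ g(∇_d)·∇_d`, zero-flux boundaries. Defaults `n_iter = 15`,
  `κ = 0.1` (on [0, 1] intensities), `λ = 0.25`. `λ ≤ 0.25` is required:
  the update is then a convex combination of a pixel and its neighbors,
  so the output range can never exceed the input range. `κ = 0.1` keeps
  tissue-to-background edges (contrast ≥ 0.5) essentially intact while
  flattening speckle-scale fluctuations.
* **Moments and alignment**: pixel indices are 0-based (the centroid and
  covariance are translation-covariant, so the base only shifts the
  centroid consistently). The principal eigenvector `v1` of the 2 × 2
  covariance is sign-ambiguous; the convention is a nonnegative
  horizontal component (never mirroring the image), falling back to a
  nonnegative vertical component for a purely vertical axis. The source
  is resampled once, under the single affine map composing the rotation
  (about the source centroid, taking `v1` to horizontal) with the
  translation of the centroid to the center of a canvas twice the source
  size — one bilinear interpolation, zero fill outside the source. Equal
  covariance eigenvalues (within a relative tolerance of 1e-9) leave the
  rotation undefined; the identity rotation is applied with a warning.

## Distances

`d_H(l, m) = sqrt(2 Σ_{i,j} (sqrt(M_l/S_l) − sqrt(M_m/S_m))²)` with each
`S` the total mass of the *aligned canvas* (the source mass minus
resampling loss), recomputed on the canvas so normalization and compared
pixels are self-consistent. With this convention `Σ M/S = 1`, hence
`d_H ≤ 2` with equality exactly for disjoint supports. (Note the factor:
the common Hellinger convention divides by √2; this package keeps the
factor-2 form deliberately, and all bounds/tests use it.)
`d_E` is the unnormalized L2 distance. The matrix is built from the
n(n−1)/2 unordered pairs, each evaluated once and mirrored, so results
are independent of evaluation order; per-image square-root normalizations
are precomputed (identical floating-point sequence to the single-pair
function).

## Embedding

Both methods consume the distance matrix directly; images are never
re-featurized.

* **IsoMap**: k-nearest-neighbor graph on D (default `k = 12`), graph
  shortest-path geodesics, classical MDS (via scikit-learn's
  precomputed-metric Isomap). A disconnected graph is an error that
  reports the component sizes, so the caller can raise `k` deliberately
  rather than silently bridging components.
* **t-SNE**: scikit-learn in precomputed-distance mode with random
  initialization and a mandatory seed (default perplexity 30, seed 0);
  identical inputs and seed reproduce coordinates bit-exactly.
  Coordinates are centered at the origin. Perplexity must satisfy
  `1 < perplexity < (n−1)/3`.
* **Residual variance**: `1 − r²` between the upper-triangle reference
  distances and the embedded Euclidean distances, where the reference is
  the graph geodesic matrix for IsoMap and D itself for t-SNE. Constant
  distance vectors make the correlation undefined; NaN is returned rather
  than an arbitrary value.

`k = 12` and perplexity 30 are package defaults chosen as common practice
for cohorts of a few hundred points; both are exposed in the config and
CLI.

## Landmark features

Per side, the scleral spur plus an auxiliary point define the cornea
line; two iris-top points define the iris line. Derived features:

* `L` (mm): Euclidean distance from the central inner cornea to the lens
  apex.
* `α`, `β` (degrees): the acute angle between the two lines
  (`arccos |u_c · u_i|`), per side. Parallel lines give 0°.
* `ARA_500` (mm²): with both edges approximated as lines, the triangle
  (A, P, Q) where A is the line intersection (recess apex), P lies on the
  cornea line 0.5 mm from the scleral spur on the side away from A (for
  a spur coincident with A: toward the iris points), and Q is the foot of
  the perpendicular from P onto the iris line. This is a deliberate
  line-based approximation of the conventional angle-recess area, which
  integrates between the actual curved edges; the 0.5 mm offset is
  anchored at the scleral spur, the conventional anchor. Areas from the
  two constructions agree in the small-recess limit where both edges are
  locally straight.

Angles and `L` are exactly invariant under rigid motions of the landmark
set; `ARA_500` to numerical precision (≤ 1e-9 mm² in tests); under
uniform scaling `L` scales linearly, angles are invariant, and `ARA_500`
quadratically *when the 0.5 mm offset is scaled with the geometry*
(the offset is an absolute clinical length, so plain coordinate scaling
does not scale the area exactly quadratically — the test scales the
offset accordingly).

## Evaluation

* **Best-correlating direction**: among unit directions `u(θ)` in the
  `(w, v)` plane, the one maximizing |Pearson r| between `coords · u` and
  a per-image feature. Closed form: the least-squares coefficients of the
  centered feature on the centered coordinates point along the optimum,
  and |r| there equals the multiple correlation √R². θ is reported in
  [0, π) with the signed r at that angle (the sign is arbitrary under an
  axis flip). Missing feature values are dropped pairwise.
* **Image Map**: a regular grid over the bounding box of the coordinates;
  all (cell, image) pairs are ranked by distance and assigned greedily
  (ties by id order) so each cell shows at most one image and each image
  appears at most once; cells with no image within half a grid spacing
  (half the larger of the two grid steps) stay empty. A zero-span
  bounding-box axis is padded to unit span so a degenerate cluster still
  renders into a single cell. The montage's top row corresponds to the
  largest `v`, like a scatter plot.
* **Label overlay**: scatter data colored by class; unlabeled points
  gray. Ordinal class labels (wide-open = 0 … closed = 3) can be
  correlated as a numeric feature.

## The phantom generator

The generator renders the structures a grader actually uses: a bright
corneal band (two concentric circular arcs, inner radius 7 mm, thickness
0.6 mm, apex 2.2 mm below the top edge), left and right iris bands
(0.35 mm thick) whose top edges meet the inner corneal arc at apex points
±5.5 mm off-center at a controllable apex angle, a pupil gap of ±1.5 mm,
and a lens arc (radius 9 mm, 0.3 mm thick) whose apex sits at the
controllable chamber depth below the central inner cornea. Band
intensities 0.9 / 0.7 / 0.5 (cornea / iris / lens) give distinct but
overlapping intensity distributions. Default frame: the instrument's
256 × 1024 px for 8 mm × 16 mm.

All geometry is analytic in physical coordinates, and the whole-eye pose
(rotation about the image center plus an integer pixel shift) is applied
to the geometry itself before rasterization rather than by resampling the
rendered image: on an anisotropic pixel grid an image-space rotation is
not a physical rigid rotation, and the analytic route keeps the stored
edge-line parameters exact ground truth at any pose. Rasterization is a
hard indicator per band (pixel-center test), so the noiseless phantom is
exactly zero outside the anatomical mask.

Noise: each signal pixel is multiplied by `exp(σ·Z)`, `Z ~ N(0, 1)`
(default σ = 0.2), a simple lognormal stand-in for coherent speckle, plus
an optional per-pixel additive background uniform in
`[0, background_level)`, then clipping to [0, 1]. The default background
is 0: exported AS-OCT B-scans have an essentially black background, and
the moment alignment assumes exactly that (see *Limitations*). Cohorts
sample angle and depth uniformly in configurable ranges (defaults
10–70° and 2–4 mm, spanning wide-open through closed-angle morphology)
with pose jitter (default ±5°, ±10 px); child seeds derive from one
`SeedSequence`, so cohorts are bit-reproducible.

What the phantom does **not** emulate: A-scan physics, refraction at the
corneal surface, intraocular-lens artifacts, scleral/limbal texture,
vignetting, or correlated speckle. Passing tests therefore demonstrate
the pipeline's geometric and statistical behavior — pose removal, metric
properties, ordering by angle/depth — not robustness to every clinical
artifact.

## Problem sizes and runtime choices

Unit tests run on a 16× coarser phantom raster (64 × 256 px, identical mm
geometry); the acceptance-style checks use the full 256 × 1024 frame with
100-phantom cohorts, the size at which the whole suite and the
reproduction script each complete in a few minutes on one CPU. The
pairwise stage is O(n²) in time and O(n) in canvas-sized memory
(square-root canvases are precomputed once per image).

## Limitations

* **Background mass biases the alignment.** An additive background spread
  over the frame contributes frame-aligned covariance. With the signal's
  covariance anisotropy `Δ_s` and the background's `Δ_b` (for a 16 × 8 mm
  frame, `Δ_b ≈ 8 mm²`), the recovered rotation is shrunk roughly by
  `w_s Δ_s / (w_s Δ_s + w_b Δ_b)` for mass fractions `w`. Measured on
  phantoms: with background mean at 2.5% of full scale (~26% of total
  mass) a 12° pose rotation is corrected to only 7.7°. The method is
  therefore reliable only when tissue dominates the mass — true for
  near-black exported B-scans, not for raw linear-scale data with a high
  noise floor. `background_level` exists precisely to probe this.
* **Moment alignment cannot correct left-right flips or vertical
  mirroring** (by design: the eigenvector sign convention never mirrors);
  anatomically mirrored scans would remain distinct.
* **t-SNE coordinates are seed-dependent** up to global rearrangement;
  only seeded runs are reproducible, and direction-based statistics (not
  raw coordinates) should be compared across runs.
* **ARA_500 uses straight-line edges**, an approximation that
  overestimates the recess area when the iris is strongly bowed.
* The degenerate-covariance fallback (identity rotation) makes alignment
  a no-op for radially symmetric images, which cannot occur for
  anatomically plausible scans but can for synthetic edge cases.
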