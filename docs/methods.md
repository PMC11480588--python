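# Methods

## Problem and pipeline

`stemleaf` segments individual plant point clouds into stem and leaf points,
splits the leaf points into per-leaf instances, and measures four phenotype
parameters: plant height, leaf length, leaf width, and leaf area. The
pipeline is

1. **Preprocessing** — radius outlier removal, seeded uniform downsampling to
   a fixed point count, and normalization of the coordinates into
   [-1, 1]^3 with the transform (centroid, max-radius scale) recorded so
   phenotyping runs on restored metric coordinates.
2. **Semantic segmentation** — a graph-encoder network over both Euclidean
   and hyperbolic feature spaces (below).
3. **Instance segmentation** — K-means (k-means++ initialization) on the
   leaf-labeled points, with the cluster count chosen by a geometric elbow
   criterion.
4. **Phenotyping** — z-extent for height; PCA-extremal chord distances for
   leaf length/width; summed Heron triangle areas of a pivot-ball surface
   triangulation for leaf area.

## Segmentation network

The network stacks two geometric graph encoder (GGE) blocks at full
resolution and three GGE-P blocks (GGE followed by farthest-point-sampling
pooling at rate 4 with neighborhood max pooling), producing the resolution
cascade N → N/4 → N/16 → N/64. Every stage output is interpolated back to N
rows by inverse-distance-weighted 3-nearest-neighbor interpolation,
concatenated, and scored per point by a shared MLP with widths (512, 256, p).

Each GGE block fuses two channels computed on the same k-d-tree KNN graph
(K = 20 by default, built in coordinate space once per stage):

- **Euclidean channel (adaptive kernel convolution).** For each edge (i, j),
  a shared two-layer perceptron maps the feature encoding
  Δf_ij = [f_i; f_j − f_i] to M six-dimensional kernels; the kernel response
  is h_ij[m] = LeakyReLU(⟨Δx_ij, g_m(Δf_ij)⟩) with the spatial encoding
  Δx_ij = [x_i; x_j − x_i]. Responses are pooled over the K neighbors by a
  channel-wise softmax attention (weights softmax(h_i1 … h_iK) per channel)
  and passed through a linear layer + LeakyReLU. The softmax axis is over
  neighbors: pooling must be permutation-invariant in the neighbor order,
  and this reading keeps it so.
- **Hyperbolic channel (star-transformer encoder).** Per-stage features are
  lifted by a linear map to the channel width and projected onto the
  Poincaré ball of curvature −c via the exponential map at the origin,
  exp_0^c(f) = tanh(√c‖f‖) f/(√c‖f‖). Each point's K neighbors form a
  cyclic ring around the center ("planet"). L stacked layers update first
  every ring node by multi-head attention over its context
  [h_{k−1}; h_k; h_{k+1}; s] and then the planet over [s; H], each followed
  by ReLU and LayerNorm. The channel output is the residual
  f^h = exp_0(lift(f)) + λ·s^L, mapped back to the tangent space by the
  logarithmic map.
- **Gate fusion.** g = sigmoid(W[f^e; f^{h'}]) element-wise;
  output = g ⊙ f^e + (1−g) ⊙ f^{h'} — a per-channel convex combination, so
  the fused feature always lies between the two channel features.

Defaults: stage widths (64, 64, 128, 256, 512); K = 20; hyperbolic encoder
L = 2 layers, 4 heads, λ = 1.0, c = 1.0 fixed; LeakyReLU slope 0.2;
element-wise gate. Ring edges can be dropped independently with probability
1 − p (default p = 1, deterministic ring); dropped edges are masked out of
the attention context.

**Ball projection.** The star-transformer layers apply LayerNorm'd attention
arithmetic directly to ball coordinates, so the residual f^h + λ·s^L can
leave the ball (‖s^L‖ ≈ √M after LayerNorm). Before the log map the feature
is rescaled onto radius (1 − 0.05)/√c whenever it lies outside. The wide
margin is an optimization choice: artanh'(0.95) ≈ 10, whereas a margin of
10⁻⁵ puts the feature where artanh' ≈ 5·10⁴ and gradients through the gate
explode, visibly stalling early training. With the default λ = 1 the
projection is usually active, which makes the hyperbolic channel effectively
directional (magnitude saturates at the projection radius); the gate learns
how much of it to use. The exponential map itself clamps its output just
inside the boundary, since tanh rounds to 1 in floating point for arguments
≳ 19.

**Gate initialization.** The gate bias starts at +2 (g ≈ 0.88), so fusion is
Euclidean-dominant while the hyperbolic branch is still untrained noise; the
bias is learnable and moves freely during training.

**Optimization.** L = α·L_CE + β·L_triplet with α = 0.9, β = 0.1
(CE-dominant; the triplet term only shapes the embedding), margin 0.2, 128
random (anchor, positive, negative) triplets per batch drawn from the
pre-head concatenated embedding. SGD with momentum 0.9, cosine-annealed
learning rate 0.1 → 0.001, batch size 4, early stopping on validation loss
(patience 10 by default). Gradients are clipped to global norm 5. Training
raises on a non-finite loss.

## Numerical engine

The network runs on a small reverse-mode autodiff tape over numpy
(`stemleaf.autodiff`); every backward rule is tested against central finite
differences. Hot paths are fused into single tape nodes (scaled-dot-product
attention, softmax pooling, LayerNorm, the kernel/spatial inner product),
gathers scatter their gradients through sparse selection matrices, and a
batch of clouds is merged into one block-diagonal graph so each op runs once
per batch. Training uses float32 tensors (`default_dtype`); all scientific
oracles (exp/log maps, metrics, phenotyping) are plain float64 numpy.

A note on equivariance: farthest point sampling starts from the point
farthest from the centroid (coordinate-lexicographic tie-break) rather than
a random index, so the sampled set — and with it the whole forward pass — is
invariant to the ordering of the input points. A seeded random start remains
available.

## Instance segmentation

K-means (k-means++, 10 restarts, seeded) on leaf points only; stem points
keep instance id −1. The cluster count is selected by the elbow criterion on
the inertia-vs-K curve, operationalized as the K whose point on the
**log-inertia** curve lies farthest from the chord joining the endpoints of
the curve. The log scale is deliberate: leaves are extended surface patches,
so the within-cluster scatter at the true K is large and the linear-scale
curve bends too early (the linear chord criterion systematically picked K
below the true leaf count), while the log curve flattens visibly once every
leaf has its own cluster. For a two-value K range there is no curve to bend;
the larger K is accepted only if it at least halves the inertia. K range
defaults to 1..10 (cucumber seedlings carry roughly 6–8 leaves). Clustering
runs on restored metric coordinates, since phenotyping follows.

## Phenotyping

- **Plant height** = z_max − z_min over the full restored cloud.
- **Leaf length/width** = Euclidean distances between the two points
  extremal along the first/second principal axis of the leaf's PCA, ordered
  so length ≥ width. Chord distances (not projected extents) follow the
  measurement convention of comparing against a ruler on the physical leaf;
  surface curvature therefore inflates both slightly relative to a flattened
  leaf. When a leaf is nearly circular (length ≈ width) the principal axes
  are ambiguous and the two measures can mix — an inherent degeneracy, not
  an implementation artifact.
- **Leaf area**: the leaf is parametrized on its principal plane and
  Delaunay-triangulated there; a triangle is kept only if a pivot ball of
  the configured radius could touch its three vertices (3D circumradius ≤
  radius — the ball-pivoting acceptance criterion, realized as an
  alpha-complex since the full pivoting front is unnecessary on
  height-field-like leaf patches). Only the largest connected sheet is
  retained, which discards spurious triangle islands formed by stray points
  that instance clustering occasionally assigns across leaf boundaries. The
  area is Σ √(s(s−e₁)(s−e₂)(s−e₃)) over the kept triangles. Default pivot
  radii are {1.5, 3, 6}× the mean nearest-neighbor spacing; the largest
  radius bounds the filter. The reference ("manual") leaf area convention is
  0.743 · L · W.

## Synthetic plants

Real training data for this task are individual plant scans with manual
stem/leaf annotation; the package ships a parametric generator that emulates
a cucumber seedling at the 6–8 leaf stage and carries exact ground truth:

- **Stem**: a slightly bowed vertical tube (default height 15 cm, radius
  0.15 cm), label 1.
- **Leaves**: bent elliptical patches r(u, v) = a·u·e₁ + b·v·e₂ + c·a·u²·e₃
  over the unit disk, attached at laddered heights (25 %–95 % of the stem)
  and golden-angle-staggered azimuths with random elevation 15–40°; label 0,
  one instance id per leaf. Default semi-axes from length 5–7 cm × width
  3.5–5 cm; bend fraction c = 0.15.
- **Ground truth**: both bend-displaced endpoints of the major axis share
  the same normal offset, so the true length chord is exactly 2a and the
  width chord exactly 2b; the four extremal points are always included in
  the sample. The patch area is computed by midpoint quadrature of
  a·b·∬√(1 + 4c²u²) du dv. Plant height is the z-extent of the noise-free
  points.
- **Sampling**: points are allocated to organs proportionally to surface
  area (the thin stem is the minority class, as in real plants) and sampled
  uniformly w.r.t. surface measure (rejection sampling); ~8 % of each leaf's
  points (at least 24) lie on the leaf margin at stratified angles — scanned
  leaves are delimited by their physical edge, and without rim samples any
  surface reconstruction clips the outline by the inscribed-polygon deficit
  (≈ 6.6/n² of the area for n rim points). Gaussian surface noise
  (default SD 0.05 cm) is added last.
- **Corruptions** mirror the robustness protocol used on real data: seeded
  uniform removal of ⌊ratio·N⌋ points, and replacement of a chosen number of
  points by uniform draws from [−1, 1]³ (labels retained), defined on
  normalized clouds.

What the generator does **not** emulate: reconstruction artifacts with
spatial structure (SfM speckle, background bleed), self-occlusion, petioles,
leaf veins/serration, and non-elliptical leaf outlines. Passing tests on
synthetic plants therefore demonstrate the mechanics and the learning
capacity of the pipeline, not field performance on photogrammetric scans.

## Scaled study sizes and regimes

All shipped experiments run on one CPU: training uses 32 plants × 512 points
(halved network widths, K = 10, 12–15 epochs), evaluation 8–10 held-out
plants, phenotyping 10 plants × 2000 points. These sizes are the package's
own defaults for its synthetic study; the architecture accepts full-scale
clouds (4096 points, full widths) unchanged.

Two junction regimes matter. With the generator default `junction_gap = 0`
the leaf blades attach directly to the stem; at 512-point resolution about
5 % of points then sit in mixed-label junction shells (their K-NN majority
label disagrees with their own), which bounds what any smooth classifier can
reach on this data — trained models plateau at ≈ 0.95 accuracy there. With
`junction_gap = 1 cm` — the petiole stand-off real cucumber leaves have
(blades sit on leaf stalks, which this generator does not model as points) —
the geometry is nearly separable (≈ 0.7 % ambiguous) and the same training
reaches ≈ 0.98. The learning-sanity experiments and the acceptance script
use the separable regime; the hard regime remains the default because real
junctions are the known failure mode of stem–leaf segmentation.

Learning-capacity ("overfit") experiments monitor the training loss itself
rather than selecting the best-validation snapshot — snapshot selection is
an anti-overfitting device and caps the training-set accuracy the experiment
is supposed to measure. Held-out accuracy is measured on separately
generated plants.

## Degenerate inputs and tie-breaks

KNN excludes the query point itself and breaks distance ties by lower index;
all-duplicate clouds remain valid. Normalization refuses coincident-point
clouds (zero scale). Vacuous metric classes (absent from prediction and
truth) score IoU 1.0 by default and can be skipped via `vacuous_iou=nan`.
R² is undefined (raises) when the reference values have zero variance.
Leaf measurements require ≥ 3 non-collinear points; reconstruction failures
for a leaf yield NaN area rather than aborting the plant.
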