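# Methods

## Overview

`morphocloud` learns orientation-independent representations of 3D
multi-piece intracellular structures from point-cloud encodings of
single-cell microscopy data. Two morphology families are supported:

* **punctate** structures (DNA replication foci, centrioles, ...): the
  biology lives in the *locations* (and intensities) of discrete spots, so
  a cell is encoded as an XYZ(+intensity) point cloud;
* **polymorphic** structures (nucleoli, Golgi, ...): the shapes of the
  individual pieces matter, so a cell is encoded by surface points plus a
  clipped signed distance field (SDF, negative inside).

Both encodings feed a rotation-equivariant vector-neuron autoencoder whose
latent is a stack of C three-dimensional vectors. Rotating the input by R
maps the latent V to V·Rᵀ; the per-channel norms ‖V_c‖ are therefore a
rotation-invariant representation, and Gram–Schmidt on two designated
latent channels recovers a proper rotation matrix used to reorient
canonical reconstructions.

## Synthetic data generators

No external data is required: two seeded generators emulate the study
conditions.

### Packing simulator (punctate)

Nucleus-like shapes are deformed ellipsoids: an icosphere (2 subdivisions
by default) radially perturbed by a band-limited random field (polynomial
harmonics to degree 3, relative amplitude 0.15) and anisotropically scaled.
Semi-axes are drawn per nucleus from x ∈ [5, 8], y ∈ [8, 14], z ∈ [3.5, 6]
(arbitrary voxel-like units; typical coordinates span −10..10). The y axis
is the longest, matching nuclei aligned to their longest axis, and the
ranges include high-aspect-ratio shapes for which the planar rules at
different angles genuinely differ.

256 points per nucleus are drawn by rejection sampling from a density
proportional to a rule weight:

| rule      | weight                                  | default β |
|-----------|------------------------------------------|-----------|
| random    | 1                                        | —         |
| radial    | exp(−β‖p − centroid‖)                    | 0.5       |
| surface   | exp(−β·dist(p, surface))                 | 1.5       |
| planar θ  | exp(β·|d_plane(p)| / d_max)              | 4.0       |

with plane normals (0,0,1), (0,1/√2,1/√2), (0,1,0) for θ = 0°, 45°, 90°.
The planar distance is normalized by the mesh extent d_max along the rule
normal so all three orientations get equally sharp gradients in
anisotropic nuclei; on a unit sphere d_max = 1 and the weight reduces to
exp(β·|d|). The exponential form is a modeling choice: it is monotone in
the stated bias direction and reduces exactly to the uniform rule at β = 0
(and the β = 0 code path is bit-identical to the random rule). β defaults
were fixed once so that the six rules are statistically separable from
each other (in particular so the planar-0 gradient across the short z axis
is not drowned by packing noise) while rejection sampling stays tractable;
rejection (not MCMC) keeps the target density exact, with an
acceptance-rate guard that suggests lowering β instead of looping forever.
Sphere radii are not modeled: points are dimensionless centroids.

### Blob generator (polymorphic)

Multi-piece segmentations are unions of non-overlapping ellipsoidal blobs
(semi-axes 2.5–5.5 voxels by default) placed in a 32³ grid, with
ground-truth per-piece volumes, surface areas and pairwise centroid
distances recorded for the regression benchmarks. Overlap is excluded
conservatively via bounding spheres with a 1-voxel gap.

What these generators do *not* emulate: real nuclear shapes (only smooth
deformed ellipsoids), spatial correlation between pieces and the nuclear
envelope, intensity textures, segmentation artifacts, and the
finite-radius collision constraints of a true packing engine. Tests that
pass on these data therefore validate the pipeline's correctness and the
recoverability of planted organization rules — not performance on real
microscopy.

## Preprocessing

### Intensity point clouds (punctate)

Masked intensities are clipped to the configured contrast range and
min–max scaled to [0, 1]; voxel sampling probabilities are

P_v = exp(λ·s·I_v) / Σ_w exp(λ·s·I_w),

where s is the adjusted Fisher–Pearson sample skewness of the masked
intensities and λ defaults to 100 for nucleus-masked and 500 for
cell-masked structures. Probabilities are computed with max-subtraction so
large λ·s cannot overflow; a constant masked image degrades to uniform
sampling with a warning. A dense cloud of 20,480 voxel draws (i.i.d. with
replacement) is converted to physical XYZ, centered on the mask centroid,
and carries the normalized intensity as a fourth coordinate. During
training a sparse 2,048-point subsample (without replacement) is taken,
the intensity column is scaled by 0.1 and then all four coordinates by a
global 0.1.

Jitter augmentation stacks eight Gaussian-jittered copies of a cloud
(σ = clip/2, clipped at ±0.2), extending 256 points to 2,048, and repeats
the process ten times per input.

### SDF pipeline (polymorphic)

Segmentations are hole-filled (binary 3D fill), meshed by marching cubes
at the 0.5 isolevel on a zero-padded volume, and rescaled into a
[0, grid]³ cube (grid 32 by default, 64 supported) either with a fixed
dataset-wide scale (preserving relative sizes) or per cell from the
bounding box; a 1-voxel margin keeps the ±2 clip band reachable outside
the shape. Surface clouds are area-weighted uniform samples (32,768
points); SDF queries are uniform in the cube with signed distance =
exact nearest-triangle distance signed by winding-number containment
(negative inside), clipped to ±2. Training subsamples 8,192 surface and
20,000 query points per pass. Multi-piece shapes use a single composite
field (distance to the nearest point of any piece).

Mesh queries (containment, nearest-triangle distance) are computed
directly in vectorized numpy: generalized winding numbers via the
van Oosterom–Strackee solid-angle formula, with an exact half-space
shortcut for convex meshes, and point–triangle distances via clamped
barycentric projection. Brute force over faces is the right regime for
the 10³–10⁴-face meshes this package produces.

## Model

### Encoder

A vector-neuron dynamic-graph edge-convolution stack. Features are
(N, C, 3) vector stacks; VN linear layers mix channels only, and the VN
leaky ReLU (slope α = 0.2) rescales each channel based on its projection
onto a learned direction, so every layer commutes exactly with rotations.
Six blocks by default; per block, a k-nearest-neighbor graph (k = 20) is
recomputed from the current flattened features, per-edge messages
concatenate [neighbor features, feature differences, neighbor features ×
anchor point, anchor point], pass through VN linear + VN leaky ReLU, and
are mean-pooled over neighbors. Intermediate block outputs are
concatenated and mixed into the final latent.

Default hidden widths are (16, 16, 16, 32, 32, 32); the desk-scale
benchmark uses (8, 8, 8, 16, 16, 16) with bottleneck 64 (256/512 are the
full-scale punctate/polymorphic sizes). A fourth (intensity) input
coordinate is lifted as a second input channel sharing the point's vector
orientation — the XYZ direction scaled by the intensity — which keeps the
lift exactly equivariant.

**Pooling over points.** The latent is pooled with an equivariant max
pool: per channel, the point whose feature has the largest projection onto
the channel-mean direction is selected (projections are
rotation-invariant, so the selection and hence equivariance survive
rotation). Mean pooling is available via config, but at desk scale its
invariant norms were barely more discriminative than chance for the six
packing rules, while max pooling — the standard choice in edge-conv point
networks — clearly separates them; max is therefore the default.

### Decoders and losses

*Punctate*: a folding decoder concatenates the invariant representation
with template source points (a Fibonacci sphere of radius 0.5 for the
packing data, a 2D plane grid otherwise) and applies two folding MLPs with
ReLU. The canonical reconstruction is reoriented by the rotation matrix
recovered from the latent (not by Procrustes). The loss is the earth
mover's distance under a squared Euclidean ground metric, reported as the
*mean* matching cost; the optimal bijection is solved exactly (Hungarian)
up to 512 points and entropically (log-domain Sinkhorn, ε = 1% of the
median pairwise cost, ≤ 2000 iterations) above. Gradients flow through
the matched squared distances with the assignment held fixed, the
standard treatment of assignment-based losses.

*Polymorphic*: an implicit decoder maps (conditioning ⊕ query coordinate)
to a scalar signed distance (4 hidden layers of 64 by default; queries are
affinely mapped to ≈[−1,1] before the MLP). During training the decoder is
conditioned on the flattened vector latent — orientation-aware, so
oriented SDF targets are reconstructable — and the invariant norms are
extracted after training for analysis.

### Training and autodiff

The numerical core is a small reverse-mode automatic-differentiation
engine over float64 numpy arrays written for this package (two-operand
einsum, gather/concat/reductions, cross products, masked nonlinearities),
with gradient correctness pinned by finite-difference tests. Optimization
is Adam (lr 10⁻³) with one sample per step, seeded shuffling, and an
optional per-epoch resampling hook (sparse subsampling / jitter). All
randomness — shape sampling, packing, initialization, subsampling,
shuffling — descends from one master seed through `numpy.random.
SeedSequence` spawning, so every pipeline is bit-reproducible.
Checkpoints are single-file archives (weights + config YAML + manifest
hash).

## Benchmark metrics

* **Reconstruction error** — EMD (punctate) or mean squared SDF error at
  held-out queries (polymorphic), per sample.
* **Rotation invariance error** — mean pairwise distance between the
  representations of uniformly rotated copies of a sample, divided by the
  mean representation norm (scale-free across models).
* **Compactness** — Levina–Bickel maximum-likelihood intrinsic dimension,
  averaged over k ∈ [5, 20], with the unbiased (k−2) normalizer (the
  log-ratio sum is Gamma(k−1, 1/m), so the inverse has expectation
  m/(k−2); the (k−1) form overestimates by (k−1)/(k−2) and misses the
  known dimension of simple manifolds). Lower is better (more compact).
* **Classification / regression heads** — stratified 5-fold multinomial
  logistic regression (top-k accuracy) and cross-validated ridge R² on
  standardized representations.
* **Interpolation metrics** — representations of a pair are linearly
  interpolated and decoded; *evolution energy* is the summed
  reconstruction-space distance between consecutive interpolants, using
  the square root of the mean EMD matching cost so a linearly decoded
  path has step-count-independent energy; *average interpolate distance*
  is the mean distance from each interpolant to its nearest dataset
  representation (an on-manifold proxy). Both definitions are this
  package's operationalizations.
* **Efficiency** — exact parameter count; wall-clock inference time is
  reported but never asserted (hardware-dependent); no device energy
  counters are read, so the energy field is null.
* **z-score summary** — per metric across models, sign-flipped so larger
  is always better; zero variance yields zeros with a warning.

## Latent-space analyses

* **PCA latent walks**: PCA fit per group; representation walked along a
  component at map points −2σ..2σ; decoded or matched to the nearest real
  sample.
* **Archetypal analysis** (principal convex hull): minimize
  ‖X − W(BX)‖² with simplex-constrained rows of W and B by alternating
  NNLS (sum-to-one via a penalty row), 5 seeded restarts, best residual
  kept. Archetypes are convex combinations of data rows by construction.
* **Volume bins**: equal-count quantile bins of nuclear volume (ties
  broken by sample id), per-bin mean representation and nearest real
  example. Equal-count (not equal-width) is the chosen reading of
  "equally sized bins".
* **LDA axes**: two-class LDA with Ledoit–Wolf shrinkage; examples
  retrieved at even projection quantiles along the axis.
* **Perturbation profiling**: per treatment, each treated cell ranks all
  other cells (treated ∪ control) by Euclidean representation distance;
  mAP over treated cells; permutation null over treatment labels with
  p = (1 + #{null ≥ obs}) / (1 + B); Benjamini–Hochberg q-values across
  treatments; significance at q < 0.05 (equivalently 1/q > 20).

## The desk-scale headline benchmark

`morphocloud.benchmarks.rule_archetype_recovery` reproduces the
unsupervised rule-discovery claim end to end at desk scale: 6 rules × 50
shared nuclei (300 packings of 256 points), autoencoder with bottleneck
64 and hidden widths (8, 8, 8, 16, 16, 16), sphere-template folding
decoder, 6 epochs of EMD training, then six archetypes fit to the
per-channel standardized invariant representations. Standardizing before
the archetype fit is a package design choice: archetypal analysis is not
equivariant to anisotropic channel scalings, and without it a few
high-magnitude channels dominate the hull geometry. Each sample is
assigned to its top-weight archetype and the number of distinct
archetype-majority rules is reported (6/6 = full recovery). Problem sizes
(50 nuclei per rule, 6 epochs, reduced widths) are the package's
desk-scale defaults; the full-scale study conditions (254 nuclei,
GPU-scale training, bottleneck 256) are documented but not the defaults.

## Numerical choices and degenerate inputs

* knn ties are broken by lower index on distances rounded at 1e−12, so
  rotated clouds produce identical graphs.
* Gram–Schmidt rotation recovery raises on near-zero (< 1e−8) or
  near-parallel (cos within 1e−6 of 1) designated channels.
* Duplicate points in the Levina–Bickel estimator trigger a tiny distance
  floor with a warning; constant targets and single-member classes are
  rejected in the regression/classification heads.
* The permutation p-value uses the add-one estimator, so p ≥ 1/(B+1) and
  the null calibration is super-uniform rather than exactly uniform.

## Known limitations

* The autodiff engine is single-threaded numpy; training throughput is
  orders of magnitude below a GPU framework, so default problem sizes are
  small. Results on the synthetic generators validate mechanism, not
  biological performance.
* Image-based baseline autoencoders (steerable CNNs, masked ViTs) and
  CellProfiler baselines are out of scope; the benchmark compares
  configurations of the point-cloud model only.
* The Sinkhorn EMD is biased slightly upward relative to the exact
  matching cost (entropic regularization); agreement is within 5% at the
  validated scales.
* At desk scale the archetype–rule alignment of the headline benchmark is
  sensitive to the random seed: the invariant representations separate the
  six rules well under a linear classifier, but the best-residual
  six-archetype fit can split one rule's elongated cluster and absorb one
  of the planar rules. Full recovery at every seed would need the
  full-scale model capacity and dataset size.
* Real-data loaders (OME-TIFF masks, manifests) are provided, but no
  real-dataset results are claimed or reproduced here.
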