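# Methods

This note documents the models, conventions and design choices behind
`meshgat`, in the order of the pipeline.

## Mesh model and quality control

A tumor surface is a triangle mesh (vertices, index triples); faces are
assumed consistently wound, and `ensure_outward_orientation` repairs winding
and flips inward-facing surfaces before signed-distance queries. Hole damage
is operationalized as the **boundary-edge fraction**: the percentage of
undirected edges incident to exactly one triangle. This is the unambiguous
discrete signature of holes, lies in [0, 100], and is invariant to vertex
order and rigid motion. A mesh is excluded when the percentage exceeds the
threshold *strictly* (default 10%): a mesh at exactly 10.0% is retained.
Other operationalizations (e.g. hole-area fraction) are possible; this one is
the default because it needs no repair or hole-triangulation step.

## Signed distance

The projection of a query point is the exact closest point over all
triangles (region-based point-triangle projection, vectorized over faces).
The sign is the sign of the dot product between the offset vector and the
**angle-weighted pseudo-normal** of the nearest surface feature — face
normal in the interior, edge pseudo-normal (mean of the two adjacent face
normals) on an edge, angle-weighted vertex normal at a vertex. The
pseudo-normal rule is the standard robust convention for sign decisions at
non-smooth projection points, where the plain face normal is ambiguous.
Positive is outside, negative inside.

## The ten features

Sizes (volume, surface area) are exact sums over triangles; volume takes the
absolute value of the signed-tetrahedra sum and is exact for watertight
meshes only (QC guarantees this upstream). Sphericity is the canonical
isoperimetric ratio π¹ᐟ³(6V)²ᐟ³/Sa ∈ (0, 1]; it refuses non-watertight
input rather than returning a meaningless value.

Eigenvalue features come from covariances of vertex coordinates, with
normalized eigenvalues λ₁ ≥ λ₂ ≥ λ₃ ≥ 0, Σλ = 1:

- **curvature** C = mean over vertices of λ₃ (local k-NN covariance,
  k = 30 by default, capped at the vertex count): 0 on a plane, ≤ 1/3;
- **eigen-entropy** E = mean over vertices of −Σ λᵢ ln λᵢ ∈ [0, ln 3]. The
  Shannon sign is used so that rugged, locally isotropic neighborhoods score
  *high* (the sign-free form is non-positive for normalized eigenvalues);
- **anisotropy** A = (λ₁ − λ₃)/λ₁ of the **whole-mesh** covariance:
  anisotropy describes the directional distribution of the point set as a
  whole (≈ 0 for a round tumor, → 1 for an elongated one).

The mode split (global anisotropy, local curvature/entropy) is a deliberate
design choice, not an accident. For *local* surface neighborhoods the three
quantities are rigidly coupled: writing a site's eigenvalues as (1, x, r)
up to scale, A = 1 − r, C = r/(1 + x + r), and E is maximized at the planar
frontier x = 1, where it decreases as A grows. A smooth surface sits on that
planar frontier, so *no* family of meshes can simultaneously raise local
anisotropy, local entropy and local curvature relative to a smooth baseline
— averaging over mixed site populations cannot cross the concave frontier
either. With global anisotropy the three features measure genuinely
independent aspects (elongation, local ruggedness, local bending) and the
expected benign/malignant contrasts are all realizable at once. Both local
and global modes remain available on every eigen feature (`mode=` /
`FeatureConfig.anisotropy_mode`).

Distance features: the mesh diameter is computed on convex-hull vertices
(exact versus the all-pairs definition); the centroid distance uses the
area-weighted mean of face centroids as the center; bounding-box min/max
default to vertex-to-box-corner extremes (`bb_mode="corner"`). The literal
distance-to-box-surface variant (`"face"`) is selectable but its minimum is
identically 0 for any mesh touching its own bounding box. Box distances
follow the axis-aligned box, so they are translation- and scale-covariant
but not rotation-invariant; all other features obey the full rigid-motion
and scaling laws (V ∝ s³, Sa ∝ s², distances ∝ s, dimensionless features
invariant).

Degenerate inputs: fewer than 4 points, zero total covariance, or zero face
area raise errors; local neighborhoods with λ₁ = 0 are skipped with a
warning; k-NN ties resolve by vertex index (scipy cKDTree order).

## Feature assessment

ANOVA is the textbook one-way F over the two classes (p from F(1, N−2));
zero within-group variance with differing means reports F = ∞, p = 0,
flagged. MRMR uses the F-statistic-relevance / mean-absolute-Pearson-
redundancy **quotient** scheme (FCQ): the first pick maximizes relevance,
later picks maximize relevance ÷ mean |ρ| against the already-selected set;
scores are min-max scaled to percent and ties break lexicographically.
Significance threshold for reporting defaults to p < 0.05. Selection is
reported, not enforced: downstream stages consume all ten features unless
overridden.

The pattern summary samples each class without replacement at the requested
subset sizes (seeded, capped at the class size with a warning) and reports
feature means; the "all" row is the exact class mean.

## Sample graph

Rows are ranked **within** each row across the ten features, and the edge
weight is the Pearson correlation of those rank profiles (Spearman). The
threshold comparison is inclusive (≥ 0.7 by default); constant rows have
undefined correlation and simply contribute no edges; isolated nodes are
retained. Edges are numbered in lexicographic (source, target) order of
unique IDs; exports round correlations to 2 decimals while full precision
stays in memory.

`build_graph` uses raw feature values by default. The **pipeline** stage
sets `standardize=True` (z-score columns first): with ten features of very
different magnitudes, raw within-row ranks are dominated by the fixed
magnitude ordering, making all rows correlate near 1 and the graph complete
— and on a complete graph additive attention collapses, because
softmax over an identical neighborhood of f(i) + g(j) no longer depends
on i. Rank profiles of *deviations* instead compare how each mesh differs
from the cohort, which yields a strongly class-assortative graph. Both
behaviours are a switch on `build_graph` and the CLI.

## GAT

Architecture: input dense layer (features → hidden units) → `attention_layers`
multi-head attention layers → output dense layer with softmax over the two
classes. Conventions: LeakyReLU slope 0.2 in the attention score; a
self-loop in every neighborhood (isolated nodes attend to themselves with
α = 1); head outputs concatenated on hidden layers and averaged on the last;
Glorot-uniform initialization, deterministic per seed. "Batch size" under
full-graph transductive training selects how many training nodes enter each
step's cross-entropy; the forward pass is always the full graph. The
optimizer is gradient descent with momentum (momentum is a tunable axis).
Node features are z-scored with statistics fitted on training nodes only.
Splits are stratified 70/15/15 by default; edges are never removed — only
the loss masks differ between splits. The best-validation-accuracy
checkpoint is returned and evaluated on all three splits.

Implementation: pure NumPy with analytically derived gradients, verified
against central finite differences (relative error < 1e-7 in the test
suite). Neighborhood softmaxes use receiver-sorted edge arrays with
`reduceat`; the α-weighted aggregation and its transpose run as CSR
sparse-matrix products on a fixed sparsity pattern.

The evaluation report stores the confusion matrix and derives accuracy,
sensitivity, precision, specificity, NPV, FPR, FDR, FNR, F1 and MCC (all in
percent). Undefined ratios are NaN/null, never silently 0, except MCC,
which returns 0 with a `mcc_degenerate` flag when a denominator factor
vanishes (the usual convention).

Cross-validation is stratified k-fold (scikit-learn folds, seeded): each
fold is held out once while the remaining folds train, transductively on
the fixed graph. The ablation driver is sequential one-axis-at-a-time over
the seven configuration axes, keeping each stage's best-test-accuracy value
(the default grid has 3+2+3+3+3+3+2 = 19 configurations).

`GATConfig` defaults are the full-scale winners (relu, 32 hidden units, 4
attention layers, learning rate 1e-6, batch 64, momentum 0.9, 8 heads). For
synthetic desk-scale runs the pipeline uses a practical training
configuration — 2 attention layers, 4 heads, learning rate 1e-3, 100
epochs — which trains in seconds and reaches the same accuracy; a learning
rate of 1e-6 needs far more epochs than is useful at this problem size.

## Synthetic generator

Each mesh is a subdivided icosphere (level 3 → 642 vertices) radially
displaced: an ellipsoid base (semi-axes in mesh units), low-order smooth
lobulation, optional Gaussian radial spikes at random directions
(spiculation) and per-vertex high-frequency radial noise. Displacing a
closed surface radially preserves its topology, so every generated mesh is
watertight; `punch_holes` exists separately to exercise QC. Benign defaults:
near-oval axes (1.0, 0.9, 0.8), gentle lobulation, no spikes, noise sd
0.004. Malignant at full contrast: axes (1.9, 1.05, 0.9) (larger and
eccentric), 14 spikes of relative height 0.45 and angular width 0.22 rad,
noise sd 0.035. `separation` ∈ [0, 1] linearly interpolates every malignant
parameter from the benign baseline; per-mesh lognormal jitter (sd 0.12)
provides within-class variance. At separation 0 the classes are
statistically identical (ANOVA finds no signal); at the default 0.8 the six
qualitative contrasts hold in batch means: malignant exceeds benign in
anisotropy, eigen-entropy, curvature, volume and surface area, and benign
exceeds malignant in sphericity.

The generator emulates *shape statistics only*. It does not model
ultrasound physics (speckle, shadowing), scanner- or operator-dependent
segmentation error, the reconstruction artifacts of image-to-mesh systems
(beyond optional hole punching), or correlations between tumor size and
image quality. Passing tests therefore demonstrate that the pipeline
recovers class structure from mesh geometry under controlled conditions,
not clinical performance on real ultrasound data.

## Problem sizes and determinism

End-to-end runs use 120 benign / 60 malignant meshes (the 2:1 class
imbalance of the motivating cohort at reduced count); the
separation-monotonicity study uses 45/45 meshes per level over 5 separation
levels × 3 seeds. Every stochastic component (generator, splits, folds,
initialization, batch order) derives from an explicit seed, and reruns with
the same manifest reproduce features and edge lists byte-for-byte.

## Known limitations

- Feature magnitudes depend on mesh resolution through the k-NN
  neighborhoods (k = 30 covers a larger surface patch on a coarser mesh);
  compare features only across meshes of similar vertex count, or fix
  subdivision in the generator.
- The hole percentage is a topological measure; a mesh with many tiny holes
  and one with a single large hole of equal boundary-edge share score alike.
- The GAT is transductive: adding new tumors requires rebuilding the graph
  and re-scoring (the trained weights remain usable).
- MCC's zero-denominator convention (0, flagged) makes degenerate confusion
  matrices comparable but is a convention, not a measurement.
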