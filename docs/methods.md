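# Methods

`sgcp` implements a two-stage pipeline for connectivity-based cortical
parcellation on voxel-level structural-connectivity graphs, together with a
synthetic generator that reproduces the statistical structure the method
assumes, so that every stage is testable without imaging data.

## Problem setting

A *target region* is an atlas-defined ROI plus a surrounding shell of
voxels. Upstream probabilistic tractography yields two matrices per target
region: a voxel-voxel intra-region count matrix, binarised into a symmetric
adjacency `A` (an edge wherever at least one fibre was tracked; the
threshold is exposed for sensitivity analysis), and a voxel-to-ROI count
matrix `X` whose row i is voxel i's *connectivity profile* over the n atlas
ROIs. Voxels also carry millimetre coordinates `P`. Parcellation is binary
voxel classification: inside vs outside the ROI, scored by Dice
2|P∩T|/(|P|+|T|) against ground truth.

Fibre counts are heavy-tailed across ROIs, so the default feature transform
is `log1p` followed by per-column max-normalisation to [0, 1]. The transform
is applied at the embedding stage, not at graph construction, so graphs
round-trip to disk with integer counts intact; it can be disabled
(`EncoderConfig.feature_transform=None`).

## Stage I: self-supervised embedding

**Augmentation.** Two stochastic views of a graph are drawn by edge
deletion and feature masking, both *centrality-adaptive*: with node degree
φ(u), edge importance is w_uv = (φ(u)+φ(v))/2 and feature importance is
w_i = Σ_u 1[X_ui > 0]·φ(u); both are log-damped, s = log w. Removal
probabilities follow

    p = min( (s_max − s) / (s_max − mean(s)) · level , p_τ )

with level p_e for edges, p_f for features and a cut-off p_τ that prevents
over-corruption: the most important item is never removed, the least
important is capped at p_τ. Degenerate cases: if all importances coincide,
every item gets min(level, p_τ); a zero-importance feature (occurring
nowhere) takes the formula's limit, p_τ (or 0 when the level is 0, so a
zero-level augmentation is exactly the identity). A `literal_formula` flag
inverts the rule to `1 − min(…)` for fidelity experiments; it deletes the
*most* central edges almost surely and is not the default because it
contradicts the stated premise of importance-preserving augmentation.
Masking is column-wise — one Bernoulli draw per feature dimension applied
to all nodes — because the masking probability is indexed by dimension
only. Occurrence may alternatively be weighted by count magnitude
(`occurrence_binarize=False`).

**Encoder.** The spatial-graph convolution updates node i by

    h̄_i = Σ_{j∈N_i} ReLU(Uᵀ(p_j − p_i) + b) ⊙ h_j ,

a neighbour sum gated by a learned function of the *relative* position
(U ∈ ℝ^{3×d}, b ∈ ℝ^d). Only coordinate differences enter, so the encoder
is translation-invariant and permutation-equivariant by construction, and a
node's embedding depends only on its ≤ n_layers-hop neighbourhood. Each
layer applies k filters and concatenates their outputs; because
concatenation multiplies width by k per layer, a *mixing* linear map
projects each layer back to the configured width (hidden_dim between
layers, output_dim at the end). Pure concatenation (`mixing=False`) is kept
for unit testing against the functional form. There is no self-term in the
neighbour sum (p_i − p_i = 0 would reduce it to a bias gate); an optional
`input_skip` adds a learned linear self-contribution, off by default. ReLU
sits between layers; the last layer is linear so embeddings are
unconstrained for cosine similarity. Defaults: 2 layers, 2 filters, hidden
32, output 32, uniform Glorot initialisation from a seeded generator.

The ablation encoder is a standard GCN — symmetric-normalised propagation
D̃^{-1/2}(A+I)D̃^{-1/2} with per-layer linear maps — at matched depth and
width, ignoring coordinates.

**Objective.** Embeddings h are projected by a one-hidden-layer MLP to a
lower-dimensional metric space z = g(h), d′ = d/2. For anchor i in one
view, the same node in the other view is the positive; all other nodes in
both views are negatives (full-graph batch — no sub-sampling at the
~10³-voxel scale):

    ℓ(z1_i, z2_i) = −log e^{θ_i,i/τ} / (e^{θ_i,i/τ} + Σ_{k≠i} e^{θ(z1_i,z2_k)/τ}
                                                     + Σ_{k≠i} e^{θ(z1_i,z1_k)/τ})

with θ cosine similarity and temperature τ = 0.5; the loss averages both
anchor directions over all N pairs. The projection is applied once
(θ computed on z = g(h)); a `double_projection` flag reproduces the
literal reading θ = s(g(z1), g(z2)) with g applied twice. Encoder and head
are trained jointly by Adam (lr 1e-3, 200 epochs, one step per region per
epoch). One shared encoder is trained on the union of regions —
self-supervised training touches no labels, and a single encoder is what
lets frozen embeddings be reused across cross-validation folds with "only a
new classifier retrained" per fold.

Numerics: cosine similarities are bounded by 1, so the soft-max is
stabilised globally via exp((S−1)/τ) and each of the three N×N similarity
blocks is exponentiated exactly once. The training loop runs in float32
(the loss is memory-bound at N×N scale; single precision is standard for
SGD), while the public functional API and all oracle comparisons are
float64. All gradients are hand-derived and verified against central finite
differences in the test suite. A non-finite loss (typically τ too small)
aborts with a diagnostic rather than training on garbage.

## Stage II: supervised parcellation

Embeddings of the *original* (un-augmented) graphs are frozen. A small MLP
(one hidden layer of 64 units by default — the headline configuration;
depth is configurable) with sigmoid output is fitted by cross-entropy
(scikit-learn `MLPClassifier`, Adam, ≤300 epochs with its default
plateau-based stopping) on the pooled (embedding, label) pairs of the
training regions, after per-fold standardisation fitted on training data
only. Predictions threshold the sigmoid score at 0.5 — fixed, never tuned
on test folds. Class imbalance (ROI ≈ 40% of the target region) is left
unweighted by default; a `balanced` flag oversamples the minority class.
Evaluation is leave-one-region-out: each fold trains on all other labelled
regions and scores the held-out region by Dice within its own target
region. The positive voxel set is reported verbatim; an opt-in
post-processing step keeps only its largest 6-connected lattice component.

## Synthetic data

The generator emulates, per region: (i) a spatially contiguous ROI — the
round(f·N) voxels closest to the grid centre in an ellipsoid metric
following the grid aspect ratio, f = 0.4 by default, reading the ambiguous
"surrounding 1.5× the ROI" as shell = 1.5×ROI (total 2.5×; f is a
parameter, not a guess baked in); (ii) connectional fingerprints —
independent Poisson counts with mean `rate_high` = 20 on a class-specific
signature set of 6 ROIs and `rate_low` = 1 elsewhere (Poisson, not
Gaussian, to preserve the non-negative integer nature of fibre counts);
(iii) an adjacency of 6-neighbourhood lattice edges kept with probability
0.9 (local tractography) plus sparse long-range edges, within-class with
probability 0.01 per pair and across classes 0.002 (shared fibre bundles
are mostly class-assortative). A `noise_swap` fraction of voxels draws its
profile from the wrong class (difficulty control, 0 by default). Voxel
pitch is 1.25 mm, the HCP DWI resolution. Defaults follow the study design
of a 12×12×10 target region (N = 1440) and 68 atlas ROIs; rates and edge
probabilities were fixed once, on the grounds above, to give strongly
separable fingerprints.

In a multi-region dataset the signature sets are disjoint across *all*
regions and classes (5 regions × 2 classes × 6 ≤ 68). This is the property
that makes leave-one-region-out meaningful: a classifier cannot transfer by
memorising feature columns, because the held-out region's fingerprint
occupies columns that were background in every training region. What *does*
transfer is structure the encoder can expose — neighbourhood composition,
degree profile, and the geometry of local and long-range edges relative to
the blob. Raw profiles accordingly transfer at chance-like Dice (~0.45)
while the spatial encoder's embeddings reach ~0.96; the GCN ablation,
lacking coordinates, is unstable across seeds (mean ~0.67). The generator
does *not* emulate realistic cortical geometry, streamline-level noise,
inter-subject variability, or distance-dependent connection probabilities —
passing tests show the pipeline recovers the structure it assumes, not that
it parcellates real cortex.

## Determinism and problem sizes

Every random draw flows from explicit integer seeds (NumPy `SeedSequence`
streams: data, encoder init, view sampling, classifier). Rerunning any CLI
stage with the same config and seed reproduces loss traces and Dice values
bitwise. The end-to-end test and acceptance runs use the default study
scale (5 regions × 1440 voxels, 200 Stage-I epochs, ~10⁴ edges per graph);
unit and property tests use 4–400-node graphs where oracles (triple-loop
aggregation, term-by-term InfoNCE, finite differences) are exact and cheap.

## Known limitations

- No GPU path; the numpy implementation targets ~10³–10⁴-voxel regions
  (the scale of single cortical target regions), not whole-brain graphs.
- The feature transform normalises per region; cross-region intensity
  harmonisation beyond that is out of scope.
- `sample_view` masking zeroes columns; it never imputes, so a masked view
  of a sparse profile can be all-zero for some voxel — the cosine of a zero
  vector is defined as 0 and logged.
- The NIfTI export writes a plain label volume and requires an affine
  supplied by the caller; no header provenance is carried.
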