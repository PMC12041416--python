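# Methods

## Problem setting

Given spot-level counts Y ∈ ℕ^{N×G} and coordinates C ∈ ℝ^{N×2} from a
spatial transcriptomics slide, the package learns an embedding H ∈ ℝ^{N×d}
whose clusters correspond to spatially contiguous, transcriptionally
coherent domains. The model assumes (i) counts are zero-inflated negative
binomial, (ii) adjacent spots tend to share domain identity, and (iii)
expression-similar spots can share identity even when distant.

## Preprocessing

Off-tissue spots are removed, then genes are ranked by the Seurat-style
normalized dispersion: counts are library-size scaled to 10 000 per spot,
per-gene dispersion var/mean is log-transformed and z-scored within 20 bins
of log1p(mean). The top `n_top` genes (default 3000) are kept; ties break
toward the lower gene index so selection is deterministic. Rows are then
scaled to 10 000 and, by default, log1p-transformed before entering the
encoder. Whether to log-transform after scaling is genuinely open; we apply
it by default (`log1p=False` disables it) because GCN layers behave better
on variance-stabilized inputs, while the ZINB decoder always receives the
*raw* HVG counts — a count likelihood is meaningless on normalized data.
Zero-count spots are dropped, not imputed.

## Graphs

* Spatial: edge (i, j) iff ‖c_i − c_j‖ ≤ r. Radii are platform presets:
  560 for DLPFC-style Visium pixel coordinates, 15 for most other platforms,
  and 1.5 (queen neighbourhood) for the unit-spaced synthetic grids used
  here. Coordinates are used as given; no rescaling.
* Feature: cosine similarity ranks k = 15 nearest neighbours per spot
  (stable sort, lower index wins ties; zero-norm rows score −1); the
  directed relation is symmetrized by union and stored binary. Cosine is
  used for *ranking* only — the stored matrix is binary by definition.
* Adaptive: each view's base pattern plus self-loops carries one free
  weight per entry, initialized to 1.0. Weights are free parameters (not
  recomputed from features), unconstrained in sign by default
  (`adaptive_nonneg` clamps them through ReLU). The two views' adaptive
  matrices are independent. Self-loops are included so the model can
  rescale the Ã diagonal.

## Encoder

Per branch, layers follow
`H(l+1) = act( A_adapt ⊙ D̃^{-1/2} Ã D̃^{-1/2} H(l) W(l) )` with Ã = A + I
and D̃ its degree matrix. The adaptive factor enters as a Hadamard product
over the stored pattern (default): since the adaptive matrix is defined on
exactly the adjacency's non-zero positions, elementwise reweighting
preserves that pattern, whereas a matrix product would densify it; the
latter reading remains available as `adaptive_mode="matmul"`. Depth and
widths default to two layers, G → 128 → 64. Hidden layers use ReLU; the
final layer of each branch is linear (`last_activation` switches this) so
embeddings are not confined to the non-negative orthant. No dropout or
batch-norm by default.

The joint branch shares one weight stack across both graphs (no adaptive
factor) producing H_sj and H_fj; H_j is their mean. The consistency loss is
the squared Frobenius distance between the N×N Gram matrices of the
row-L2-normalized H_sj and H_fj — normalization makes each Gram entry a
cosine similarity, bounded and scale-free; the spot-level (N×N) Gram is
used because the constraint targets spot-similarity structure.

## Fusion

Attention: one shared projection (d → d_att, default 64), one shared query
vector; score e_iv = qᵀ tanh(W h_iv + b), softmax across the three views
per spot (per-spot granularity by default; `attention_granularity="global"`
averages scores over spots first), then a single linear layer F (d → d,
dimension preserved). Learnable fusion: tanh(c_j)·H_j + tanh(c_s)·H_s +
tanh(c_f)·H_f with c initialized at 0.5 (tanh ≈ 0.46, a near-equal
symmetric start). The final embedding is the mean of the two fusions.

## ZINB decoder and losses

One shared hidden layer (d → 128, ReLU) feeds three linear heads with μ =
exp(·), θ = softplus(·) floored at 1e-4 and capped at 1e4 (log-gamma
stability), π = σ(·). The reconstruction loss is the mean negative ZINB
log-likelihood over all N×M entries plus λ·mean(π²), λ = 1 by default
(order-of-magnitude comparable to a per-entry NLL); `loss_reduction="sum"`
gives the summed variant. Dispersion is per spot×gene. Zeros are handled
with log-sum-exp, so the likelihood is exact and stable for π → {0, 1}.
The decoder target is raw counts, never normalized expression.

The spatial regularizer scores cosine similarities S of the *current*
embedding (no stop-gradient):
`L_reg = −½ [ mean_{(i,j)∈G_nei} log σ(S_ij) + mean_{(i,j)∈G_neg} log(1−σ(S_ij)) ]`
with G_nei the spatial edges and G_neg uniform non-adjacent pairs,
|G_neg| = |G_nei|, re-sampled every epoch from a seeded generator —
balancing the two mean terms. Both normalizing factors are means, as
written.

Total: L = α·L_ZINB + β·L_con + γ·L_reg with α = 1, β = 10, γ = 0.1.

## Training

Full-batch Adam, learning rate 1e-3, weight decay 1e-4, 600 epochs, no
early stopping by default (`patience` enables it). All parameters — encoder
stacks, both adaptive value vectors, attention head, fusion scalars,
decoder — are optimized jointly. Every random draw (initialization,
negative sampling) derives from a single seed, so runs are bitwise
reproducible on one machine. A non-finite loss aborts with the epoch index
and per-component values. Gradients are computed by the in-package
reverse-mode autodiff engine (`_autodiff.py`), verified against central
finite differences in the test suite; sparse propagation uses a fixed
pattern, with per-entry gradients gathered from the dense downstream
gradient.

Full-batch dense Gram matrices put a practical ceiling around a few tens of
thousands of spots, which covers single Visium/Stereo-seq slides.

## Clustering and metrics

Default clusterer: full-covariance Gaussian mixture with fixed seed and
user-supplied k (k-means as fallback); no spatial label-refinement
post-processing. Agreement metrics (ARI, NMI, homogeneity, completeness,
V-measure) come from scikit-learn's contingency-table implementations; the
tests cross-check ARI against an O(N²) pair-counting oracle and assert the
V = harmonic(HS, CS) identity. The ZINB mean matrix μ is exposed as the
denoised expression.

## Synthetic slides

The generator emulates a sequencing-based ST slide: spots on a unit-spaced
square grid, K spatially contiguous domains (horizontal bands by default;
seeded Voronoi patches for irregular boundaries), disjoint blocks of marker
genes per domain, NB counts thinned by independent dropout. Defaults —
30×30 grid, K = 3, 200 genes, 10 markers per domain, base mean 1.0, marker
fold change 3.0, dispersion θ = 0.5, dropout π = 0.3 — were chosen once as
a realistic Visium-like regime: ≈70 % zeros, strong overdispersion
(θ < 1), and a marker effect moderate enough that expression alone ranks
spots poorly while the spatial structure remains recoverable. What the
simulation does *not* model: platform spot geometry (hexagonal packing),
cell-type mixtures within spots, gene–gene correlation beyond domain
means, spatially smooth baseline gradients, and histology covariates.
Passing the recovery test therefore shows the pipeline extracts planted
spatial-expression structure under realistic sparsity — not that it matches
annotation-level accuracy on real tissue.

Problem sizes in the tests and the acceptance script (900 spots, 200 genes,
600 epochs) are the package's standard demonstration scale; preprocessing,
graph construction and training complete in a few minutes on one CPU.

## Known limitations

* Full-batch only; no mini-batching, no GPU.
* Single slide; no cross-slice integration or image features.
* The consistency loss is O(N²) memory in dense form.
* Attention is single-head; no gating or multi-head variants.
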