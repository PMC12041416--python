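# mvgst — multi-view graph convolutional spatial-domain identification

`mvgst` identifies **spatial domains** — spatially contiguous tissue regions
with coherent gene-expression identity, such as cortical layers — from
spatial transcriptomics (ST) data: a spot × gene count matrix plus 2-D spot
coordinates, as produced by 10x Visium and similar platforms. It is aimed at
computational biologists who want an unsupervised embedding of an ST slide
that respects both expression similarity and tissue geometry, with the usual
downstream steps (clustering, scoring against annotations, expression
denoising) built in.

## The model

Two binary graphs are built over the N spots: a **spatial graph** A^s
(spots within radius *r* of each other) and a **feature graph** A^f
(cosine-similarity k-nearest neighbours of the normalized expression rows,
k = 15). Each gets an **adaptive adjacency**: one free weight per stored
edge (plus self-loops), initialized at 1 and updated by gradient descent, so
the graph structure itself is learned on a fixed sparsity pattern.

A three-branch GCN encodes the normalized HVG expression X:

* spatial and feature branches propagate with
  `H(l+1) = ReLU( A_adapt ⊙ D̃^{-1/2} Ã D̃^{-1/2} H(l) W(l) )`, `Ã = A + I`,
  giving view embeddings H_s and H_f;
* a **joint branch** shares one weight stack between both graphs using the
  plain normalized rule, giving H_sj and H_fj with joint embedding
  `H_j = (H_sj + H_fj)/2`, pulled together by a consistency loss
  `L_con = ‖ H̃_sj H̃_sjᵀ − H̃_fj H̃_fjᵀ ‖²` on row-normalized Gram matrices.

The three views are fused twice — by a shared-query attention head
(per-spot softmax coefficients over views) and by a tanh-squashed learnable
weighted sum — and averaged into the final embedding H. A **ZINB decoder**
reconstructs the raw HVG counts from H through per-entry mean μ, dispersion
θ and zero-inflation π, trained by the negative ZINB log-likelihood with a
λ·mean(π²) penalty. A **spatial contrast** `L_reg` pushes cosine
similarities of adjacent spots up and of sampled non-adjacent pairs down.
The total objective is

```
L = α·L_ZINB + β·L_con + γ·L_reg,   α = 1, β = 10, γ = 0.1
```

optimized full-batch with Adam. Domains are obtained by Gaussian-mixture
(or k-means) clustering of H.

The trainable stack runs on a compact reverse-mode autodiff engine over
numpy (`mvgst/_autodiff.py`), keeping the package free of a deep-learning
framework dependency.

## Worked example

```python
from mvgst import (preprocess, build_spatial_adjacency, build_feature_adjacency,
                   train, cluster_embedding, score_clustering)
from mvgst.simulate import SMALL_CONFIG, simulate_slide
from mvgst.training import TrainConfig

cm, truth = simulate_slide(SMALL_CONFIG)     # 900 spots, 3 band domains, 200 genes
data = preprocess(cm)                        # filter -> HVG -> normalize (+log1p)
As = build_spatial_adjacency(data.coords, 1.5)   # queen adjacency on the unit grid
Af = build_feature_adjacency(data.X, 15)
result = train(data, As, Af, TrainConfig(radius=1.5))
pred = cluster_embedding(result.embedding, k=3, seed=0)
print(score_clustering(pred, truth))
print(score_clustering(cluster_embedding(data.X, k=3, seed=0), truth))
```

prints (last total loss 1.489 after 600 epochs):

```
{'ARI': 0.9376, 'NMI': 0.8997, 'HS': 0.8995, 'CS': 0.8998, 'V': 0.8997}
{'ARI': 0.0475, 'NMI': 0.0430, 'HS': 0.0428, 'CS': 0.0431, 'V': 0.0430}
```

First line: clustering the trained embedding recovers the three planted
domains almost perfectly (ARI 0.94). Second line: the same clusterer on the
raw normalized expression barely beats chance (ARI 0.05) — on this sparse,
overdispersed slide the spatial structure carries the signal, and the model
extracts it.

The same workflow is available from the shell:

```bash
mvgst simulate slide/ --seed 0
mvgst preprocess slide/ processed.h5ad
mvgst train processed.h5ad run/ --radius 1.5 --epochs 600 --seed 0
mvgst cluster-eval run/embedding.csv eval/ --k 3 --truth-csv slide/labels.csv
```

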