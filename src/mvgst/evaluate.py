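"""Clustering of the learned embedding and agreement scoring.

Domains are obtained by fitting a full-covariance Gaussian mixture (default)
or k-means to the embedding rows; agreement with reference labels is scored
with the five standard contingency-table metrics: ARI, NMI, homogeneity,
completeness and V-measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skm
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture


@dataclass
class DomainLabels:
    labels: np.ndarray  # (N,) ints in [0, K)
    K: int
    spot_ids: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.K):
            raise ValueError("labels out of range [0, K)")


def cluster_embedding(H: np.ndarray, k: int, method: str = "gmm",
                      seed: int = 0, spot_ids=None) -> DomainLabels:
    """Partition embedding rows into k domains (deterministic given seed)."""
    H = np.asarray(H, dtype=float)
    n = len(H)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if k == 1:
        return DomainLabels(labels=np.zeros(n, dtype=int), K=1, spot_ids=spot_ids)
    n_distinct = len(np.unique(H, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct embedding rows")
    if method == "gmm":
        model = GaussianMixture(n_components=k, covariance_type="full",
                                random_state=seed, n_init=1, max_iter=300)
        labels = model.fit_predict(H)
    elif method == "kmeans":
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(H)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return DomainLabels(labels=labels, K=k, spot_ids=spot_ids)


def score_clustering(pred: DomainLabels, truth: DomainLabels) -> dict[str, float]:
    """ARI, NMI, homogeneity, completeness and V-measure of pred vs truth."""
    if len(pred.labels) != len(truth.labels):
        raise ValueError("prediction and reference label lengths differ")
    t, p = truth.labels, pred.labels
    hs, cs, v = skm.homogeneity_completeness_v_measure(t, p)
    return {
        "ARI": float(skm.adjusted_rand_score(t, p)),
        "NMI": float(skm.normalized_mutual_info_score(t, p)),
        "HS": float(hs),
        "CS": float(cs),
        "V": float(v),
    }


def reconstruct_expression(model, data) -> np.ndarray:
    """Denoised expression: the ZINB mean matrix μ of the trained decoder."""
    return model.reconstruct(data.X)
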