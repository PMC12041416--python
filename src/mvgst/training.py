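"""Spatial regularization, total objective and the full-batch training loop.

The total objective is

    L = α·L_ZINB + β·L_con + γ·L_reg,      α=1, β=10, γ=0.1 by default,

jointly optimized (Adam, full batch) over the three-branch encoder, the two
adaptive adjacencies, both fusion strategies and the ZINB decoder.  The
spatial regularizer is a logistic contrast on embedding cosine similarities:
adjacent spot pairs are pushed toward similarity, a freshly sampled set of
non-adjacent pairs per epoch is pushed apart.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _autodiff as ag
from ._autodiff import Adam, Tensor
from .encoder import MultiViewEncoder, ViewEmbeddings, consistency_loss
from .fusion import AttentionHead, FusionWeights, attention_fuse, final_embed, learnable_fuse
from .graphs import AdaptiveAdjacency, SparseAdjacency, init_adaptive
from .preprocess import ProcessedData
from .zinb import ZINBDecoder, zinb_loss


@dataclass
class TrainConfig:
    """Hyperparameters of the full model; defaults are the package defaults."""

    alpha: float = 1.0  # ZINB reconstruction weight
    beta: float = 10.0  # consistency weight
    gamma: float = 0.1  # spatial regularization weight
    lambda_pi: float = 1.0  # zero-inflation penalty inside the ZINB loss
    epochs: int = 600
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    seed: int = 0
    hidden_dim: int = 128
    embed_dim: int = 64
    att_dim: int = 64
    decoder_hidden: int = 128
    k_neighbors: int = 15
    radius: float = 15.0
    log1p: bool = True
    adaptive_mode: str = "hadamard"  # or "matmul"
    adaptive_nonneg: bool = False
    last_activation: str = "linear"
    attention_granularity: str = "spot"  # or "global"
    loss_reduction: str = "mean"  # ZINB aggregation: "mean" or "sum"
    n_negatives: int | None = None  # default: one per positive pair
    patience: int | None = None  # early stop on total loss; None = off

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def spatial_reg_loss(H, pos_pairs: np.ndarray, neg_pairs: np.ndarray):
    """-½ [ mean log σ(S_ij) over neighbours + mean log(1-σ(S_ij)) over non-neighbours ].

    S_ij is the cosine similarity of embedding rows i and j; σ the logistic
    function.  Bounded below by -log σ(1) ≈ 0.3133 since S ∈ [-1, 1].
    """
    pos_pairs = np.asarray(pos_pairs, dtype=np.intp).reshape(-1, 2)
    neg_pairs = np.asarray(neg_pairs, dtype=np.intp).reshape(-1, 2)
    if len(pos_pairs) == 0 or len(neg_pairs) == 0:
        raise ValueError("both neighbour and non-neighbour pair sets must be non-empty")
    Hn = ag.row_normalize(ag.as_tensor(H))

    def cos(pairs):
        a = ag.take_rows(Hn, pairs[:, 0])
        b = ag.take_rows(Hn, pairs[:, 1])
        return ag.tsum(ag.mul(a, b), axis=1)

    pos_term = ag.tmean(ag.logsigmoid(cos(pos_pairs)))
    neg_term = ag.tmean(ag.logsigmoid(ag.mul(cos(neg_pairs), -1.0)))
    out = ag.mul(ag.add(pos_term, neg_term), -0.5)
    return out if isinstance(H, Tensor) else out.data


def sample_negative_pairs(adj: SparseAdjacency, n_samples: int,
                          seed_or_rng) -> np.ndarray:
    """Uniform non-adjacent (i, j), i != j pairs; reproducible given the seed."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    n = adj.n
    if adj.n_undirected >= n * (n - 1) // 2:
        raise ValueError("graph is complete; no non-adjacent pairs exist")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    forbidden = adj.edge_set()
    out: list[tuple[int, int]] = []
    while len(out) < n_samples:
        batch = rng.integers(0, n, size=(max(4 * n_samples, 64), 2))
        for i, j in batch:
            if i != j and (int(i), int(j)) not in forbidden:
                out.append((int(i), int(j)))
                if len(out) == n_samples:
                    break
    return np.asarray(out, dtype=np.intp)


def total_loss(l_zinb, l_con, l_reg, cfg: TrainConfig):
    """α·L_ZINB + β·L_con + γ·L_reg."""
    out = ag.add(
        ag.add(ag.mul(ag.as_tensor(l_zinb), cfg.alpha),
               ag.mul(ag.as_tensor(l_con), cfg.beta)),
        ag.mul(ag.as_tensor(l_reg), cfg.gamma),
    )
    if any(isinstance(x, Tensor) for x in (l_zinb, l_con, l_reg)):
        return out
    return float(out.data)


class SpatialDomainModel:
    """Encoder + adaptive adjacencies + two-strategy fusion + ZINB decoder."""

    def __init__(self, n_genes: int, cfg: TrainConfig, As: SparseAdjacency,
                 Af: SparseAdjacency, rng: np.random.Generator):
        dims = [n_genes, cfg.hidden_dim, cfg.embed_dim]
        self.cfg = cfg
        self.encoder = MultiViewEncoder(dims, rng,
                                        last_activation=cfg.last_activation,
                                        adaptive_mode=cfg.adaptive_mode)
        self.adapt_s = init_adaptive(As, nonneg=cfg.adaptive_nonneg)
        self.adapt_f = init_adaptive(Af, nonneg=cfg.adaptive_nonneg)
        self.attention = AttentionHead(cfg.embed_dim, cfg.att_dim, rng,
                                       granularity=cfg.attention_granularity)
        self.fusion_weights = FusionWeights.init()
        self.decoder = ZINBDecoder(cfg.embed_dim, n_genes, rng,
                                   hidden=cfg.decoder_hidden)
        self.As, self.Af = As, Af

    @property
    def params(self) -> list[Tensor]:
        return [
            *self.encoder.params,
            self.adapt_s.values,
            self.adapt_f.values,
            *self.attention.params,
            *self.fusion_weights.params,
            *self.decoder.params,
        ]

    def forward(self, X):
        views = self.encoder.forward(X, self.As, self.Af, self.adapt_s, self.adapt_f)
        H_att, coeffs = attention_fuse(views.Hj, views.Hs, views.Hf, self.attention)
        H_learn = learnable_fuse(views.Hj, views.Hs, views.Hf, self.fusion_weights)
        H = final_embed(H_att, H_learn)
        return H, views, coeffs

    def embed(self, X) -> np.ndarray:
        return self.forward(X)[0].data.copy()

    def reconstruct(self, X) -> np.ndarray:
        """ZINB mean matrix μ: the denoised expression."""
        H, _, _ = self.forward(X)
        return self.decoder.forward(H).mu.data.copy()

    # -- checkpointing ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        np.savez(path, **{f"p{i}": p.data for i, p in enumerate(self.params)})

    def load(self, path: str | Path) -> None:
        with np.load(path) as archive:
            for i, p in enumerate(self.params):
                p.data[...] = archive[f"p{i}"]


@dataclass
class TrainResult:
    embedding: np.ndarray  # (N, d) final fused embedding
    model: SpatialDomainModel
    trace: pd.DataFrame  # per-epoch total/zinb/consistency/spatial losses
    attention: np.ndarray  # (N, 3) final attention coefficients
    config: TrainConfig = field(repr=False)


def train(data: ProcessedData, As: SparseAdjacency, Af: SparseAdjacency,
          cfg: TrainConfig | None = None) -> TrainResult:
    """Full-batch joint training; all randomness derives from ``cfg.seed``."""
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    model = SpatialDomainModel(data.n_genes, cfg, As, Af, rng)
    opt = Adam(model.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    X = data.X
    counts = data.counts
    pos_pairs = As.edges[As.edges[:, 0] < As.edges[:, 1]]
    if len(pos_pairs) == 0:
        raise ValueError("spatial graph has no edges; increase the radius")
    n_neg = cfg.n_negatives or len(pos_pairs)
    neg_rng = np.random.default_rng(rng.integers(0, 2**31))

    records = []
    best, stall = np.inf, 0
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        H, views, _ = model.forward(X)
        params_zinb = model.decoder.forward(H)
        l_zinb = zinb_loss(counts, params_zinb, lambda_pi=cfg.lambda_pi,
                           reduction=cfg.loss_reduction)
        l_con = consistency_loss(views.Hsj, views.Hfj)
        neg_pairs = sample_negative_pairs(As, n_neg, neg_rng)
        l_reg = spatial_reg_loss(H, pos_pairs, neg_pairs)
        loss = total_loss(l_zinb, l_con, l_reg, cfg)
        components = {"total": float(loss.data), "zinb": float(l_zinb.data),
                      "consistency": float(l_con.data), "spatial": float(l_reg.data)}
        if not np.isfinite(components["total"]):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: {components}"
            )
        records.append({"epoch": epoch, **components})
        loss.backward()
        opt.step()
        if cfg.patience is not None:
            if components["total"] < best - 1e-9:
                best, stall = components["total"], 0
            else:
                stall += 1
                if stall > cfg.patience:
                    break

    H, _, coeffs = model.forward(X)
    return TrainResult(embedding=H.data.copy(), model=model,
                       trace=pd.DataFrame(records), attention=coeffs, config=cfg)
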