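"""Two-strategy fusion of the joint, spatial and feature embeddings.

Strategy one is a shared attention head: each view's rows pass through one
shared projection, a shared query vector scores them, and a per-spot softmax
over the three views yields attention coefficients; the weighted sum goes
through a single linear output layer F.  Strategy two is a weighted sum with
three free scalars squashed through tanh.  The final embedding is the mean
of the two fused representations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ag
from ._autodiff import Tensor


class AttentionHead:
    """Shared projection + shared query + single linear output layer.

    Per spot i and view v the score is ``e_iv = q . tanh(W h_iv + b)``;
    coefficients are softmax(e_i) across the three views.  With
    ``granularity='global'`` the scores are averaged over spots first, giving
    one coefficient triple for the whole slide.
    """

    def __init__(self, d: int, d_att: int, rng: np.random.Generator,
                 granularity: str = "spot"):
        if granularity not in ("spot", "global"):
            raise ValueError("granularity must be 'spot' or 'global'")
        self.granularity = granularity
        self.proj = ag.glorot(rng, d, d_att)
        self.bias = Tensor(np.zeros(d_att), requires_grad=True)
        self.query = ag.glorot(rng, d_att, 1)
        self.out_W = ag.glorot(rng, d, d)
        self.out_b = Tensor(np.zeros(d), requires_grad=True)

    @property
    def params(self) -> list[Tensor]:
        return [self.proj, self.bias, self.query, self.out_W, self.out_b]

    def _score(self, H):
        # (N, 1) attention logit for one view
        e = ag.matmul(ag.tanh(ag.add(ag.matmul(H, self.proj), self.bias)), self.query)
        if self.granularity == "global":
            e = ag.tmean(e, axis=0, keepdims=True)
        return e


def attention_fuse(Hj, Hs, Hf, head: AttentionHead):
    """Softmax-weighted combination of the three views through F.

    Returns (fused N x d tensor, coefficients N x 3 ndarray in view order
    joint/spatial/feature).  Coefficients are non-negative and sum to one per
    spot by construction.
    """
    Hj, Hs, Hf = map(ag.as_tensor, (Hj, Hs, Hf))
    ej, es, ef = head._score(Hj), head._score(Hs), head._score(Hf)
    m = ag.maximum(ag.maximum(ej, es), ef)
    wj = ag.exp(ag.add(ej, ag.mul(m, -1.0)))
    ws = ag.exp(ag.add(es, ag.mul(m, -1.0)))
    wf = ag.exp(ag.add(ef, ag.mul(m, -1.0)))
    Z = ag.add(ag.add(wj, ws), wf)
    aj, a_s, af = ag.div(wj, Z), ag.div(ws, Z), ag.div(wf, Z)
    mix = ag.add(ag.add(ag.mul(aj, Hj), ag.mul(a_s, Hs)), ag.mul(af, Hf))
    fused = ag.add(ag.matmul(mix, head.out_W), head.out_b)
    n = Hj.data.shape[0]
    coeffs = np.concatenate(
        [np.broadcast_to(a.data, (n, 1)) for a in (aj, a_s, af)], axis=1
    )
    return fused, coeffs


@dataclass
class FusionWeights:
    """Three unconstrained scalars; effective weights are tanh(c) in (-1, 1)."""

    cj: Tensor
    cs: Tensor
    cf: Tensor

    @classmethod
    def init(cls, value: float = 0.5) -> "FusionWeights":
        # symmetric start: tanh(0.5) ~ 0.46 for every view
        return cls(*(Tensor(np.array(value), requires_grad=True) for _ in range(3)))

    @property
    def params(self) -> list[Tensor]:
        return [self.cj, self.cs, self.cf]


def learnable_fuse(Hj, Hs, Hf, w: FusionWeights):
    """tanh(cj)*Hj + tanh(cs)*Hs + tanh(cf)*Hf."""
    return ag.add(
        ag.add(ag.mul(ag.tanh(w.cj), Hj), ag.mul(ag.tanh(w.cs), Hs)),
        ag.mul(ag.tanh(w.cf), Hf),
    )


def final_embed(H_attention, H_learnable):
    """Final embedding: mean of the two fusion strategies."""
    return ag.mul(ag.add(H_attention, H_learnable), 0.5)
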