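"""Three-branch multi-view GCN encoder.

The spatial and feature branches propagate over their own adaptive
adjacencies, each layer applying

    H(l+1) = act( Aadapt ⊙ D̃^{-1/2} Ã D̃^{-1/2} · H(l) · W(l) ),    Ã = A + I,

where the adaptive reweighting is an elementwise (Hadamard) product over the
stored sparsity pattern by default (a true sparse matrix product is available
as ``adaptive_mode='matmul'``).  The joint branch runs the standard
normalized propagation rule with a single weight stack shared between the
spatial and the feature graph, producing Hsj and Hfj whose average is the
joint embedding Hj; a consistency penalty pulls their row-cosine Gram
matrices together.

Hidden layers use ReLU; the last layer of every branch is linear by default
so embeddings are not constrained to the non-negative orthant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ag
from ._autodiff import Tensor
from .graphs import AdaptiveAdjacency, SparseAdjacency, normalized_adjacency


def gcn_propagate(
    H,
    A: SparseAdjacency,
    adapt: AdaptiveAdjacency | None,
    W,
    activation: str = "relu",
    adaptive_mode: str = "hadamard",
):
    """One propagation step; ``adapt=None`` gives the plain normalized rule."""
    rows, cols, anorm = normalized_adjacency(A)
    shape = (A.n, A.n)
    if adapt is None:
        out = ag.spmm(anorm, rows, cols, shape, H)
    elif adaptive_mode == "hadamard":
        if len(adapt.rows) != len(rows):
            raise ValueError("adaptive pattern does not match the adjacency pattern")
        out = ag.spmm(ag.mul(adapt.weight_values(), anorm), rows, cols, shape, H)
    elif adaptive_mode == "matmul":
        out = ag.spmm(anorm, rows, cols, shape, H)
        out = ag.spmm(adapt.weight_values(), adapt.rows, adapt.cols, shape, out)
    else:
        raise ValueError(f"unknown adaptive_mode {adaptive_mode!r}")
    out = ag.matmul(out, W)
    if activation == "relu":
        out = ag.relu(out)
    elif activation != "linear":
        raise ValueError(f"unknown activation {activation!r}")
    return out


def joint_propagate(H, A: SparseAdjacency, W, activation: str = "relu"):
    """Parameter-shared propagation: the same W serves both graphs."""
    return gcn_propagate(H, A, None, W, activation=activation)


def joint_embed(Hsj, Hfj):
    """Joint embedding = elementwise mean of the two shared-branch outputs."""
    return ag.mul(ag.add(Hsj, Hfj), 0.5)


def consistency_loss(Hsj, Hfj):
    """Squared Frobenius distance of the row-cosine Gram matrices.

    Rows are L2-normalized first, so each Gram entry is a cosine similarity
    between two spots and the loss is scale-free; zero iff the two views
    induce identical spot-spot similarity structure.
    """
    Hs_n = ag.row_normalize(ag.as_tensor(Hsj))
    Hf_n = ag.row_normalize(ag.as_tensor(Hfj))
    Gs = ag.matmul(Hs_n, ag.transpose(Hs_n))
    Gf = ag.matmul(Hf_n, ag.transpose(Hf_n))
    return ag.tsum(ag.square(ag.add(Gs, ag.mul(Gf, -1.0))))


@dataclass
class ViewEmbeddings:
    """The five encoder outputs (all N x d)."""

    Hs: Tensor
    Hf: Tensor
    Hsj: Tensor
    Hfj: Tensor
    Hj: Tensor


class MultiViewEncoder:
    """Spatial, feature and joint GCN stacks with a common layer layout.

    Parameters
    ----------
    dims : sequence of int
        Layer widths from input genes to embedding, e.g. ``[M, 128, 64]``.
    rng : numpy Generator used for Glorot initialization.
    last_activation : 'linear' (default) or 'relu' for the final layer.
    adaptive_mode : how adaptive weights combine with the normalized matrix.
    """

    def __init__(self, dims, rng: np.random.Generator,
                 last_activation: str = "linear", adaptive_mode: str = "hadamard"):
        if len(dims) < 2:
            raise ValueError("need at least input and output dims")
        self.dims = list(dims)
        self.last_activation = last_activation
        self.adaptive_mode = adaptive_mode
        self.Ws = [ag.glorot(rng, a, b) for a, b in zip(dims, dims[1:])]
        self.Wf = [ag.glorot(rng, a, b) for a, b in zip(dims, dims[1:])]
        self.Wj = [ag.glorot(rng, a, b) for a, b in zip(dims, dims[1:])]

    @property
    def params(self) -> list[Tensor]:
        return [*self.Ws, *self.Wf, *self.Wj]

    def _run_stack(self, X, A, adapt, weights):
        H = ag.as_tensor(X)
        last = len(weights) - 1
        for layer, W in enumerate(weights):
            act = self.last_activation if layer == last else "relu"
            H = gcn_propagate(H, A, adapt, W, activation=act,
                              adaptive_mode=self.adaptive_mode)
        return H

    def forward(
        self,
        X,
        As: SparseAdjacency,
        Af: SparseAdjacency,
        adapt_s: AdaptiveAdjacency,
        adapt_f: AdaptiveAdjacency,
    ) -> ViewEmbeddings:
        Hs = self._run_stack(X, As, adapt_s, self.Ws)
        Hf = self._run_stack(X, Af, adapt_f, self.Wf)
        Hsj = self._run_stack(X, As, None, self.Wj)
        Hfj = self._run_stack(X, Af, None, self.Wj)
        return ViewEmbeddings(Hs=Hs, Hf=Hf, Hsj=Hsj, Hfj=Hfj,
                              Hj=joint_embed(Hsj, Hfj))
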