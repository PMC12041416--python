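"""Spatial and expression-similarity adjacency graphs, plus the adaptive
(learnable per-edge weight) adjacency bound to a fixed sparsity pattern.

The spatial graph connects spots whose Euclidean distance is within a
platform-dependent radius; the feature graph connects cosine-similarity
k-nearest neighbours of the normalized expression rows, symmetrized by union.
Both are binary.  The adaptive adjacency shares a base graph's pattern
(augmented with self-loops) and carries one trainable weight per stored
entry, initialized to 1 so that at initialization propagation reduces to the
standard symmetric-normalized GCN rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from ._autodiff import Tensor

#: Default neighbourhood radii in platform units; DLPFC-style Visium slides
#: use spot-pixel spacing where 560 captures the six hexagonal neighbours.
RADIUS_PRESETS = {"dlpfc": 560.0, "default": 15.0}
DEFAULT_K = 15


@dataclass
class SparseAdjacency:
    """Symmetric binary adjacency stored as an explicit directed edge list.

    ``edges`` holds BOTH (i, j) and (j, i) for every undirected edge and no
    self-loops; self-loops enter only at propagation time via A + I.
    """

    n: int
    edges: np.ndarray  # (E, 2) int
    values: np.ndarray = None  # (E,) float, binary for base graphs

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.intp).reshape(-1, 2)
        if self.values is None:
            self.values = np.ones(len(self.edges))
        self.values = np.asarray(self.values, dtype=float)
        if len(self.edges) and (self.edges.min() < 0 or self.edges.max() >= self.n):
            raise ValueError("edge indices out of range")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loops must not be stored explicitly")

    @property
    def n_undirected(self) -> int:
        return len(self.edges) // 2

    def degrees(self) -> np.ndarray:
        """Weighted degree of A (no self-loop)."""
        deg = np.zeros(self.n)
        np.add.at(deg, self.edges[:, 0], self.values)
        return deg

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def to_edge_list(self, path: str | Path) -> None:
        """Write a 3-column (i, j, weight) text file, 0-based."""
        with open(path, "w") as fh:
            for (i, j), w in zip(self.edges, self.values):
                fh.write(f"{i}\t{j}\t{w:g}\n")

    @classmethod
    def from_edge_list(cls, path: str | Path, n: int) -> "SparseAdjacency":
        data = np.loadtxt(path, ndmin=2)
        if data.size == 0:
            return cls(n=n, edges=np.empty((0, 2), dtype=np.intp))
        return cls(n=n, edges=data[:, :2].astype(np.intp), values=data[:, 2])


def _check_symmetry(edges: np.ndarray) -> None:
    fwd = {(int(i), int(j)) for i, j in edges}
    if any((j, i) not in fwd for i, j in fwd):
        raise ValueError("adjacency pattern is not symmetric")


def build_spatial_adjacency(coords: np.ndarray, radius: float) -> SparseAdjacency:
    """Connect spot pairs within ``radius`` (Euclidean, inclusive)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    pairs = cKDTree(coords).query_pairs(r=radius, output_type="ndarray")
    edges = np.concatenate([pairs, pairs[:, ::-1]], axis=0) if len(pairs) else np.empty((0, 2), dtype=np.intp)
    adj = SparseAdjacency(n=n, edges=edges)
    if n and (adj.degrees() == 0).any():
        warnings.warn(
            f"{int((adj.degrees() == 0).sum())} spot(s) have no spatial neighbour "
            f"within radius {radius}", stacklevel=2,
        )
    return adj


def build_feature_adjacency(X: np.ndarray, k: int = DEFAULT_K) -> SparseAdjacency:
    """k-nearest-neighbour graph under cosine similarity of expression rows.

    Cosine similarity ranks the neighbours; stored weights are binary.  The
    directed kNN relation is symmetrized by union.  Ties, including the fully
    degenerate identical-row case, break toward the lower spot index.  Rows
    with zero norm have undefined cosine similarity and are treated as
    similarity -1 to everything.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_spots (got k={k}, n={n})")
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} spot(s) have zero expression norm; "
            "their cosine similarity is undefined and treated as -1", stacklevel=2,
        )
    Xn = X / np.where(zero, 1.0, norms)[:, None]
    sim = Xn @ Xn.T
    sim[zero, :] = -1.0
    sim[:, zero] = -1.0
    np.fill_diagonal(sim, -np.inf)
    # stable argsort on -sim: among equal similarities the lower index wins
    order = np.argsort(-sim, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    directed = set(zip(rows.tolist(), order.ravel().tolist()))
    und = {(i, j) for i, j in directed} | {(j, i) for i, j in directed}
    edges = np.array(sorted(und), dtype=np.intp) if und else np.empty((0, 2), dtype=np.intp)
    return SparseAdjacency(n=n, edges=edges)


@dataclass
class AdaptiveAdjacency:
    """Trainable per-entry weights on a frozen pattern = base edges + loops."""

    n: int
    rows: np.ndarray  # (P,) pattern row indices (edges then self-loops)
    cols: np.ndarray  # (P,)
    values: Tensor = field(repr=False)  # (P,) trainable, init 1.0
    nonneg: bool = False

    def weight_values(self):
        """Values as used in propagation (optionally clamped to >= 0)."""
        if self.nonneg:
            from ._autodiff import relu

            return relu(self.values)
        return self.values


def init_adaptive(base: SparseAdjacency, nonneg: bool = False) -> AdaptiveAdjacency:
    """Adaptive weights over ``base``'s pattern plus self-loops, all 1.0."""
    _check_symmetry(base.edges)
    loops = np.arange(base.n, dtype=np.intp)
    rows = np.concatenate([base.edges[:, 0], loops])
    cols = np.concatenate([base.edges[:, 1], loops])
    values = Tensor(np.ones(len(rows)), requires_grad=True)
    return AdaptiveAdjacency(n=base.n, rows=rows, cols=cols, values=values, nonneg=nonneg)


def normalized_adjacency(adj: SparseAdjacency):
    """Pattern and values of D̃^{-1/2} Ã D̃^{-1/2} with Ã = A + I.

    Returns (rows, cols, values) with self-loop entries appended after the
    edge entries, in the same order `init_adaptive` lays out its pattern.
    """
    deg_tilde = adj.degrees() + 1.0
    inv_sqrt = 1.0 / np.sqrt(deg_tilde)
    loops = np.arange(adj.n, dtype=np.intp)
    rows = np.concatenate([adj.edges[:, 0], loops])
    cols = np.concatenate([adj.edges[:, 1], loops])
    vals = np.concatenate([adj.values, np.ones(adj.n)]) * inv_sqrt[rows] * inv_sqrt[cols]
    return rows, cols, vals
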