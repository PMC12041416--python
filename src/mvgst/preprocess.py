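"""Count-matrix preprocessing: tissue filtering, HVG selection, normalization.

Spots outside the tissue are removed first, then genes are ranked by a
Seurat-style mean-binned normalized dispersion and the top ``n_top`` retained,
and finally each spot's counts are scaled to a fixed library size of 10 000
(optionally followed by ``log1p``).  The raw highly-variable-gene counts are
kept alongside the normalized matrix because the reconstruction loss is a
count-likelihood and must see untransformed counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SCALE_FACTOR = 10_000.0
HVG_BINS = 20


@dataclass
class CountMatrix:
    """Spot-by-gene raw counts with planar spot coordinates."""

    counts: np.ndarray  # (N, M) non-negative integers
    coords: np.ndarray  # (N, 2)
    spot_ids: np.ndarray  # (N,) str
    gene_ids: np.ndarray  # (M,) str
    in_tissue: np.ndarray | None = None  # (N,) bool; None means all in tissue

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.coords = np.asarray(self.coords, dtype=float)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (spots x genes)")
        n, m = self.counts.shape
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords must be ({n}, 2), got {self.coords.shape}")
        if len(self.spot_ids) != n or len(self.gene_ids) != m:
            raise ValueError("spot_ids/gene_ids lengths do not match counts")
        if len(set(self.spot_ids)) != n:
            raise ValueError("duplicate spot_ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.in_tissue is not None:
            self.in_tissue = np.asarray(self.in_tissue, dtype=bool)
            if self.in_tissue.shape != (n,):
                raise ValueError("in_tissue length does not match counts")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_spots(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            counts=self.counts[idx],
            coords=self.coords[idx],
            spot_ids=self.spot_ids[idx],
            gene_ids=self.gene_ids,
            in_tissue=None if self.in_tissue is None else self.in_tissue[idx],
        )

    def subset_genes(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return replace(self, counts=self.counts[:, idx], gene_ids=self.gene_ids[idx])


@dataclass
class ExpressionMatrix:
    """Library-size-normalized (and optionally log1p) expression."""

    X: np.ndarray  # (N, M) non-negative reals
    gene_ids: np.ndarray
    spot_ids: np.ndarray
    log1p: bool = False


def filter_spots(cm: CountMatrix) -> CountMatrix:
    """Keep only spots flagged as inside the tissue (order preserved)."""
    if cm.in_tissue is None:
        return cm
    if not cm.in_tissue.any():
        raise ValueError("all spots are flagged off-tissue; nothing to analyze")
    out = cm.subset_spots(cm.in_tissue)
    out.in_tissue = np.ones(out.n_spots, dtype=bool)
    return out


def hvg_dispersion(counts: np.ndarray, n_bins: int = HVG_BINS) -> np.ndarray:
    """Mean-binned normalized dispersion per gene (Seurat flavour).

    Counts are library-size normalized to 10 000 per spot; per-gene dispersion
    var/mean is log-transformed and z-scored within ``n_bins`` bins of
    log1p(mean expression).  Genes with zero expression get dispersion -inf.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    X = counts / lib * SCALE_FACTOR
    n = X.shape[0]
    mean = X.mean(axis=0)
    if n > 1:
        var = X.var(axis=0, ddof=1)
    else:
        var = np.zeros_like(mean)
    safe_mean = np.where(mean == 0, 1e-12, mean)
    disp = var / safe_mean
    expressed = disp > 0
    if not expressed.any():
        return np.full(counts.shape[1], -np.inf)
    log_disp = np.where(expressed, np.log(np.where(expressed, disp, 1.0)), np.nan)
    log_mean = np.log1p(mean)

    df = pd.DataFrame({"mean": log_mean, "disp": log_disp})
    df["bin"] = pd.cut(df["mean"], bins=n_bins)
    grouped = df.groupby("bin", observed=True)["disp"]
    bin_mean = grouped.transform("mean")
    bin_std = grouped.transform("std")
    # singleton bins have undefined std: score those genes against the bin mean
    singleton = bin_std.isna() | (bin_std == 0)
    norm = (df["disp"] - np.where(singleton, 0.0, bin_mean)) / np.where(
        singleton, np.where(bin_mean.abs() > 0, bin_mean.abs(), 1.0), bin_std
    )
    out = norm.to_numpy()
    out[~expressed] = -np.inf
    return out


def select_hvg(cm: CountMatrix, n_top: int = 3000) -> CountMatrix:
    """Retain the ``n_top`` most highly variable genes.

    Ranking is by normalized dispersion, ties broken deterministically toward
    the lower gene index.  If no gene shows variance (degenerate input) genes
    are kept by total count instead, with a warning.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if cm.n_genes <= n_top:
        return cm
    stat = hvg_dispersion(cm.counts)
    if not np.any(np.isfinite(stat)):
        warnings.warn(
            "no gene has positive dispersion; ranking by total count instead",
            stacklevel=2,
        )
        stat = cm.counts.sum(axis=0).astype(float)
    # stable sort on (-stat, index): lower index wins ties
    order = np.lexsort((np.arange(cm.n_genes), -stat))
    keep = np.sort(order[:n_top])
    return cm.subset_genes(keep)


def normalize(cm: CountMatrix, log1p: bool = False) -> ExpressionMatrix:
    """Scale each spot's counts to sum to 10 000 (then optional log1p).

    Spots with zero total count are dropped with a warning; the returned
    matrix carries the surviving spot ids.
    """
    totals = cm.counts.sum(axis=1)
    nonzero = totals > 0
    if not nonzero.all():
        warnings.warn(
            f"dropping {int((~nonzero).sum())} spot(s) with zero total count",
            stacklevel=2,
        )
        cm = cm.subset_spots(nonzero)
        totals = totals[nonzero]
    if cm.n_spots == 0:
        raise ValueError("no spots with nonzero counts remain")
    X = cm.counts / totals[:, None] * SCALE_FACTOR
    if log1p:
        X = np.log1p(X)
    return ExpressionMatrix(X=X, gene_ids=cm.gene_ids, spot_ids=cm.spot_ids, log1p=log1p)


@dataclass
class ProcessedData:
    """Everything downstream modules need: encoder input + raw HVG counts."""

    X: np.ndarray  # (N, M) normalized (log1p by default) expression
    counts: np.ndarray  # (N, M) raw HVG counts, target of the ZINB decoder
    coords: np.ndarray  # (N, 2)
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    log1p: bool = True
    extras: dict = field(default_factory=dict)

    @property
    def n_spots(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]


def preprocess(cm: CountMatrix, n_top: int = 3000, log1p: bool = True) -> ProcessedData:
    """Full pipeline: tissue filter -> HVG selection -> normalization."""
    cm = filter_spots(cm)
    totals = cm.counts.sum(axis=1)
    if not (totals > 0).all():
        warnings.warn(
            f"dropping {int((totals == 0).sum())} zero-count spot(s)", stacklevel=2
        )
        cm = cm.subset_spots(totals > 0)
        if cm.n_spots == 0:
            raise ValueError("no spots with nonzero counts remain")
    cm = select_hvg(cm, n_top)
    # HVG subsetting may strand a spot with all-zero counts in the kept genes
    hvg_totals = cm.counts.sum(axis=1)
    if not (hvg_totals > 0).all():
        warnings.warn(
            f"dropping {int((hvg_totals == 0).sum())} spot(s) with no HVG counts",
            stacklevel=2,
        )
        cm = cm.subset_spots(hvg_totals > 0)
    em = normalize(cm, log1p=log1p)
    return ProcessedData(
        X=em.X,
        counts=np.asarray(cm.counts, dtype=float),
        coords=cm.coords,
        spot_ids=cm.spot_ids,
        gene_ids=cm.gene_ids,
        log1p=log1p,
    )
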