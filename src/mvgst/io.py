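"""Readers and writers for the formats the pipeline touches.

Supported inputs: a 10x Visium-style directory (MTX matrix + barcodes/features
TSV + tissue positions CSV), an AnnData ``.h5ad`` container with counts and a
``spatial`` coordinate slot, and a plain CSV pair (counts + coordinates).
Processed data round-trips through ``.h5ad``.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse as sp

from .preprocess import CountMatrix, ProcessedData


def _find(directory: Path, names: list[str]) -> Path | None:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    return None


def read_visium(path: str | Path) -> CountMatrix:
    """Read a Visium-style directory: MTX + features/barcodes + positions.

    The MTX matrix follows the 10x convention (rows = genes, columns =
    spots).  Tissue positions may be the headered ``tissue_positions.csv`` or
    the legacy header-less ``tissue_positions_list.csv``; pixel coordinates
    are used as spot coordinates.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    mtx = _find(directory, ["matrix.mtx", "matrix.mtx.gz"])
    feats = _find(directory, ["features.tsv", "features.tsv.gz", "genes.tsv", "genes.tsv.gz"])
    bars = _find(directory, ["barcodes.tsv", "barcodes.tsv.gz"])
    pos = _find(
        directory,
        [
            "tissue_positions.csv",
            "tissue_positions_list.csv",
            "spatial/tissue_positions.csv",
            "spatial/tissue_positions_list.csv",
        ],
    )
    missing = [n for n, p in [("matrix.mtx", mtx), ("features.tsv", feats),
                              ("barcodes.tsv", bars), ("tissue_positions", pos)] if p is None]
    if missing:
        raise FileNotFoundError(f"missing Visium files in {directory}: {', '.join(missing)}")

    mat = spio.mmread(str(mtx))
    counts = np.asarray(sp.csr_matrix(mat).T.todense())  # spots x genes

    def read_tsv(p: Path) -> pd.DataFrame:
        opener = gzip.open if p.suffix == ".gz" else open
        with opener(p, "rt") as fh:
            return pd.read_csv(fh, sep="\t", header=None)

    gene_ids = read_tsv(feats).iloc[:, 0].astype(str).to_numpy()
    barcodes = read_tsv(bars).iloc[:, 0].astype(str).to_numpy()

    first = pd.read_csv(pos, nrows=1, header=None)
    has_header = not str(first.iloc[0, 1]).lstrip("-").isdigit()
    positions = pd.read_csv(pos, header=0 if has_header else None)
    positions.columns = [
        "barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col",
    ][: positions.shape[1]]
    positions = positions.set_index("barcode").reindex(barcodes)
    if positions["in_tissue"].isna().any():
        raise ValueError("tissue positions file does not cover all barcodes")
    coords = positions[["pxl_row", "pxl_col"]].to_numpy(dtype=float)
    in_tissue = positions["in_tissue"].to_numpy(dtype=int).astype(bool)
    return CountMatrix(counts=counts, coords=coords, spot_ids=barcodes,
                       gene_ids=gene_ids, in_tissue=in_tissue)


def read_h5ad_counts(path: str | Path) -> CountMatrix:
    """Read counts + spatial coordinates from an AnnData container.

    Counts are taken from ``layers['counts']`` when present, else ``X``;
    coordinates from ``obsm['spatial']``.
    """
    adata = ad.read_h5ad(path)
    if "spatial" not in adata.obsm:
        raise ValueError(f"{path}: no obsm['spatial'] coordinate table")
    counts = adata.layers["counts"] if "counts" in adata.layers else adata.X
    if sp.issparse(counts):
        counts = np.asarray(counts.todense())
    counts = np.asarray(counts)
    in_tissue = None
    if "in_tissue" in adata.obs:
        in_tissue = adata.obs["in_tissue"].to_numpy().astype(bool)
    return CountMatrix(
        counts=counts,
        coords=np.asarray(adata.obsm["spatial"], dtype=float)[:, :2],
        spot_ids=adata.obs_names.to_numpy(),
        gene_ids=adata.var_names.to_numpy(),
        in_tissue=in_tissue,
    )


def read_csv_pair(counts_csv: str | Path, coords_csv: str | Path) -> CountMatrix:
    """Plain-CSV fallback: spots-x-genes counts and a spot coordinate table.

    The coordinates CSV needs columns (spot_id, x, y) and may carry an
    optional ``in_tissue`` column.
    """
    counts_df = pd.read_csv(counts_csv, index_col=0)
    coords_df = pd.read_csv(coords_csv)
    coords_df = coords_df.set_index(coords_df.columns[0]).reindex(counts_df.index)
    if coords_df.iloc[:, :2].isna().any().any():
        raise ValueError("coordinates CSV does not cover all spots in the counts CSV")
    in_tissue = None
    if "in_tissue" in coords_df.columns:
        in_tissue = coords_df["in_tissue"].to_numpy().astype(bool)
    return CountMatrix(
        counts=counts_df.to_numpy(),
        coords=coords_df.iloc[:, :2].to_numpy(dtype=float),
        spot_ids=counts_df.index.astype(str).to_numpy(),
        gene_ids=counts_df.columns.astype(str).to_numpy(),
        in_tissue=in_tissue,
    )


def load_input(path: str | Path) -> CountMatrix:
    """Dispatch on input type: directory -> Visium, .h5ad -> AnnData."""
    p = Path(path)
    if p.is_dir():
        return read_visium(p)
    if p.suffix == ".h5ad":
        return read_h5ad_counts(p)
    raise ValueError(f"cannot infer input format of {p}; pass a Visium directory or .h5ad")


def to_anndata(data: ProcessedData) -> ad.AnnData:
    adata = ad.AnnData(
        X=data.X.astype(np.float32),
        obs=pd.DataFrame(index=pd.Index(data.spot_ids.astype(str), name="spot_id")),
        var=pd.DataFrame(index=pd.Index(data.gene_ids.astype(str), name="gene_id")),
    )
    adata.layers["counts"] = data.counts.astype(np.float32)
    adata.obsm["spatial"] = data.coords
    adata.uns["log1p_applied"] = bool(data.log1p)
    for key, value in data.extras.items():
        adata.obsm[key] = value
    return adata


def write_processed(data: ProcessedData, path: str | Path) -> None:
    to_anndata(data).write_h5ad(path)


def read_processed(path: str | Path) -> ProcessedData:
    adata = ad.read_h5ad(path)
    if "counts" not in adata.layers or "spatial" not in adata.obsm:
        raise ValueError(f"{path} is not a processed container (missing counts/spatial)")
    X = adata.X
    if sp.issparse(X):
        X = np.asarray(X.todense())
    counts = adata.layers["counts"]
    if sp.issparse(counts):
        counts = np.asarray(counts.todense())
    return ProcessedData(
        X=np.asarray(X, dtype=float),
        counts=np.asarray(counts, dtype=float),
        coords=np.asarray(adata.obsm["spatial"], dtype=float),
        spot_ids=adata.obs_names.to_numpy(),
        gene_ids=adata.var_names.to_numpy(),
        log1p=bool(adata.uns.get("log1p_applied", True)),
    )


def read_labels_csv(path: str | Path) -> pd.Series:
    """Two-column (spot_id, label) CSV -> Series indexed by spot id."""
    df = pd.read_csv(path)
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))


def write_labels_csv(spot_ids, labels, path: str | Path) -> None:
    pd.DataFrame({"spot_id": spot_ids, "label": labels}).to_csv(path, index=False)
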