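"""Count-matrix I/O and preprocessing.

Cells x genes is the canonical orientation everywhere in the package; readers
transpose on ingest when the on-disk convention is genes x cells (e.g. 10x
MatrixMarket exports). Raw counts are kept alongside the processed matrix
because the ZINB reconstruction loss models raw counts with per-cell size
factors, while the encoders consume the normalized/log/scaled matrix.

Supported formats
-----------------
delimited
    TSV/CSV with a header row of gene ids and a first column of cell ids.
matrixmarket
    ``.mtx`` sparse triplet with ``barcodes`` / ``features`` sidecar files,
    genes x cells on disk (10x convention).
hdf5_container
    An ``.h5ad`` AnnData file, or a plain HDF5 file with datasets named
    ``matrix`` (cells x genes), ``obs_names`` and ``var_names``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._exceptions import InputError, ValidationError

__all__ = [
    "CountMatrix",
    "PreprocessConfig",
    "read_counts",
    "write_counts",
    "select_hvg",
    "normalize_counts",
    "preprocess",
]

Orientation = Literal["cells_by_genes", "genes_by_cells"]
Format = Literal["delimited", "matrixmarket", "hdf5_container"]


@dataclass
class CountMatrix:
    """A cells x genes expression matrix with identifiers.

    ``values`` holds raw non-negative integer counts before processing and
    real values after.  ``raw`` retains the (HVG-subset) raw counts once the
    matrix has been processed; ``size_factors`` appear after normalization
    (per-cell total / median total) and later scale the ZINB mean head.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    is_processed: bool = False
    size_factors: np.ndarray | None = None
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("count matrix must be two-dimensional")
        n, d = self.values.shape
        if n < 2 or d < 2:
            raise ValidationError(f"need at least 2 cells and 2 genes, got {n}x{d}")
        if len(self.cell_ids) != n or len(self.gene_ids) != d:
            raise ValidationError(
                f"id lengths ({len(self.cell_ids)}, {len(self.gene_ids)}) do not "
                f"match matrix shape {n}x{d}"
            )
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicated cell ids")
        if not self.is_processed:
            if np.any(self.values < 0):
                raise ValidationError("raw counts must be non-negative")
            if not np.allclose(self.values, np.round(self.values), atol=1e-6):
                raise ValidationError("raw counts must be integral")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def raw_values(self) -> np.ndarray:
        """Raw counts aligned with ``values`` (the matrix itself when raw)."""
        return self.values if not self.is_processed else self.raw

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class PreprocessConfig:
    """Switches for the standard preprocessing recipe.

    n_hvg : number of highly variable genes retained (M); 2000 keeps the
    strongest clustering signal on most datasets and is the default.
    """

    n_hvg: int = 2000
    normalize: bool = True
    log_transform: bool = True
    scale: bool = True

    def __post_init__(self) -> None:
        if self.n_hvg < 2:
            raise ValidationError("n_hvg must be >= 2")


def _dedupe(names: Sequence[str]) -> list[str]:
    """Disambiguate duplicate names by suffixing -1, -2, ..."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}-{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def _read_delimited(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    sep = "," if path.endswith(".csv") else None  # None: sniff whitespace/tab
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    return df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns]


def _read_matrixmarket(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    from scipy.io import mmread

    base = os.path.dirname(path) or "."
    sidecars = {}
    for kind, candidates in {
        "rows": ("features.tsv", "genes.tsv", "rows.tsv"),
        "cols": ("barcodes.tsv", "cols.tsv"),
    }.items():
        for cand in candidates:
            p = os.path.join(base, cand)
            if os.path.exists(p):
                sidecars[kind] = p
                break
        else:
            raise InputError(f"missing {candidates[0]} sidecar next to {path}")
    mat = np.asarray(mmread(path).todense(), dtype=float)
    rows = pd.read_csv(sidecars["rows"], sep="\t", header=None)[0].astype(str).tolist()
    cols = pd.read_csv(sidecars["cols"], sep="\t", header=None)[0].astype(str).tolist()
    if len(rows) != mat.shape[0] or len(cols) != mat.shape[1]:
        raise ValidationError(
            f"matrix shape {mat.shape} does not match sidecar lengths "
            f"({len(rows)} rows, {len(cols)} cols)"
        )
    return mat, rows, cols


def _read_hdf5(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    import h5py

    with h5py.File(path, "r") as f:
        if "matrix" in f and "obs_names" in f and "var_names" in f:
            mat = np.asarray(f["matrix"], dtype=float)
            obs = [s.decode() if isinstance(s, bytes) else str(s) for s in f["obs_names"][:]]
            var = [s.decode() if isinstance(s, bytes) else str(s) for s in f["var_names"][:]]
            return mat, obs, var
    # fall through to AnnData (.h5ad layout)
    import anndata as ad

    adata = ad.read_h5ad(path)
    x = adata.X
    if not isinstance(x, np.ndarray):
        x = np.asarray(x.todense())
    return np.asarray(x, dtype=float), adata.obs_names.astype(str).tolist(), adata.var_names.astype(str).tolist()


def read_counts(
    path: str,
    format: Format = "delimited",
    orientation: Orientation = "cells_by_genes",
) -> CountMatrix:
    """Read a raw count matrix, returning it in cells x genes orientation.

    ``orientation`` describes the on-disk layout; the returned matrix is
    always cells x genes.  Duplicate gene names are disambiguated by
    suffixing.
    """
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    readers = {
        "delimited": _read_delimited,
        "matrixmarket": _read_matrixmarket,
        "hdf5_container": _read_hdf5,
    }
    if format not in readers:
        raise ValidationError(f"unknown format {format!r}")
    mat, rows, cols = readers[format](path)
    if orientation == "genes_by_cells":
        mat = mat.T
        rows, cols = cols, rows
    if np.any(mat < 0):
        raise ValidationError("negative entries in count matrix")
    return CountMatrix(values=mat, cell_ids=[str(r) for r in rows], gene_ids=_dedupe(cols))


def write_counts(x: CountMatrix, path: str, sep: str = "\t") -> None:
    """Write a CountMatrix in the delimited layout ``read_counts`` accepts."""
    df = x.to_dataframe()
    if not x.is_processed:
        df = df.astype(int)
    df.to_csv(path, sep=sep)


def gene_dispersion(values: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean-binned normalized dispersion (variance/mean) per gene.

    Genes are binned by mean expression; each gene's dispersion is z-scored
    within its bin so that highly variable genes stand out at every
    expression level.  Zero-mean genes get dispersion -inf (never selected).
    """
    mean = values.mean(axis=0)
    var = values.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        # constant or silent genes can never be highly variable
        disp = np.where((mean > 0) & (var > 0), var / np.maximum(mean, 1e-12),
                        -np.inf)
    finite = np.isfinite(disp)
    norm = np.full_like(disp, -np.inf)
    if finite.sum() == 0:
        return norm
    # bin by mean rank so bins are equally populated
    order = np.argsort(mean[finite], kind="stable")
    ranks = np.empty(finite.sum())
    ranks[order] = np.arange(finite.sum())
    bins = np.minimum((ranks / max(len(ranks), 1) * n_bins).astype(int), n_bins - 1)
    d = disp[finite]
    out = np.empty_like(d)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = d[sel].mean(), d[sel].std()
        out[sel] = (d[sel] - mu) / (sd if sd > 0 else 1.0)
    norm[finite] = out
    return norm


def select_hvg(x: CountMatrix, m: int = 2000) -> CountMatrix:
    """Keep the min(m, d) most variable genes, in original gene order.

    Ranking is by mean-binned normalized dispersion; ties are broken
    lexicographically by gene id so the selection is deterministic.
    """
    if x.is_processed:
        raise ValidationError("select_hvg expects a raw count matrix")
    if m < 2:
        raise ValidationError("m must be >= 2")
    if not np.any(x.values > 0):
        raise ValidationError("all-zero count matrix")
    d = x.n_genes
    m_eff = min(m, d)
    if m_eff == d:
        return replace(x, values=x.values.copy(), gene_ids=list(x.gene_ids))
    disp = gene_dispersion(x.values)
    # sort by (-dispersion, gene_id) then keep the top m in original order
    order = sorted(range(d), key=lambda j: (-disp[j], x.gene_ids[j]))
    keep = np.sort(np.array(order[:m_eff]))
    return replace(
        x,
        values=x.values[:, keep].copy(),
        gene_ids=[x.gene_ids[j] for j in keep],
    )


def normalize_counts(x: CountMatrix, cfg: PreprocessConfig | None = None) -> CountMatrix:
    """Median-total size-factor scaling -> log1p -> per-gene z-score.

    Size factors s_i = total_i / median(total) are recorded on the result so
    the ZINB likelihood can later rescale its mean head; the raw counts are
    retained as the reconstruction target.
    """
    if x.is_processed:
        raise ValidationError("normalize_counts expects a raw count matrix")
    cfg = cfg or PreprocessConfig()
    raw = x.values.copy()
    totals = raw.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValidationError(
            f"cells with zero total count: {[x.cell_ids[i] for i in zero[:5]]}"
        )
    size_factors = totals / np.median(totals)
    vals = raw / size_factors[:, None] if cfg.normalize else raw.astype(float)
    if cfg.log_transform:
        vals = np.log1p(vals)
    if cfg.scale:
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0)
        vals = (vals - mu) / np.where(sd > 0, sd, 1.0)
    return replace(
        x,
        values=vals,
        is_processed=True,
        size_factors=size_factors,
        raw=raw,
    )


def preprocess(x: CountMatrix, cfg: PreprocessConfig | None = None) -> CountMatrix:
    """HVG selection followed by normalization — the standard entry recipe."""
    cfg = cfg or PreprocessConfig()
    return normalize_counts(select_hvg(x, cfg.n_hvg), cfg)
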