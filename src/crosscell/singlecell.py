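"""Validation of gene sets against single-nucleus / single-cell matrices.

Matrices travel as :class:`anndata.AnnData` (cells x genes, sparse
allowed) with a cluster label per cell.  Filtering keeps genes detected
in at least three cells and cells detecting between 300 and 5000 genes
(gene filter first, then cell filter, applied once).  Normalization is
global scaling: ln(1 + count / cell total * 10000); the natural log
follows the convention of the single-cell toolchain this emulates and is
configurable.  Per-cluster metrics are the mean normalized expression
and the detection proportion above a threshold; gene-set comparisons use
ECDFs with a two-sample Kolmogorov-Smirnov test.  Depth curves
downsample reads without replacement (multivariate hypergeometric) and
count genes with log2(TPM + 1) > 1.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse
import scipy.stats

from .normalize import tpm as _tpm

MIN_CELLS_PER_GENE = 3
MIN_GENES_PER_CELL = 300
MAX_GENES_PER_CELL = 5000
DETECTION_THRESHOLD = 1.0
EXPRESSED_LOG2_TPM = 1.1  # gene expressed iff log2(TPM+1) > 1.1


def _dense(X) -> np.ndarray:
    if scipy.sparse.issparse(X):
        return np.asarray(X.todense())
    return np.asarray(X)


def filter_cells_genes(adata: ad.AnnData,
                       min_cells: int = MIN_CELLS_PER_GENE,
                       min_genes: int = MIN_GENES_PER_CELL,
                       max_genes: int = MAX_GENES_PER_CELL
                       ) -> tuple[ad.AnnData, dict[str, list[str]]]:
    """Drop rarely detected genes, then out-of-range cells.

    Boundaries follow the defining wording strictly: a gene detected in
    exactly ``min_cells`` cells is retained; a cell detecting exactly
    ``min_genes`` or ``max_genes`` genes is retained.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty matrix")
    X = adata.X
    detected = (X > 0)
    if scipy.sparse.issparse(X):
        cells_per_gene = np.asarray(detected.sum(axis=0)).ravel()
    else:
        cells_per_gene = detected.sum(axis=0)
    gene_keep = cells_per_gene >= min_cells
    removed_genes = adata.var_names[~gene_keep].tolist()
    adata = adata[:, gene_keep]
    X = adata.X
    if scipy.sparse.issparse(X):
        genes_per_cell = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        genes_per_cell = (X > 0).sum(axis=1)
    cell_keep = (genes_per_cell >= min_genes) & (genes_per_cell <= max_genes)
    removed_cells = adata.obs_names[~cell_keep].tolist()
    if not cell_keep.any():
        raise ValueError("all cells removed by the detected-gene filter")
    out = adata[cell_keep].copy()
    return out, {"genes": removed_genes, "cells": removed_cells}


def normalize_global_scaling(adata: ad.AnnData, scale: float = 1e4,
                             log=np.log1p) -> ad.AnnData:
    """value = log(1 + count / cell_total * scale), default natural log."""
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = adata.obs_names[np.where(totals == 0)[0][0]]
        raise ValueError(f"cell {bad!r} has zero total counts")
    out = adata.copy()
    out.X = log(X / totals[:, None] * scale)
    return out


def cluster_metrics(adata_norm: ad.AnnData, genes: Sequence[str],
                    cluster_key: str = "cluster",
                    threshold: float = DETECTION_THRESHOLD
                    ) -> tuple[pd.DataFrame, list[str]]:
    """Mean normalized expression and detection proportion per (gene,
    cluster).

    Genes absent from the matrix are returned in the second element of the
    tuple, never silently dropped.
    """
    present = [g for g in genes if g in adata_norm.var_names]
    missing = [g for g in genes if g not in adata_norm.var_names]
    clusters = adata_norm.obs[cluster_key]
    rows = []
    for cl in pd.unique(clusters):
        mask = (clusters == cl).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"cluster {cl!r} is empty")
        sub = _dense(adata_norm[mask, present].X)
        means = sub.mean(axis=0)
        props = (sub > threshold).mean(axis=0)
        for g, m, p in zip(present, means, props):
            rows.append({"gene_id": g, "cluster": cl,
                         "mean_expr": float(m), "detection_prop": float(p)})
    return pd.DataFrame(rows), missing


def detection_proportion(values, threshold: float = DETECTION_THRESHOLD) -> float:
    """Fraction of values strictly above the threshold."""
    arr = np.asarray(values, dtype=float)
    return float((arr > threshold).mean())


@dataclass
class ECDFComparison:
    """Two-sample ECDF comparison with a Kolmogorov-Smirnov test."""

    values_a: np.ndarray
    values_b: np.ndarray
    statistic: float
    pvalue: float

    def ecdf(self, which: str = "a"):
        vals = np.sort(self.values_a if which == "a" else self.values_b)
        return vals, np.arange(1, len(vals) + 1) / len(vals)


def ecdf_compare(values_a, values_b) -> ECDFComparison:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both gene sets must be nonempty")
    res = scipy.stats.ks_2samp(a, b, alternative="two-sided")
    return ECDFComparison(values_a=a, values_b=b,
                          statistic=float(res.statistic),
                          pvalue=float(res.pvalue))


def downsample_counts(counts: pd.Series, depth: int,
                      rng: np.random.Generator) -> pd.Series:
    """Draw ``depth`` reads without replacement from a count vector."""
    vec = counts.to_numpy()
    total = int(vec.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample total {total}")
    draw = rng.multivariate_hypergeometric(vec.astype(np.int64), depth,
                                           method="marginals")
    return pd.Series(draw, index=counts.index)


def downsample_detection_curve(counts: pd.Series, depths: Sequence[int],
                               lengths_bp: pd.Series,
                               threshold: float = EXPRESSED_LOG2_TPM,
                               seed: int | None = 0,
                               allow_zero_depth: bool = False) -> pd.DataFrame:
    """Genes detected per downsampling depth for one sample.

    TPM is computed with whole-gene lengths; a gene counts as expressed
    iff log2(TPM + 1) > threshold (equivalently TPM > 2**threshold - 1).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth == 0:
            if not allow_zero_depth:
                raise ValueError("depth must be positive")
            rows.append({"depth": 0, "n_detected": 0})
            continue
        sub = downsample_counts(counts, int(depth), rng)
        vals = _tpm(sub.to_frame("s"), lengths_bp)["s"]
        detected = int((np.log2(vals + 1.0) > threshold).sum())
        rows.append({"depth": int(depth), "n_detected": detected})
    return pd.DataFrame(rows)
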